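import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import malefert as mf
from malefert.imputation import fit_conditional_distribution


class TestFitConditionalDistribution:
    def test_direct_normalization(self):
        t = mf.BirthTable.from_records(
            [(2000, 30, 33, 90.0), (2000, 30, 28, 10.0)]
        )
        cond = fit_conditional_distribution(t)
        p = cond.prob(2000, 30)
        assert p[33] == pytest.approx(0.9)
        assert p[28] == pytest.approx(0.1)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_known_birth_gives_degenerate_distribution(self):
        t = mf.BirthTable.from_records([(2000, 22, 40, 1.0)])
        p = fit_conditional_distribution(t).prob(2000, 22)
        assert p[40] == 1.0
        assert p.drop(40).sum() == 0.0

    def test_widening_window_pools_adjacent_mother_ages(self):
        # maternal age 15 has only unknown-father births; ages 16 has known.
        t = mf.BirthTable.from_records(
            [
                (2000, 15, mf.UNKNOWN, 10.0),
                (2000, 16, 30, 6.0),
                (2000, 16, 35, 2.0),
                (2000, 20, 50, 100.0),
            ]
        )
        p = fit_conditional_distribution(t).prob(2000, 15)
        # pooled over maternal ages 14-16 present in the data, i.e. 16 only
        assert p[30] == pytest.approx(0.75)
        assert p[35] == pytest.approx(0.25)
        assert p[50] == 0.0

    def test_year_without_known_fathers_is_an_error(self):
        t = mf.BirthTable.from_records(
            [(2000, 30, 33, 5.0), (2001, 30, mf.UNKNOWN, 5.0)]
        )
        with pytest.raises(mf.ImputationError, match="2001"):
            fit_conditional_distribution(t)


class TestConditionalImpute:
    def test_worked_example_assigns_100_births_to_age_33(self, worked_example_table):
        out = mf.conditional_impute(worked_example_table)
        known_before = 100.0
        at_33 = out.df.query("mother_age == 30 and father_age == 33")["count"].sum()
        assert at_33 - known_before == pytest.approx(100.0, abs=1e-9)

    def test_complete_table_is_untouched(self, worked_example_table):
        complete = mf.BirthTable(
            worked_example_table.df[
                worked_example_table.df["father_age"] != mf.UNKNOWN
            ]
        )
        out = mf.conditional_impute(complete)
        pd.testing.assert_frame_equal(out.df, complete.df)

    def test_toy_table_matches_hand_enumeration(self):
        # 3 maternal x 3 paternal ages, 50 missing per maternal age
        records, expected = [], {}
        dists = {20: [5.0, 3.0, 2.0], 21: [1.0, 1.0, 2.0], 22: [0.0, 4.0, 6.0]}
        fathers = [22, 25, 28]
        for m, counts in dists.items():
            total = sum(counts)
            for p, c in zip(fathers, counts):
                if c:
                    records.append((2000, m, p, c))
                expected[(m, p)] = c + 50.0 * c / total
            records.append((2000, m, mf.UNKNOWN, 50.0))
        out = mf.conditional_impute(mf.BirthTable.from_records(records))
        for (m, p), want in expected.items():
            got = out.df.query("mother_age == @m and father_age == @p")["count"].sum()
            assert got == pytest.approx(want, abs=1e-9), (m, p)

    def test_double_unknown_births_follow_the_joint_distribution(self):
        t = mf.BirthTable.from_records(
            [
                (2000, 25, 27, 30.0),
                (2000, 30, 33, 70.0),
                (2000, mf.UNKNOWN, mf.UNKNOWN, 10.0),
            ]
        )
        out = mf.conditional_impute(t)
        assert out.total() == pytest.approx(110.0, abs=1e-9)
        got = out.df.query("mother_age == 25 and father_age == 27")["count"].sum()
        assert got == pytest.approx(33.0, abs=1e-9)

    def test_unknown_mother_known_father_rows_are_kept(self):
        t = mf.BirthTable.from_records(
            [(2000, 30, 33, 5.0), (2000, mf.UNKNOWN, 40, 2.0), (2000, 30, mf.UNKNOWN, 4.0)]
        )
        out = mf.conditional_impute(t)
        kept = out.df.query("mother_age == @mf.UNKNOWN and father_age == 40")["count"].sum()
        assert kept == 2.0
        assert not out.has_unknown_father()


class TestUnconditionalImpute:
    def test_uniform_marginal_splits_evenly(self):
        t = mf.BirthTable.from_records(
            [
                (2000, 25, 30, 10.0),
                (2000, 35, 33, 10.0),
                (2000, 30, mf.UNKNOWN, 100.0),
            ]
        )
        out = mf.unconditional_impute(t)
        a = out.df.query("mother_age == 30 and father_age == 30")["count"].sum()
        b = out.df.query("mother_age == 30 and father_age == 33")["count"].sum()
        assert a == pytest.approx(50.0) and b == pytest.approx(50.0)

    def test_single_atom_marginal(self):
        t = mf.BirthTable.from_records(
            [(2000, 25, 35, 3.0), (2000, 40, mf.UNKNOWN, 7.0)]
        )
        out = mf.unconditional_impute(t)
        assert out.df.query("father_age == 35")["count"].sum() == pytest.approx(10.0)

    def test_unconditional_is_biased_when_gap_depends_on_mother_age(self):
        sizes = {c: 100_000.0 * (1.25 if c < 1962 else 0.85) for c in range(1930, 1990)}
        base = dict(
            years=(1995, 1995), gap_age_slope=0.1, cohort_sizes=sizes, srb=105.0
        )
        truth_cfg = mf.ScenarioConfig(**base)
        exp = mf.generate_exposures(truth_cfg)
        complete = mf.generate_births(truth_cfg, exp)
        true_tfr = mf.true_indicators(complete, exp)[1995].male_tfr
        miss_cfg = mf.ScenarioConfig(
            **base, missing_model="MAR_maternal_age", missing_base=0.2, missing_slope=0.0666
        )
        observed = mf.apply_missingness(complete, miss_cfg)
        cond_tfr = mf.tfr(mf.compute_asfr(mf.conditional_impute(observed), exp, "male", 1995))
        unc_tfr = mf.tfr(mf.compute_asfr(mf.unconditional_impute(observed), exp, "male", 1995))
        assert abs(cond_tfr - true_tfr) < 1e-9
        assert abs(unc_tfr - true_tfr) > abs(cond_tfr - true_tfr)


class TestInvariants:
    @given(seed=st.integers(0, 200))
    def test_conservation_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        records = [
            (2000 + int(y), int(m), int(p), float(c))
            for y, m, p, c in zip(
                rng.integers(0, 2, n),
                rng.integers(15, 50, n),
                rng.integers(15, 60, n),
                rng.uniform(0, 100, n),
            )
        ]
        # make some fathers unknown but keep at least one known per year
        records.append((2000, 30, 33, 1.0))
        records.append((2001, 30, 33, 1.0))
        records.append((2000, 25, mf.UNKNOWN, float(rng.uniform(0, 50))))
        records.append((2001, 44, mf.UNKNOWN, float(rng.uniform(0, 50))))
        t = mf.BirthTable.from_records(records)
        before = t.totals_by_year()
        for impute in (mf.conditional_impute, mf.unconditional_impute):
            after = impute(t).totals_by_year()
            pd.testing.assert_series_equal(before, after, atol=1e-9, rtol=0)

    def test_imputed_father_ages_stay_on_male_support(self, worked_example_table):
        out = mf.conditional_impute(worked_example_table)
        assert out.df["father_age"].between(15, 59).all()

    def test_conditional_imputation_is_exact_under_mar(self):
        cfg = mf.ScenarioConfig(years=(1991, 1991))
        exp = mf.generate_exposures(cfg)
        complete = mf.generate_births(cfg, exp)
        miss = mf.ScenarioConfig(
            years=(1991, 1991), missing_model="MAR_maternal_age",
            missing_base=0.3, missing_slope=0.05,
        )
        observed = mf.apply_missingness(complete, miss)
        out = mf.conditional_impute(observed)
        true_sched = mf.compute_asfr(complete, exp, "male", 1991)
        got_sched = mf.compute_asfr(out, exp, "male", 1991)
        assert np.allclose(true_sched.rates, got_sched.rates, atol=1e-9)
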