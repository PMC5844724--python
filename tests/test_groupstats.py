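"""Rater averaging, rank tests vs enumeration oracles, summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larctex import (
    StudyConfig,
    average_raters,
    mann_whitney,
    paired_wilcoxon,
    run_group_tables,
    summarize_median_iqr,
)

from oracles import mannwhitney_exact_p, signed_rank_exact_p


class TestAverageRaters:
    def test_identical_raters_identity(self, small_cohort):
        cohort = small_cohort["cohort"]
        a = cohort[cohort.rater == "A"].copy()
        b = a.copy()
        b["rater"] = "B"
        doubled = pd.concat([a, b], ignore_index=True)
        out = average_raters(doubled)
        merged = out.merge(a, on=["patient_id", "timepoint"], suffixes=("_avg", ""))
        assert np.allclose(merged["uniformity_avg"], merged["uniformity"])

    def test_arithmetic_mean_of_two_raters(self, small_cohort):
        cohort = small_cohort["cohort"].copy()
        out = average_raters(cohort)
        row = cohort[(cohort.patient_id == "P001") & (cohort.timepoint == "pre")]
        want = row["entropy"].mean()
        got = out[(out.patient_id == "P001") & (out.timepoint == "pre")]["entropy"].iloc[0]
        assert got == pytest.approx(want, abs=1e-12)

    def test_row_count_halves(self, small_cohort):
        cohort = small_cohort["cohort"]
        out = average_raters(cohort)
        assert len(out) == len(cohort) / 2

    def test_missing_rater_names_cell(self, small_cohort):
        cohort = small_cohort["cohort"]
        broken = cohort.drop(
            cohort[
                (cohort.patient_id == "P002")
                & (cohort.timepoint == "early")
                & (cohort.rater == "B")
            ].index
        )
        with pytest.raises(ValueError, match="P002.*early"):
            average_raters(broken)


class TestPairedWilcoxon:
    def test_identical_pairs_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.warns(RuntimeWarning, match="zero"):
            res = paired_wilcoxon(x, x)
        assert res.p_value == 1.0

    def test_six_same_sign_differences_exact(self):
        pre = np.zeros(6)
        early = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = paired_wilcoxon(pre, early)
        assert res.p_value == pytest.approx(2 / 64, abs=1e-12)
        assert res.p_value == pytest.approx(signed_rank_exact_p(early - pre), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pre = rng.normal(size=8)
        early = pre + rng.normal(size=8)
        res = paired_wilcoxon(pre, early)
        assert res.p_value == pytest.approx(signed_rank_exact_p(early - pre), abs=1e-9)

    def test_power_at_study_size(self, rng):
        # shift 0.8 SD with n = 59 pairs: essentially always detected
        hits = 0
        for _ in range(20):
            pre = rng.standard_normal(59)
            early = pre + 0.8
            hits += paired_wilcoxon(pre, early).p_value < 0.001
        assert hits == 20


class TestMannWhitney:
    def test_worked_exact_case(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(
            mannwhitney_exact_p([1, 2, 3], [4, 5, 6]), abs=1e-12
        )

    def test_identical_groups_null(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value >= 0.99

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=int(rng.integers(3, 8)))
        b = rng.normal(size=int(rng.integers(3, 8)))
        res = mann_whitney(a, b)
        assert res.p_value == pytest.approx(mannwhitney_exact_p(a, b), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney([], [1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-50, 50), min_size=3, max_size=12, unique=True),
        b=st.lists(st.integers(-50, 50), min_size=3, max_size=12, unique=True),
    )
    def test_invariant_to_monotone_transform(self, a, b):
        p0 = mann_whitney(a, b).p_value
        f = lambda x: np.exp(np.asarray(x) / 25.0)
        assert mann_whitney(f(a), f(b)).p_value == pytest.approx(p0, abs=1e-12)


class TestSummaries:
    def test_odd_sample_median(self):
        assert summarize_median_iqr([1, 2, 3, 4, 5])[0] == 3.0

    def test_constant_vector(self):
        med, q1, q3 = summarize_median_iqr([7.0] * 9)
        assert med == q1 == q3 == 7.0

    def test_uniform_distributional_check(self, rng):
        x = rng.random(1000)
        med, q1, q3 = summarize_median_iqr(x)
        assert q1 == pytest.approx(0.25, abs=0.05)
        assert med == pytest.approx(0.50, abs=0.05)
        assert q3 == pytest.approx(0.75, abs=0.05)


class TestGroupTables:
    def test_directional_pcr_differences_on_default_cohort(self):
        from larctex import extract_cohort, generate_cohort, CohortSpec

        images, labels = generate_cohort(CohortSpec(seed=0))
        cohort = extract_cohort(images, labels, StudyConfig())
        averaged = average_raters(cohort)
        tables = run_group_tables(averaged, label="pcr")
        pre = tables["response"].set_index("parameter")
        assert pre.loc["pre-uniformity", "responder_median"] > pre.loc[
            "pre-uniformity", "nonresponder_median"
        ]
        assert pre.loc["pre-energy", "responder_median"] > pre.loc[
            "pre-energy", "nonresponder_median"
        ]
        assert pre.loc["pre-entropy", "responder_median"] < pre.loc[
            "pre-entropy", "nonresponder_median"
        ]
        # early treatment broadens the intensity histogram
        paired = tables["paired"].set_index("parameter")
        assert paired.loc["sd", "early_median"] > paired.loc["sd", "pre_median"]
        for name in ("kurtosis", "uniformity"):
            assert paired.loc[name, "early_median"] < paired.loc[name, "pre_median"]

    def test_single_patient_cohort_clean_error(self, small_cohort):
        cohort = small_cohort["cohort"]
        one = average_raters(cohort[cohort.patient_id == "P001"])
        with pytest.raises(ValueError, match="patients"):
            run_group_tables(one)

    def test_holm_adjustment_monotone(self, small_cohort):
        averaged = average_raters(small_cohort["cohort"])
        plain = run_group_tables(averaged, label="pcr")["response"]
        adj = run_group_tables(averaged, label="pcr", holm=True)["response"]
        assert (adj["p_holm"] >= plain["p"] - 1e-15).all()
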