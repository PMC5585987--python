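"""ddCt arithmetic, one-way ANOVA, Tukey letters, profile report, noise envelope."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from genefam.expression import (
    CtTable,
    ExpressionError,
    anova_oneway,
    delta_delta_ct,
    expression_profile_report,
    tukey_cld,
)


def _table(rows, reference="EF1a", calibrator=None):
    return CtTable(pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"]),
                   reference_gene=reference, calibrator_sample=calibrator)


def _hand_example():
    return _table([
        ("gX", "cal", 1, 28.0), ("EF1a", "cal", 1, 21.0),
        ("gX", "trt", 1, 25.0), ("EF1a", "trt", 1, 20.0),
    ], calibrator="cal")


class TestDeltaDeltaCt:
    def test_hand_worked_fold_of_four(self):
        """dCt 5 vs 7 gives ddCt -2, i.e. a four-fold induction."""
        long = delta_delta_ct(_hand_example())
        trt = long[long["sample"] == "trt"].iloc[0]
        cal = long[long["sample"] == "cal"].iloc[0]
        assert (cal.delta_ct, trt.delta_ct) == (7.0, 5.0)
        assert trt.delta_delta_ct == -2.0
        assert trt.fold_change == pytest.approx(4.0)

    def test_calibrator_fold_is_exactly_one(self):
        long = delta_delta_ct(_hand_example())
        cal = long[long["sample"] == "cal"]
        assert cal["fold_change"].mean() == pytest.approx(1.0)
        assert cal["delta_delta_ct"].mean() == pytest.approx(0.0)

    @given(st.floats(-5, 5))
    def test_global_ct_shift_invariance(self, shift):
        """Shifting every Ct by a constant leaves all folds unchanged."""
        base = delta_delta_ct(_hand_example())
        shifted_rows = [
            ("gX", "cal", 1, 28.0 + shift), ("EF1a", "cal", 1, 21.0 + shift),
            ("gX", "trt", 1, 25.0 + shift), ("EF1a", "trt", 1, 20.0 + shift),
        ]
        shifted = delta_delta_ct(_table(shifted_rows, calibrator="cal"))
        assert np.allclose(base["fold_change"], shifted["fold_change"])

    def test_missing_reference_named(self):
        rows = [("gX", "cal", 1, 28.0), ("EF1a", "cal", 1, 21.0),
                ("gX", "trt", 2, 25.0)]
        with pytest.raises(ExpressionError, match="trt"):
            delta_delta_ct(_table(rows, calibrator="cal"))


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert (res.F, res.p) == (0.0, 1.0)

    def test_textbook_sum_of_squares(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5 (df 1), SSW = 4 (df 4) -> F = 1.5
        res = anova_oneway({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert res.F == pytest.approx(1.5)
        f, p = sps.f_oneway([1, 2, 3], [2, 3, 4])
        assert res.F == pytest.approx(f) and res.p == pytest.approx(p)

    @given(st.floats(0.1, 50))
    def test_scale_invariance(self, c):
        base = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 5.0]})
        scaled = anova_oneway({"a": [c, 2 * c, 3 * c], "b": [2 * c, 4 * c, 5 * c]})
        assert scaled.F == pytest.approx(base.F, rel=1e-9)

    def test_single_replicate_group_rejected(self):
        with pytest.raises(ExpressionError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestTukeyCld:
    def test_equal_means_share_one_letter(self):
        _, letters = tukey_cld({"a": 1.0, "b": 1.0, "c": 1.0}, mse=0.5,
                               n_per_group=3, df_within=6)
        assert set(letters.values()) == {"a"}

    def test_forced_separation(self):
        _, letters = tukey_cld({"lo": 0.0, "hi": 50.0}, mse=0.01,
                               n_per_group=3, df_within=4)
        assert letters["hi"] != letters["lo"]

    def test_extremes_differ_middle_bridges(self):
        # hsd ~ 4.34 * sqrt(0.3585/3) ~= 1.5: only the 0 vs 2 comparison exceeds it
        pairwise, letters = tukey_cld({"A": 0.0, "B": 1.0, "C": 2.0}, mse=0.3585,
                                      n_per_group=3, df_within=6)
        assert sorted(letters.values()) == ["a", "ab", "b"]
        sig = {frozenset((r.group_a, r.group_b)): r.significant
               for r in pairwise.itertuples(index=False)}
        assert sig == {frozenset("AB"): False, frozenset("BC"): False,
                       frozenset("AC"): True}

    def test_critical_range_matches_studentized_range(self):
        pairwise, _ = tukey_cld({"a": 0.0, "b": 1.0}, mse=2.0, n_per_group=4,
                                df_within=6, alpha=0.05)
        q = sps.studentized_range.ppf(0.95, 2, 6)
        assert pairwise["critical_range"].iloc[0] == pytest.approx(q * math.sqrt(2.0 / 4))

    @given(st.integers(0, 2**31 - 1))
    def test_letters_consistent_with_pairwise_tests(self, seed):
        """Groups declared different never share a letter, and vice versa."""
        rng = np.random.default_rng(seed)
        means = {f"g{i}": float(rng.normal(0, 2)) for i in range(5)}
        pairwise, letters = tukey_cld(means, mse=float(rng.uniform(0.1, 2.0)),
                                      n_per_group=3, df_within=10)
        for row in pairwise.itertuples(index=False):
            shared = set(letters[row.group_a]) & set(letters[row.group_b])
            assert row.significant == (not shared)

    def test_nonpositive_mse_rejected(self):
        with pytest.raises(ExpressionError):
            tukey_cld({"a": 0.0, "b": 1.0}, mse=0.0, n_per_group=3, df_within=4)


class TestProfileReport:
    def _noiseless_table(self, fold_map, n_rep=3):
        rows = []
        for sample, fold in fold_map.items():
            for rep in range(1, n_rep + 1):
                rows.append(("EF1a", sample, rep, 19.0))
                rows.append(("gX", sample, rep, 25.0 - math.log2(fold)))
        return _table(rows, calibrator="0h")

    def test_planted_eightfold_is_preferential(self):
        report = expression_profile_report(
            self._noiseless_table({"0h": 1.0, "1h": 8.0, "24h": 2.0}))
        summ = report["gX"]
        assert summ.preferential_sample == "1h"
        row = summ.table.set_index("sample").loc["1h"]
        assert row.mean_fold == pytest.approx(8.0)
        assert summ.anova is not None

    def test_single_sample_summary_only(self):
        report = expression_profile_report(self._noiseless_table({"0h": 1.0}))
        assert report["gX"].anova is None
        assert report["gX"].table.shape[0] == 1

    def test_identical_replicates_zero_sd(self):
        report = expression_profile_report(
            self._noiseless_table({"0h": 1.0, "3h": 2.0}, n_rep=2))
        assert (report["gX"].table["sd_fold"] == 0).all()

    def test_bundle_planted_folds_recovered(self, bundle):
        """The generator's planted 8x induction is recovered within noise."""
        table = CtTable.from_tsv(bundle.paths["ct_table"],
                                 reference_gene=bundle.ground_truth["reference_gene"],
                                 calibrator_sample=bundle.ground_truth["calibrator_sample"])
        report = expression_profile_report(table)
        truth = bundle.ground_truth["fold_changes"]["g01"]
        peak_sample = max(truth, key=truth.get)
        summ = report["g01"]
        assert summ.preferential_sample == peak_sample
        est = summ.table.set_index("sample").loc[peak_sample, "mean_fold"]
        sigma = bundle.ground_truth["ct_noise_sd"]
        assert truth[peak_sample] / 2 ** (3 * sigma) <= est <= truth[peak_sample] * 2 ** (3 * sigma)


class TestNoiseEnvelope:
    def test_fold_estimate_within_envelope(self):
        """With sigma = 0.2 Ct noise the mean-ddCt fold estimate stays inside
        [f/2^(3 sigma), f 2^(3 sigma)] in >= 99% of simulations (binomial
        consistency check over 200 replicates, fixed seed)."""
        rng = np.random.default_rng(2024)
        sigma, fold, n_rep, n_sim = 0.2, 8.0, 3, 200
        lo, hi = fold / 2 ** (3 * sigma), fold * 2 ** (3 * sigma)
        failures = 0
        for _ in range(n_sim):
            rows = []
            for sample, f in (("0h", 1.0), ("trt", fold)):
                for rep in range(1, n_rep + 1):
                    ref = 19.0 + rng.normal(0, sigma)
                    rows.append(("EF1a", sample, rep, ref))
                    rows.append(("gX", sample, rep,
                                 ref + 6.0 - math.log2(f) + rng.normal(0, sigma)))
            long = delta_delta_ct(_table(rows, calibrator="0h"))
            mean_ddct = long.loc[long["sample"] == "trt", "delta_delta_ct"].mean()
            est = 2.0 ** (-mean_ddct)
            if not (lo <= est <= hi):
                failures += 1
        # consistent with a >= 99% in-envelope rate at alpha = 0.01
        pvalue = sps.binomtest(failures, n_sim, 0.01, alternative="greater").pvalue
        assert pvalue > 0.01, f"{failures}/{n_sim} outside envelope"
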