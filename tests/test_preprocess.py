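"""Normalization chain, quantile normalization, fold-range tabulation,
and the two array-identity QC checks."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bxdeqtl import (
    ExpressionPanel,
    InvalidParameterError,
    NormalizedPanel,
    ValidationError,
    fold_range_histogram,
    normalize_panel,
    quantile_normalize,
    sex_check,
    strain_identity_check,
    summarize_by_strain,
)
from bxdeqtl.core import StrainSummary
from bxdeqtl.preprocess import FOLD_LABELS, LOG2_LABELS, two_means_split


def _panel(signals: np.ndarray, sexes=None, strains=None, f1=None) -> ExpressionPanel:
    n_a, n_p = signals.shape
    arrays = [f"a{i}" for i in range(n_a)]
    probes = [f"p{i}" for i in range(n_p)]
    samples = pd.DataFrame(
        {
            "strain_id": strains or [f"S{i}" for i in range(n_a)],
            "sex": sexes or ["F"] * n_a,
            "is_f1": f1 or [False] * n_a,
        },
        index=pd.Index(arrays, name="array_id"),
    )
    anno = pd.DataFrame(
        {"symbol": probes, "chrom": ["1"] * n_p, "mb": np.linspace(1, 50, n_p)},
        index=pd.Index(probes, name="probe_id"),
    )
    return ExpressionPanel(samples, anno, pd.DataFrame(signals, index=arrays, columns=probes))


class TestQuantileNormalize:
    def test_rank_mean_by_hand(self):
        out = quantile_normalize(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        np.testing.assert_allclose(out, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_tie_rule_by_hand(self):
        # reference = mean of sorted rows = [2, 2.5, 3.5]; the tied pair in
        # row 1 occupies ranks 1-2 and receives their reference mean 2.25
        out = quantile_normalize(np.array([[1.0, 1.0, 2.0], [3.0, 4.0, 5.0]]))
        np.testing.assert_allclose(out[0], [2.25, 2.25, 3.5])
        np.testing.assert_allclose(out[1], [2.0, 2.5, 3.5])

    def test_identically_distributed_arrays_unchanged(self):
        x = np.array([[0.0, 1.0, 3.0], [3.0, 0.0, 1.0]])
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_requires_two_arrays(self):
        with pytest.raises(InvalidParameterError):
            quantile_normalize(np.array([[1.0, 2.0]]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sorted_vectors_identical_and_ranks_preserved(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 25))
        out = quantile_normalize(x)
        ref = np.sort(out[0])
        for row_in, row_out in zip(x, out):
            np.testing.assert_allclose(np.sort(row_out), ref)
            # within-array rank order preserved (ties may merge, never cross)
            order = np.argsort(row_in, kind="stable")
            assert (np.diff(row_out[order]) >= -1e-12).all()


class TestNormalizePanel:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_every_array_mean8_sd2(self, seed):
        rng = np.random.default_rng(seed)
        panel = _panel(rng.gamma(2.0, 200.0, size=(5, 40)))
        norm = normalize_panel(panel)
        v = norm.values.to_numpy()
        np.testing.assert_allclose(v.mean(axis=1), 8.0, atol=1e-9)
        np.testing.assert_allclose(v.std(axis=1, ddof=0), 2.0, atol=1e-9)

    def test_three_value_example_by_hand(self):
        # both arrays carry {0,1,3}: the quantile step is the identity on the
        # log2 values, so the output is exactly the 2Z+8 transform of log2(x+1)
        panel = _panel(np.array([[0.0, 1.0, 3.0], [3.0, 0.0, 1.0]]))
        norm = normalize_panel(panel)
        log2 = np.log2(np.array([0.0, 1.0, 3.0]) + 1)
        z = (log2 - log2.mean()) / log2.std(ddof=0)
        expected = 2 * z + 8
        np.testing.assert_allclose(norm.values.iloc[0].to_numpy(), expected, atol=1e-12)
        np.testing.assert_allclose(
            norm.values.iloc[1].to_numpy(), expected[[2, 0, 1]], atol=1e-12
        )

    def test_zero_variance_array_named_in_error(self):
        panel = _panel(np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]]))
        with pytest.raises(ValidationError, match="a0"):
            normalize_panel(panel)

    def test_z_step_idempotent_on_normalized_values(self, small_norm):
        v = small_norm.values.to_numpy()
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=0, keepdims=True)
        np.testing.assert_allclose(2 * z + 8, v, atol=1e-9)


class TestFoldRangeHistogram:
    def test_bin_assignment(self):
        values = pd.DataFrame(
            {
                "flat": [8.0, 8.0, 8.0],       # range 0 -> first bin
                "mid": [6.0, 8.0, 10.5],       # range 4.5 -> "16-32"/"4-5"
                "wide": [2.0, 8.0, 9.0],       # range 7 -> "64-inf"
            }
        )
        summary = StrainSummary(values, pd.Series(1, index=values.index),
                                pd.DataFrame(index=values.columns))
        hist = fold_range_histogram(summary)
        assert list(hist["fold_range"]) == list(FOLD_LABELS)
        assert list(hist["log2_range"]) == list(LOG2_LABELS)
        lookup = hist.set_index("log2_range")["n_probes"]
        assert lookup["0-1"] == 1 and lookup["4-5"] == 1 and lookup["6-inf"] == 1
        assert hist["n_probes"].sum() == 3

    def test_counts_sum_and_array_permutation_invariance(self, small_norm):
        hist = fold_range_histogram(small_norm)
        assert hist["n_probes"].sum() == small_norm.n_probes
        shuffled = NormalizedPanel(
            small_norm.samples, small_norm.probes, small_norm.values.iloc[::-1]
        )
        pd.testing.assert_frame_equal(hist, fold_range_histogram(shuffled))


class TestSexCheck:
    MARKERS = ["p0", "p1", "p2"]

    def _sexed_panel(self, effect=4.0, noise=1.0, swap=None, seed=0):
        rng = np.random.default_rng(seed)
        n = 30
        sexes = ["F" if i % 2 == 0 else "M" for i in range(n)]
        base = rng.normal(8, noise, size=(n, 60))
        is_f = np.array([effect if s == "F" else 0.0 for s in sexes])
        base[:, :3] += is_f[:, None]
        declared = list(sexes)
        if swap is not None:
            declared[swap] = "M" if declared[swap] == "F" else "F"
        return _panel(np.exp2(base), sexes=declared), sexes

    def test_planted_sex_effect_all_called(self):
        panel, true_sexes = self._sexed_panel()
        report = sex_check(normalize_panel(panel), self.MARKERS, [])
        assert list(report.sex["inferred_sex"]) == true_sexes
        assert not report.sex["mismatch"].any()

    def test_swapped_declaration_flagged_exactly(self):
        panel, _ = self._sexed_panel(swap=3)
        report = sex_check(normalize_panel(panel), self.MARKERS, [])
        assert list(report.sex.index[report.sex["mismatch"]]) == ["a3"]

    def test_degenerate_markers_indeterminate(self):
        panel, _ = self._sexed_panel(effect=0.0, noise=1.0)
        norm = normalize_panel(panel)
        norm.values["p0"] = 8.0  # identical marker values on every array
        report = sex_check(norm, ["p0"], [])
        assert (report.sex["inferred_sex"] == "indeterminate").all()
        assert report.sex["mismatch"].all()

    def test_missing_marker_probe_listed(self, small_norm):
        with pytest.raises(ValidationError, match="nope_at"):
            sex_check(small_norm, ["nope_at"], [])


class TestStrainIdentityCheck:
    def test_clean_panel_all_pass(self, small_norm, small_genotypes, small_truth):
        report = strain_identity_check(small_norm, small_genotypes, small_truth.mendelian_probes)
        non_f1 = ~small_norm.samples["is_f1"]
        verdicts = report.strain.loc[non_f1.index[non_f1], "identity_verdict"]
        assert (verdicts == "pass").all()
        f1_verdicts = report.strain.loc[non_f1.index[~non_f1], "identity_verdict"]
        assert (f1_verdicts == "skipped").all()

    def test_relabelled_array_flagged(self, small_norm, small_genotypes, small_truth):
        samples = small_norm.samples.copy()
        arrays = samples.index[~samples["is_f1"]]
        victim = arrays[0]
        donor = samples.loc[arrays[-1], "strain_id"]
        assert samples.loc[victim, "strain_id"] != donor
        samples.loc[victim, "strain_id"] = donor
        relabelled = NormalizedPanel(samples, small_norm.probes, small_norm.values)
        report = strain_identity_check(relabelled, small_genotypes, small_truth.mendelian_probes)
        conc = report.strain.loc[victim, "identity_concordance"]
        if conc < 0.8:
            assert report.strain.loc[victim, "flagged"]

    def test_no_probes_is_an_error(self, small_norm, small_genotypes):
        with pytest.raises(InvalidParameterError):
            strain_identity_check(small_norm, small_genotypes, [])

    def test_unimodal_probe_excluded_with_warning(self, small_norm, small_genotypes, small_truth):
        probes = list(small_truth.mendelian_probes)
        background = [p for p in small_norm.values.columns
                      if p not in set(probes) and small_norm.probes.loc[p, "chrom"] != "unmapped"][0]
        with pytest.warns(UserWarning, match="not bimodal"):
            report = strain_identity_check(
                small_norm, small_genotypes, probes + [background]
            )
        assert (report.strain["n_mendelian_probes"] == len(probes)).all()


class TestTwoMeansSplit:
    def test_clear_separation(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        high, sil = two_means_split(x)
        np.testing.assert_array_equal(high, [False] * 3 + [True] * 3)
        assert sil > 0.9

    def test_constant_returns_none(self):
        assert two_means_split(np.ones(5)) is None


class TestSummarizeByStrain:
    def test_replicate_mean_and_f1_exclusion(self, small_norm):
        summary = summarize_by_strain(small_norm)
        assert not any(s.startswith(("B6D2", "D2B6")) for s in summary.strains)
        strain = summary.strains[0]
        arrays = small_norm.samples.index[small_norm.samples["strain_id"] == strain]
        np.testing.assert_allclose(
            summary.values.loc[strain],
            small_norm.values.loc[arrays].mean(axis=0),
        )
        assert (summary.counts >= 1).all()

    def test_single_array_is_identity(self):
        panel = _panel(np.arange(8.0).reshape(2, 4) + 1)
        norm = normalize_panel(panel)
        summary = summarize_by_strain(norm)
        np.testing.assert_allclose(summary.values.to_numpy(),
                                   norm.values.to_numpy())

    def test_pair_of_replicates_averages(self):
        panel = _panel(np.array([[7.0, 1.0], [9.0, 3.0]]), strains=["S", "S"])
        norm = NormalizedPanel(panel.samples, panel.probes, panel.signals * 1.0)
        summary = summarize_by_strain(norm)
        np.testing.assert_allclose(summary.values.loc["S"], [8.0, 2.0])
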