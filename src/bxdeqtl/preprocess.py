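"""Normalization chain and array-identity quality control.

The normalization applied to every dataset, in this exact order:

1. add an offset of 1 unit to each raw signal (so all logs are positive),
2. take log2,
3. quantile-normalize the log2 values over the full set of arrays,
4. compute per-array Z scores, multiply by 2 and add 8.

The result is positive everywhere, every array has mean 8 and population
standard deviation 2, and one unit corresponds to roughly a two-fold
difference in expression.

Two sample-identity checks accompany the chain: a sex check from
female/male marker transcripts (Xist-like probes are only expressed at high
levels in females) and a strain-identity check from Mendelian bimodal
transcripts, whose expression is directly correlated with the genotype at
their own locus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ExpressionPanel,
    GenotypeMatrix,
    InvalidParameterError,
    NormalizedPanel,
    StrainSummary,
    ValidationError,
)

#: fold-range histogram bin edges on the log2 scale (left-closed, right-open)
FOLD_BIN_EDGES = (0, 1, 2, 3, 4, 5, 6, np.inf)
FOLD_LABELS = ("1-2", "2-4", "4-8", "8-16", "16-32", "32-64", "64-inf")
LOG2_LABELS = ("0-1", "1-2", "2-3", "3-4", "4-5", "5-6", "6-inf")


def quantile_normalize(matrix) -> np.ndarray:
    """Force all arrays (rows) to share an identical value distribution.

    Each value is replaced by the mean, across arrays, of the values at the
    same rank (the initial step of the RMA transform). Ties within an array
    all receive the mean of the rank-mean reference values over the ranks
    they occupy, so the transform is well defined and rank-preserving.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidParameterError("need a 2-D matrix with at least 2 arrays")
    sorted_rows = np.sort(x, axis=1)
    ref = sorted_rows.mean(axis=0)
    cum = np.concatenate([[0.0], np.cumsum(ref)])

    out = np.empty_like(x)
    for i in range(x.shape[0]):
        order = np.argsort(x[i], kind="stable")
        sr = x[i][order]
        # runs of tied values occupy a contiguous rank block
        starts = np.flatnonzero(np.concatenate([[True], np.diff(sr) != 0]))
        ends = np.concatenate([starts[1:], [len(sr)]])
        run_means = (cum[ends] - cum[starts]) / (ends - starts)
        assigned = np.repeat(run_means, ends - starts)
        out[i][order] = assigned
    return out


def normalize_panel(raw: ExpressionPanel) -> NormalizedPanel:
    """Apply the full normalization chain to a raw panel.

    Raises :class:`ValidationError`, naming the array, if any array has zero
    variance after quantile normalization (its Z scores would be undefined).
    """
    if raw.n_arrays < 2 or raw.n_probes < 2:
        raise InvalidParameterError("need at least 2 arrays and 2 probes")
    x = np.log2(raw.signals.to_numpy(dtype=float) + 1.0)
    q = quantile_normalize(x)
    mean = q.mean(axis=1, keepdims=True)
    sd = q.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() <= 0)
    if flat.size:
        raise ValidationError(
            f"array {raw.signals.index[flat[0]]!r} has zero variance after "
            "quantile normalization; Z scores undefined"
        )
    values = 2.0 * (q - mean) / sd + 8.0
    return NormalizedPanel(
        raw.samples.copy(),
        raw.probes.copy(),
        pd.DataFrame(values, index=raw.signals.index, columns=raw.signals.columns),
    )


def _values_matrix(data) -> pd.DataFrame:
    if isinstance(data, (NormalizedPanel, StrainSummary)):
        return data.values
    return pd.DataFrame(data)


def fold_range_histogram(data) -> pd.DataFrame:
    """Tabulate per-probe expression ranges into fold-change bins.

    ``data`` may be a :class:`NormalizedPanel` (range across arrays) or a
    :class:`StrainSummary` (range across strains). The range max - min is in
    normalized units where 1 unit is about a 2-fold difference; bins are
    left-closed, right-open: [0,1), [1,2), ..., [6, inf).
    """
    values = _values_matrix(data)
    if values.shape[1] < 1:
        raise InvalidParameterError("need at least one probe")
    v = values.to_numpy(dtype=float)
    ranges = v.max(axis=0) - v.min(axis=0)
    counts, _ = np.histogram(ranges, bins=np.asarray(FOLD_BIN_EDGES, dtype=float))
    return pd.DataFrame(
        {
            "fold_range": FOLD_LABELS,
            "log2_range": LOG2_LABELS,
            "n_probes": counts.astype(int),
        }
    )


def two_means_split(x: np.ndarray):
    """Exact 1-D two-means clustering by best split of the sorted values.

    Returns (high_mask, silhouette) or None when the values are constant
    (no meaningful split exists).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    cum = np.cumsum(xs)
    total = cum[-1]
    best_k, best_ss = 1, np.inf
    for k in range(1, n):
        m1 = cum[k - 1] / k
        m2 = (total - cum[k - 1]) / (n - k)
        ss = ((xs[:k] - m1) ** 2).sum() + ((xs[k:] - m2) ** 2).sum()
        if ss < best_ss:
            best_ss, best_k = ss, k
    high = np.zeros(n, dtype=bool)
    high[order[best_k:]] = True

    # mean silhouette coefficient of the two clusters
    d = np.abs(x[:, None] - x[None, :])
    sil = np.zeros(n)
    for i in range(n):
        same = high == high[i]
        same[i] = False
        a = d[i, same].mean() if same.any() else 0.0
        b = d[i, ~same & (np.arange(n) != i)].mean()
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return high, float(sil.mean())


@dataclass
class QcReport:
    """Per-array identity QC verdicts; every array appears exactly once."""

    sex: pd.DataFrame = field(default_factory=pd.DataFrame)
    strain: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def flagged_arrays(self) -> list[str]:
        flagged: set[str] = set()
        if len(self.sex) and "mismatch" in self.sex:
            flagged |= set(self.sex.index[self.sex["mismatch"]])
        if len(self.strain) and "flagged" in self.strain:
            flagged |= set(self.strain.index[self.strain["flagged"]])
        return sorted(flagged)

    def to_frame(self) -> pd.DataFrame:
        out = self.sex.join(self.strain, how="outer")
        out.index.name = "array_id"
        return out.reset_index()


def sex_check(
    norm: NormalizedPanel,
    female_marker_probes: list[str],
    male_marker_probes: list[str] = (),
) -> QcReport:
    """Infer each array's sex from marker transcripts and flag mismatches.

    The per-array score is mean(female markers) - mean(male markers); arrays
    are split by exact two-means and the high-score cluster is called female.
    Degenerate input (all arrays identical on the markers) yields
    ``indeterminate`` calls, all flagged.
    """
    markers = list(female_marker_probes) + list(male_marker_probes)
    if not markers:
        raise InvalidParameterError("need at least one sex marker probe")
    missing = [p for p in markers if p not in norm.values.columns]
    if missing:
        raise ValidationError(f"sex marker probes absent from panel: {missing}")

    score = np.zeros(norm.n_arrays)
    if female_marker_probes:
        score = score + norm.values[list(female_marker_probes)].mean(axis=1).to_numpy()
    if male_marker_probes:
        score = score - norm.values[list(male_marker_probes)].mean(axis=1).to_numpy()

    split = two_means_split(score)
    declared = norm.samples["sex"].astype(str)
    if split is None:
        inferred = pd.Series("indeterminate", index=norm.values.index)
        mismatch = pd.Series(True, index=norm.values.index)
    else:
        high, _ = split
        inferred = pd.Series(np.where(high, "F", "M"), index=norm.values.index)
        mismatch = inferred != declared.reindex(norm.values.index)
    frame = pd.DataFrame(
        {
            "declared_sex": declared.reindex(norm.values.index),
            "inferred_sex": inferred,
            "mismatch": mismatch,
        }
    )
    return QcReport(sex=frame)


def strain_identity_check(
    norm: NormalizedPanel,
    genotypes: GenotypeMatrix,
    mendelian_probes: list[str],
    concordance_threshold: float = 0.8,
    silhouette_threshold: float = 0.7,
) -> QcReport:
    """Confirm array-to-strain assignment from Mendelian bimodal transcripts.

    For each Mendelian probe the arrays are split low/high by two-means and
    each array's class is compared with its strain's genotype at the marker
    nearest the probe (high class mapped to whichever allele maximizes
    overall concordance). Probes whose split silhouette falls below
    ``silhouette_threshold`` (unimodal expression) are excluded with a
    warning. Arrays with concordance below ``concordance_threshold`` are
    flagged; arrays whose strain has no genotypes (e.g. F1s) are skipped.
    """
    if not mendelian_probes:
        raise InvalidParameterError("need at least one Mendelian probe")
    missing = [p for p in mendelian_probes if p not in norm.values.columns]
    if missing:
        raise ValidationError(f"Mendelian probes absent from panel: {missing}")

    map_t = genotypes.map.table
    arrays = norm.values.index
    strains = norm.samples["strain_id"].reindex(arrays)
    known = strains.isin(genotypes.strains).to_numpy()

    agree = np.zeros(len(arrays))
    used = np.zeros(len(arrays))
    n_used_probes = 0
    for probe in mendelian_probes:
        anno = norm.probes.loc[probe]
        chrom = str(anno["chrom"])
        sub = map_t[map_t["chrom"] == chrom]
        if sub.empty or pd.isna(anno["mb"]):
            raise ValidationError(
                f"Mendelian probe {probe!r} has no marker-map coverage (chr {chrom})"
            )
        nearest = sub.iloc[(sub["mb"] - float(anno["mb"])).abs().argmin()]["marker_id"]
        geno = genotypes.calls[nearest]

        split = two_means_split(norm.values[probe].to_numpy())
        if split is None:
            warnings.warn(f"Mendelian probe {probe!r} constant; excluded from identity check")
            continue
        high, sil = split
        if sil < silhouette_threshold:
            warnings.warn(
                f"Mendelian probe {probe!r} not bimodal (silhouette {sil:.2f}); excluded"
            )
            continue
        n_used_probes += 1
        g = geno.reindex(strains).to_numpy(dtype=float)  # per-array genotype
        valid = known & ~np.isnan(g)
        match_d_high = (high == (g > 0)) & valid
        match_b_high = (high == (g < 0)) & valid
        # orient the high class to the allele with majority agreement
        matches = match_d_high if match_d_high.sum() >= match_b_high.sum() else match_b_high
        agree += matches & valid
        used += valid

    with np.errstate(invalid="ignore"):
        concordance = np.where(used > 0, agree / np.maximum(used, 1), np.nan)
    verdict = np.where(
        ~known,
        "skipped",
        np.where(used == 0, "skipped", np.where(concordance >= concordance_threshold, "pass", "flagged")),
    )
    frame = pd.DataFrame(
        {
            "identity_concordance": concordance,
            "identity_verdict": verdict,
            "flagged": verdict == "flagged",
            "n_mendelian_probes": n_used_probes,
        },
        index=arrays,
    )
    return QcReport(strain=frame)


def run_qc(
    norm: NormalizedPanel,
    genotypes: GenotypeMatrix | None = None,
    female_marker_probes: list[str] = (),
    male_marker_probes: list[str] = (),
    mendelian_probes: list[str] = (),
    **kwargs,
) -> QcReport:
    """Run whichever identity checks have marker probes available."""
    report = QcReport()
    if female_marker_probes or male_marker_probes:
        report.sex = sex_check(norm, female_marker_probes, male_marker_probes).sex
    if mendelian_probes and genotypes is not None:
        report.strain = strain_identity_check(norm, genotypes, mendelian_probes, **kwargs).strain
    return report


def summarize_by_strain(norm: NormalizedPanel) -> StrainSummary:
    """Average replicate arrays per strain; F1 arrays are excluded.

    Mapping consumes one value per strain, so this is the hand-off between
    normalization and the genome scan.
    """
    keep = ~norm.samples["is_f1"].astype(bool)
    samples = norm.samples[keep]
    values = norm.values.loc[samples.index]
    grouped = values.groupby(samples["strain_id"], sort=True)
    means = grouped.mean()
    counts = grouped.size()
    means.index.name = "strain_id"
    return StrainSummary(means, counts, norm.probes.copy())
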