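"""Correlation networks and seeded principal-component signatures.

Two complementary procedures for extracting co-regulated gene sets from the
strain-mean expression matrix:

* all-pairs correlation above a threshold (Pearson or Spearman), the way a
  correlation network is assembled;
* a cell-type signature seeded with a few marker genes: the first principal
  component of the standardized seed profiles is treated as a latent
  cell-proportion score per strain, and every probe correlated with it above
  a threshold joins the signature (Klra3/Gzma/Il18rap/Klrg1-style NK
  signatures, Cd3d for T cells, Cd19 for B cells).

Correlation p-values use the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2)
with n-2 degrees of freedom (exact under normality); the Spearman p applies
the same transform to rho.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidParameterError, StrainSummary, ValidationError


def correlation_test(r: float, n: int) -> float:
    """Two-sided p-value for a correlation of ``r`` over ``n`` samples.

    Uses the t transform with n-2 degrees of freedom. |r| = 1 returns 0.0
    (the statistic underflows any representable tail probability).
    """
    if n < 4:
        raise InvalidParameterError("need at least 4 samples")
    r = float(r)
    if abs(r) > 1:
        raise InvalidParameterError("correlation outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _drop_constant(values: pd.DataFrame) -> pd.DataFrame:
    v = values.to_numpy(dtype=float)
    keep = v.var(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(values.columns, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} constant probes from correlation: {dropped[:3]}")
        values = values.loc[:, keep]
    return values


def correlation_pairs(
    summary: StrainSummary,
    method: str = "pearson",
    threshold: float = 0.8,
    min_variance: float = 0.0,
) -> pd.DataFrame:
    """All unordered probe pairs whose |correlation| exceeds ``threshold``.

    ``method`` selects the gating statistic (pearson or spearman); both
    coefficients are reported for every returned pair, along with the sample
    size and the two-sided p-value of the gating statistic. Pairs are listed
    once with probe_a < probe_b, sorted lexicographically.
    """
    if method not in ("pearson", "spearman"):
        raise InvalidParameterError(f"unknown correlation method {method!r}")
    if not 0 < threshold <= 1:
        raise InvalidParameterError("threshold must be in (0, 1]")
    if summary.n_strains < 4:
        raise InvalidParameterError("need at least 4 strains")

    values = summary.values[sorted(summary.values.columns)]
    values = _drop_constant(values)
    if min_variance > 0:
        v = values.to_numpy(dtype=float)
        values = values.loc[:, v.var(axis=0) >= min_variance]
    probes = values.columns.tolist()
    n = len(values)
    x = values.to_numpy(dtype=float)
    pear = np.corrcoef(x, rowvar=False)
    ranks = stats.rankdata(x, axis=0)
    spear = np.corrcoef(ranks, rowvar=False)

    gate = pear if method == "pearson" else spear
    iu, ju = np.triu_indices(len(probes), k=1)
    sel = np.abs(gate[iu, ju]) > threshold
    rows = []
    for i, j in zip(iu[sel], ju[sel]):
        r_gate = gate[i, j]
        rows.append(
            {
                "probe_a": probes[i],
                "probe_b": probes[j],
                "pearson_r": float(pear[i, j]),
                "spearman_rho": float(spear[i, j]),
                "n": n,
                "p": correlation_test(np.clip(r_gate, -1, 1), n),
            }
        )
    out = pd.DataFrame(rows, columns=["probe_a", "probe_b", "pearson_r", "spearman_rho", "n", "p"])
    return out.sort_values(["probe_a", "probe_b"], kind="stable").reset_index(drop=True)


@dataclass
class Signature:
    """A seeded PC1 expression signature.

    ``scores`` holds the per-strain first-principal-component score of the
    standardized seed profiles (oriented so the mean seed loading is
    positive); ``members`` lists every probe whose |correlation| with the
    scores clears the gate, with the signed correlation reported. Seeds are
    recorded even when they fall below the threshold.
    """

    seeds: list[str]
    scores: pd.Series
    members: pd.DataFrame
    threshold: float
    p_threshold: float | None = None


def pc_signature(
    summary: StrainSummary,
    seed_probes: list[str],
    threshold: float = 0.8,
    max_members: int | None = None,
    p_threshold: float | None = None,
) -> Signature:
    """Expand a seed gene set into a signature via its first principal component.

    The seed submatrix is strain-standardized per probe (correlation-matrix
    PCA), PC1 scores are computed per strain and oriented so the mean seed
    loading is positive, and every probe in the summary is correlated with
    the scores. Membership is gated on |r| >= ``threshold`` or, when
    ``p_threshold`` is given, on p <= p_threshold; ``max_members`` caps the
    signature by descending |r|.
    """
    seeds = list(seed_probes)
    if len(seeds) < 2:
        raise InvalidParameterError("need at least 2 seed probes")
    if summary.n_strains < 4:
        raise InvalidParameterError("need at least 4 strains")
    missing = [s for s in seeds if s not in summary.values.columns]
    if missing:
        raise ValidationError(f"seed probes absent from panel: {missing}")

    x = summary.values[seeds].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        dead = [s for s, v in zip(seeds, sd) if v == 0]
        warnings.warn(f"seed probes with zero variance excluded: {dead}")
        seeds = [s for s, v in zip(seeds, sd) if v > 0]
        if len(seeds) < 2:
            raise ValidationError("fewer than 2 informative seed probes")
        x = summary.values[seeds].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=0)
    z = (x - x.mean(axis=0)) / sd

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    if loadings.mean() < 0:
        scores, loadings = -scores, -loadings
    scores_s = pd.Series(scores, index=summary.values.index, name="pc1")

    values = _drop_constant(summary.values)
    v = values.to_numpy(dtype=float)
    vz = (v - v.mean(axis=0)) / v.std(axis=0, ddof=0)
    sz = (scores - scores.mean()) / scores.std(ddof=0)
    corr = vz.T @ sz / len(sz)
    n = len(sz)

    frame = pd.DataFrame(
        {
            "probe_id": values.columns,
            "symbol": summary.probes["symbol"].reindex(values.columns).to_numpy(),
            "correlation": corr,
        }
    )
    frame["p"] = [correlation_test(np.clip(r, -1, 1), n) for r in frame["correlation"]]
    if p_threshold is not None:
        member_mask = frame["p"] <= p_threshold
    else:
        member_mask = frame["correlation"].abs() >= threshold
    members = frame[member_mask].copy()
    members = members.reindex(members["correlation"].abs().sort_values(ascending=False).index)
    if max_members is not None:
        members = members.head(max_members)
    members = members.reset_index(drop=True)
    return Signature(seeds, scores_s, members, threshold, p_threshold)
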