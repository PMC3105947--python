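"""Per-transcript heritability from replicate arrays.

Heritability is estimated by one-way ANOVA with mouse strain as the single
factor: h2 = between / (between + within), where ``between`` is the variance
of the strain means and ``within`` is the pooled within-strain (replicate)
variance. Both components are nonnegative, so h2 always lies in [0, 1];
records where both components are zero return h2 = 0 by convention. With
the number of replicates growing, the estimate converges to
sigma_b^2 / (sigma_b^2 + sigma_e^2).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NormalizedPanel, ValidationError


@dataclass
class HeritabilityRecord:
    probe_id: str
    h2: float
    between_ms: float
    within_ms: float
    n_strains: int
    n_arrays: int


def _strain_groups(norm: NormalizedPanel):
    """Non-F1 arrays grouped by strain; errors if no strain is replicated."""
    keep = ~norm.samples["is_f1"].astype(bool)
    samples = norm.samples[keep]
    values = norm.values.loc[samples.index]
    strain = samples["strain_id"]
    counts = strain.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 strains for heritability")
    if (counts < 2).all():
        raise ValidationError("within-strain variance undefined: no strain has replicate arrays")
    return values, strain


def _components(values: pd.DataFrame, strain: pd.Series):
    """Between (variance of strain means) and within (pooled) components.

    Vectorized over probes; returns (between, within, k strains, n arrays).
    """
    grouped = values.groupby(strain, sort=True)
    means = grouped.mean()  # strains x probes
    counts = grouped.size().to_numpy()
    k = len(means)
    n = len(values)

    grand = means.mean(axis=0)
    between = ((means - grand) ** 2).sum(axis=0) / (k - 1)

    # pooled within-strain variance with sum(n_i - 1) degrees of freedom
    expanded = means.reindex(strain.to_numpy())
    expanded.index = values.index
    ss_within = ((values - expanded) ** 2).sum(axis=0)
    df_within = int((counts - 1).sum())
    within = ss_within / df_within
    return between.to_numpy(), within.to_numpy(), k, n


def anova_heritability(norm: NormalizedPanel, probe_id: str) -> HeritabilityRecord:
    """Heritability of a single probe (strain as the one ANOVA factor)."""
    if probe_id not in norm.values.columns:
        raise ValidationError(f"unknown probe {probe_id!r}")
    values, strain = _strain_groups(norm)
    b, w, k, n = _components(values[[probe_id]], strain)
    total = b[0] + w[0]
    h2 = 0.0 if total == 0 else float(b[0] / total)
    return HeritabilityRecord(probe_id, h2, float(b[0]), float(w[0]), k, n)


def heritability_table(norm: NormalizedPanel) -> pd.DataFrame:
    """Heritability of every probe, sorted by h2 descending then probe id.

    Columns: probe_id, h2, between_ms, within_ms, n_strains, n_arrays.
    """
    values, strain = _strain_groups(norm)
    if values.shape[1] == 0:
        return pd.DataFrame(
            columns=["probe_id", "h2", "between_ms", "within_ms", "n_strains", "n_arrays"]
        )
    b, w, k, n = _components(values, strain)
    total = b + w
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(total > 0, b / np.where(total > 0, total, 1.0), 0.0)
    out = pd.DataFrame(
        {
            "probe_id": values.columns,
            "h2": h2,
            "between_ms": b,
            "within_ms": w,
            "n_strains": k,
            "n_arrays": n,
        }
    )
    return out.sort_values(["h2", "probe_id"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )
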