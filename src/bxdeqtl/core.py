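"""Core data containers and error types for RI-panel expression genetics.

The containers wrap pandas objects with validated axes:

* :class:`MarkerMap` — ordered genetic/physical marker positions.
* :class:`GenotypeMatrix` — strains × markers homozygous allele codes.
* :class:`ExpressionPanel` — raw probe-set signals with sample and probe metadata.
* :class:`NormalizedPanel` — same axes after the normalization chain
  (values are dimensionless; one unit is roughly a two-fold expression change).
* :class:`StrainSummary` — one mean expression value per strain per probe,
  the substrate for mapping and correlation analysis.

Allele coding convention throughout: B (C57BL/6J-derived) = -1,
D (DBA/2J-derived) = +1, missing = NaN, so a positive additive coefficient
means the D allele increases the trait.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X",)
UNMAPPED = "unmapped"

#: allele code for the C57BL/6J-derived haplotype
B_CODE = -1.0
#: allele code for the DBA/2J-derived haplotype
D_CODE = 1.0


class PanelError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PanelError, ValueError):
    """A function argument violates its precondition."""


class ValidationError(PanelError, ValueError):
    """A data container violates one of its invariants."""


class ParseError(PanelError, ValueError):
    """An on-disk artifact could not be parsed."""


_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def chrom_sort_key(label: str) -> int:
    """Sort key placing autosomes 1..19 first, then X, then anything else."""
    return _CHROM_RANK.get(str(label), len(CHROMOSOMES))


@dataclass
class MarkerMap:
    """Ordered marker positions: one row per marker.

    ``table`` columns: ``marker_id``, ``chrom`` (label in 1..19, X),
    ``cm`` (genetic position, centimorgan), ``mb`` (physical position,
    megabase). Rows are kept sorted by chromosome then genetic position.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker_id", "chrom", "cm", "mb"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"marker map missing columns: {missing}")
        t = self.table.copy()
        t["chrom"] = t["chrom"].astype(str)
        t = t.sort_values(
            ["chrom", "cm"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        self.table = t
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValidationError(f"duplicate marker ids: {dups[:5]}")
        bad = sorted(set(t["chrom"]) - set(CHROMOSOMES))
        if bad:
            raise ValidationError(f"unknown chromosome labels in map: {bad}")
        if (t["cm"] < 0).any() or (t["mb"] < 0).any():
            raise ValidationError("marker positions must be nonnegative")
        for chrom, sub in t.groupby("chrom", sort=False):
            if not (np.diff(sub["cm"].to_numpy()) > 0).all():
                raise ValidationError(f"genetic positions not strictly increasing on chr {chrom}")
            if not (np.diff(sub["mb"].to_numpy()) > 0).all():
                raise ValidationError(f"physical positions not strictly increasing on chr {chrom}")

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        seen = self.table["chrom"].unique().tolist()
        return sorted(seen, key=chrom_sort_key)

    def chromosome_span_mb(self, chrom: str) -> float:
        sub = self.table[self.table["chrom"] == str(chrom)]
        return float(sub["mb"].max())


@dataclass
class GenotypeMatrix:
    """Homozygous allele calls for isogenic strains.

    ``calls``: DataFrame indexed by strain id, one column per marker id in map
    order; entries in {-1.0 (B), +1.0 (D), NaN (missing)}. RI strains are fully
    inbred, so only homozygous codes exist.
    """

    calls: pd.DataFrame
    map: MarkerMap

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.calls.columns) != self.map.marker_ids:
            raise ValidationError("genotype columns do not match marker map order")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == B_CODE) | (vals == D_CODE)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValidationError(f"non-homozygous or unknown genotype codes: {bad}")
        if self.calls.index.duplicated().any():
            raise ValidationError("duplicate strain ids in genotype matrix")

    @property
    def strains(self) -> list[str]:
        return self.calls.index.tolist()

    @property
    def n_strains(self) -> int:
        return len(self.calls)


def _check_sample_frame(samples: pd.DataFrame) -> None:
    required = ["strain_id", "sex", "is_f1"]
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    bad_sex = sorted(set(samples["sex"].astype(str)) - {"F", "M"})
    if bad_sex:
        raise ValidationError(f"sex labels must be F or M, got: {bad_sex}")


def _check_probe_frame(probes: pd.DataFrame) -> None:
    required = ["symbol", "chrom", "mb"]
    missing = [c for c in required if c not in probes.columns]
    if missing:
        raise ValidationError(f"probe sheet missing columns: {missing}")
    allowed = set(CHROMOSOMES) | {UNMAPPED}
    bad = sorted(set(probes["chrom"].astype(str)) - allowed)
    if bad:
        raise ValidationError(f"unknown probe chromosome labels: {bad}")


@dataclass
class ExpressionPanel:
    """Raw probe-set intensities (arrays × probes) with metadata.

    ``samples`` is indexed by array id with columns ``strain_id``, ``sex``
    (F/M) and ``is_f1``; ``probes`` is indexed by probe id with columns
    ``symbol``, ``chrom`` (map label or ``unmapped``) and ``mb``; ``signals``
    holds nonnegative raw intensities with matching axes.
    """

    samples: pd.DataFrame
    probes: pd.DataFrame
    signals: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_sample_frame(self.samples)
        _check_probe_frame(self.probes)
        no_meta = [a for a in self.signals.index if a not in self.samples.index]
        if no_meta:
            raise ValidationError(f"arrays without sample metadata: {no_meta}")
        no_anno = [p for p in self.signals.columns if p not in self.probes.index]
        if no_anno:
            raise ValidationError(f"probes without annotation: {no_anno[:5]}")
        vals = self.signals.to_numpy(dtype=float)
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative signal for array {self.signals.index[i]!r}, "
                f"probe {self.signals.columns[j]!r}"
            )

    @property
    def n_arrays(self) -> int:
        return len(self.signals)

    @property
    def n_probes(self) -> int:
        return self.signals.shape[1]


@dataclass
class NormalizedPanel:
    """Expression panel after the normalization chain (2Z+8 scale).

    Each array has mean 8 and population standard deviation 2 by construction;
    one unit corresponds to roughly a two-fold difference in expression.
    """

    samples: pd.DataFrame
    probes: pd.DataFrame
    values: pd.DataFrame

    @property
    def n_arrays(self) -> int:
        return len(self.values)

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


@dataclass
class StrainSummary:
    """Per-strain mean normalized expression (strains × probes).

    F1 arrays are excluded; ``counts`` records the number of replicate
    arrays averaged per strain. Probe annotation travels along so that
    downstream eQTL classification knows where each probe lives.
    """

    values: pd.DataFrame
    counts: pd.Series
    probes: pd.DataFrame

    @property
    def strains(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def n_strains(self) -> int:
        return len(self.values)
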