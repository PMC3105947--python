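"""Transcriptome-wide eQTL cataloguing and cis/trans classification.

Every probe passing a variance filter is scanned over the full position
grid; the peak position, LRS, LOD and additive coefficient are catalogued.
An eQTL is classified *cis* when its peak lies on the probe's own
chromosome within a 10 Mb window of the probe's annotated position
(boundary inclusive), *trans* otherwise, and *unclassified* when the probe
is unmapped. Counts of cis/trans peaks above a ladder of LRS thresholds
and cis-candidate lookup inside a phenotype QTL interval complete the
module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InvalidParameterError, StrainSummary, UNMAPPED
from .linkage import (
    LN10_2,
    MIN_STRAINS,
    PositionGrid,
    RSS_FLOOR,
    ValidationError,
    _max_lrs_many,
    _scan_core,
    hk_scan,
)

logger = logging.getLogger(__name__)

#: default cis window, megabases (peak-to-gene distance, inclusive)
CIS_WINDOW_MB = 10.0
#: LRS threshold ladder used in the cis/trans tabulation
DEFAULT_LRS_THRESHOLDS = (12.0, 16.0, 20.0, 30.0, 50.0)


@dataclass
class PeakRecord:
    """Peak linkage record for one probe."""

    probe_id: str
    symbol: str
    probe_chrom: str
    probe_mb: float
    peak_chrom: str
    peak_mb: float
    peak_cm: float
    lrs: float
    lod: float
    additive: float
    mean_expr: float
    p: float | None
    classification: str


def classify_eqtl(
    probe_chrom, probe_mb, peak_chrom, peak_mb, window_mb: float = CIS_WINDOW_MB
) -> str:
    """cis / trans / unclassified, by the same-chromosome 10 Mb rule.

    A peak is cis when it falls on the probe's chromosome within
    ``window_mb`` of the probe position, inclusive on the boundary; probes
    without a genomic annotation are unclassified.
    """
    if probe_chrom is None or str(probe_chrom) == UNMAPPED or pd.isna(probe_mb):
        return "unclassified"
    if str(probe_chrom) == str(peak_chrom) and abs(float(probe_mb) - float(peak_mb)) <= window_mb:
        return "cis"
    return "trans"


def transcriptome_scan(
    summary: StrainSummary,
    grid: PositionGrid,
    min_variance: float = 1e-8,
    n_perm: int | None = None,
    seed: int = 0,
    cis_window_mb: float = CIS_WINDOW_MB,
) -> list[PeakRecord]:
    """Scan every probe and catalogue its peak, classified cis/trans.

    Probes whose per-strain variance falls below ``min_variance`` are
    skipped (logged). Ties in the peak LRS resolve to the lowest chromosome
    then lowest position (the grid ordering). When ``n_perm`` is given, a
    per-probe genome-wide empirical p-value is computed by strain-label
    permutation. Records are returned in probe-id order.
    """
    strains = summary.values.index.tolist()
    if list(grid.strains) != strains:
        # align on the intersection, preserving grid order
        common = [s for s in grid.strains if s in set(strains)]
        if len(common) < MIN_STRAINS:
            raise ValidationError("fewer than 8 strains shared between summary and grid")
        sel = [grid.strains.index(s) for s in common]
        dosage = grid.dosage[sel]
        values = summary.values.loc[common]
    else:
        dosage = grid.dosage
        values = summary.values
    n = len(values)
    if n < MIN_STRAINS:
        raise ValidationError("need at least 8 strains")

    probe_ids = sorted(values.columns)
    y_all = values[probe_ids].to_numpy(dtype=float).T  # probes x strains
    variances = y_all.var(axis=1)
    keep = variances > min_variance
    skipped = [p for p, k in zip(probe_ids, keep) if not k]
    if skipped:
        logger.info("skipped %d constant/low-variance probes: %s ...", len(skipped), skipped[:3])

    positions = grid.positions
    records: list[PeakRecord] = []
    rng = np.random.default_rng(seed)
    complete = not np.isnan(dosage).any()

    for pi, probe in enumerate(probe_ids):
        if not keep[pi]:
            continue
        y = y_all[pi]
        if complete:
            lrs, beta, sat = _scan_core(y, dosage)
        else:
            res = hk_scan(pd.Series(y, index=values.index, name=probe), _subgrid(grid, dosage, values.index))
            lrs, beta = res.lrs, res.additive
        k = int(np.argmax(lrs))
        row = positions.iloc[k]
        anno = summary.probes.loc[probe]
        p_val = None
        if n_perm:
            perms = np.empty((n_perm, n))
            for i in range(n_perm):
                perms[i] = rng.permutation(y)
            maxima = _max_lrs_many(perms, dosage)
            p_val = float((np.sum(maxima >= lrs[k]) + 1) / (n_perm + 1))
        records.append(
            PeakRecord(
                probe_id=probe,
                symbol=str(anno["symbol"]),
                probe_chrom=str(anno["chrom"]),
                probe_mb=float(anno["mb"]) if not pd.isna(anno["mb"]) else np.nan,
                peak_chrom=str(row["chrom"]),
                peak_mb=float(row["mb"]),
                peak_cm=float(row["cm"]),
                lrs=float(lrs[k]),
                lod=float(lrs[k] / LN10_2),
                additive=float(beta[k]),
                mean_expr=float(y.mean()),
                p=p_val,
                classification=classify_eqtl(
                    anno["chrom"], anno["mb"], row["chrom"], row["mb"], cis_window_mb
                ),
            )
        )
    return records


def _subgrid(grid: PositionGrid, dosage: np.ndarray, index) -> PositionGrid:
    return PositionGrid(grid.positions, dosage, list(index))


def peaks_to_frame(records: list[PeakRecord]) -> pd.DataFrame:
    """Peak catalog as a DataFrame, one row per probe, probe-id order."""
    cols = [
        "probe_id", "symbol", "probe_chrom", "probe_mb", "peak_chrom", "peak_mb",
        "peak_cm", "lrs", "lod", "additive", "mean_expr", "p", "classification",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame([r.__dict__ for r in records])[cols]
    return out.sort_values("probe_id", kind="stable").reset_index(drop=True)


def threshold_counts(records: list[PeakRecord], thresholds=DEFAULT_LRS_THRESHOLDS) -> pd.DataFrame:
    """Numbers of cis- and trans-classified peaks at each LRS threshold.

    Counts are monotone nonincreasing in the threshold by construction.
    """
    rows = []
    for t in thresholds:
        n_cis = sum(1 for r in records if r.classification == "cis" and r.lrs >= t)
        n_trans = sum(1 for r in records if r.classification == "trans" and r.lrs >= t)
        rows.append((float(t), n_cis, n_trans))
    return pd.DataFrame(rows, columns=["threshold_lrs", "n_cis", "n_trans"])


def cis_candidates_in_interval(
    records: list[PeakRecord],
    chrom,
    start_mb: float,
    end_mb: float,
    min_lrs: float = 12.0,
) -> pd.DataFrame:
    """Candidate-gene lookup: cis-eQTLs whose gene lies in a QTL interval.

    Returns cis-classified records with probe position inside the closed
    interval [start_mb, end_mb] on ``chrom`` and peak LRS >= ``min_lrs``,
    sorted by probe position. Column layout follows the candidate tables:
    probe set, symbol, location, mean expression, max LRS.
    """
    if start_mb > end_mb:
        raise InvalidParameterError(f"malformed interval: start {start_mb} > end {end_mb}")
    rows = [
        r
        for r in records
        if r.classification == "cis"
        and str(r.probe_chrom) == str(chrom)
        and start_mb <= r.probe_mb <= end_mb
        and r.lrs >= min_lrs
    ]
    rows.sort(key=lambda r: (r.probe_mb, r.probe_id))
    return pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "symbol": r.symbol,
                "chrom": r.probe_chrom,
                "mb": r.probe_mb,
                "mean_expr": r.mean_expr,
                "max_lrs": r.lrs,
            }
            for r in rows
        ],
        columns=["probe_id", "symbol", "chrom", "mb", "mean_expr", "max_lrs"],
    )
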