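"""Haley-Knott interval mapping for recombinant-inbred panels.

The scan regresses a per-strain trait on the expected D-allele dosage at a
grid of positions (observed markers plus pseudomarkers at <= 1 cM steps over
all autosomes and X). At each position the likelihood ratio statistic is

    LRS = n * ln(RSS0 / RSS1),    LOD = LRS / (2 ln 10),

where RSS0 is the intercept-only residual sum of squares and RSS1 the
residual sum of squares of the dosage regression. The additive coefficient
is the regression slope: positive means the D (DBA/2J) allele increases the
trait.

Genome-wide significance is calibrated by permuting trait values across
strain labels (genotypes fixed) and recording the genome-wide maximum LRS
per permutation; empirical p-values use the plus-one rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GenotypeMatrix,
    InvalidParameterError,
    ValidationError,
    chrom_sort_key,
)

LN10_2 = 2.0 * np.log(10.0)
#: relative floor for RSS1 before the LRS is capped (perfect-fit saturation)
RSS_FLOOR = 1e-12
#: minimum number of strains with complete data for a scan
MIN_STRAINS = 8


def ri_recombination_fraction(distance_cm):
    """RI-scale recombination fraction between two loci ``distance_cm`` apart.

    Applies the Haldane map function r = (1 - exp(-2d/100))/2 and then the
    sib-mating RI map expansion R = 4r/(1+6r) (the probability that a fixed
    sib-mated RI line is recombinant between the two loci). Accepts scalars
    or arrays; returns values in [0, 0.5].
    """
    d = np.asarray(distance_cm, dtype=float)
    if (d < 0).any():
        raise InvalidParameterError("genetic distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    big_r = 4.0 * r / (1.0 + 6.0 * r)
    return big_r if big_r.ndim else float(big_r)


def lrs_lod_convert(value, direction: str = "to_lod"):
    """Convert between LRS and LOD: LOD = LRS / (2 ln 10).

    ``direction`` is ``"to_lod"`` or ``"to_lrs"``.
    """
    v = np.asarray(value, dtype=float)
    if (v < 0).any():
        raise InvalidParameterError("LRS/LOD values must be nonnegative")
    if direction == "to_lod":
        out = v / LN10_2
    elif direction == "to_lrs":
        out = v * LN10_2
    else:
        raise InvalidParameterError(f"unknown direction {direction!r}")
    return out if out.ndim else float(out)


@dataclass
class PositionGrid:
    """Scan positions with per-strain expected D-allele dosage.

    ``positions`` has one row per evaluated position (columns ``chrom``,
    ``cm``, ``mb``, ``left_marker``, ``right_marker``, ``is_marker``),
    ordered by chromosome then genetic position. ``dosage`` is a
    strains × positions array of expected dosages in [-1, 1]; at an observed
    non-missing marker the dosage equals the observed code.
    """

    positions: pd.DataFrame
    dosage: np.ndarray
    strains: list[str]

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def expected_dosage(genotypes: GenotypeMatrix, step_cm: float = 1.0) -> PositionGrid:
    """Build the scan grid and expected dosages from observed genotypes.

    Pseudomarkers are placed every ``step_cm`` between the first and last
    marker of each chromosome; observed marker positions are always included.
    The expected dosage at a pseudomarker is P(D | flanks) - P(B | flanks)
    under the RI Markov model, conditioning on the nearest non-missing
    marker on each side (single-flank conditioning at chromosome ends).
    Physical positions are linear cM->Mb interpolations between markers.
    Chromosomes outside the autosome/X label set are skipped with a warning.
    """
    if step_cm <= 0:
        raise InvalidParameterError("grid step must be positive")
    mm = genotypes.map
    strains = genotypes.strains
    n_s = len(strains)

    pos_frames = []
    dosage_blocks = []
    for chrom, sub in mm.table.groupby("chrom", sort=False):
        mcm = sub["cm"].to_numpy()
        mmb = sub["mb"].to_numpy()
        mids = sub["marker_id"].tolist()
        if len(mids) == 0:
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        grid_cm = np.unique(
            np.concatenate(
                [mcm, np.arange(mcm[0], mcm[-1], step_cm), [mcm[-1]]]
            )
        )
        grid_mb = np.interp(grid_cm, mcm, mmb)

        # flanking observed markers by position (for bookkeeping columns)
        right_idx = np.searchsorted(mcm, grid_cm, side="left")
        left_idx = np.searchsorted(mcm, grid_cm, side="right") - 1
        is_marker = np.isin(grid_cm, mcm)
        left_ids = [mids[max(i, 0)] for i in left_idx]
        right_ids = [mids[min(i, len(mids) - 1)] for i in right_idx]

        calls = genotypes.calls[mids].to_numpy(dtype=float)  # strains x markers
        block = np.empty((n_s, len(grid_cm)))
        for s in range(n_s):
            block[s] = _strain_dosage(calls[s], mcm, grid_cm)
        dosage_blocks.append(block)
        pos_frames.append(
            pd.DataFrame(
                {
                    "chrom": str(chrom),
                    "cm": grid_cm,
                    "mb": grid_mb,
                    "left_marker": left_ids,
                    "right_marker": right_ids,
                    "is_marker": is_marker,
                }
            )
        )
    if not pos_frames:
        raise ValidationError("no mappable chromosomes in marker map")
    order = sorted(range(len(pos_frames)), key=lambda k: chrom_sort_key(pos_frames[k]["chrom"].iloc[0]))
    positions = pd.concat([pos_frames[k] for k in order], ignore_index=True)
    dosage = np.hstack([dosage_blocks[k] for k in order])
    return PositionGrid(positions, dosage, strains)


def _strain_dosage(g: np.ndarray, mcm: np.ndarray, grid_cm: np.ndarray) -> np.ndarray:
    """Expected dosage for one strain at all grid positions of one chromosome."""
    informative = ~np.isnan(g)
    if not informative.any():
        return np.full(len(grid_cm), np.nan)
    pi = mcm[informative]
    gi = g[informative]

    right = np.searchsorted(pi, grid_cm, side="left")
    left = np.searchsorted(pi, grid_cm, side="right") - 1
    li = np.clip(left, 0, len(pi) - 1)
    ri = np.clip(right, 0, len(pi) - 1)
    rl = ri_recombination_fraction(np.maximum(grid_cm - pi[li], 0.0))
    rr = ri_recombination_fraction(np.maximum(pi[ri] - grid_cm, 0.0))
    gl, gr = gi[li], gi[ri]

    # transition products for the hidden state at the pseudomarker
    t_ld = np.where(gl > 0, 1 - rl, rl)   # P(x=D | left)
    t_lb = 1.0 - t_ld
    t_rd = np.where(gr > 0, 1 - rr, rr)   # P(right | x=D)
    t_rb = 1.0 - t_rd
    p_d = t_ld * t_rd
    p_b = t_lb * t_rb
    dos = (p_d - p_b) / (p_d + p_b)

    # chromosome ends: condition on the single available flank
    only_left = right >= len(pi)
    only_right = left < 0
    dos = np.where(only_left, gl * (1 - 2 * rl), dos)
    dos = np.where(only_right, gr * (1 - 2 * rr), dos)

    # exact marker positions take the observed code
    at_marker = np.isclose(grid_cm[:, None], pi[None, :], atol=1e-9).any(axis=1)
    exact = np.isclose(grid_cm[:, None], pi[None, :], atol=1e-9).argmax(axis=1)
    dos = np.where(at_marker, gi[exact], dos)
    return dos


@dataclass
class ScanResult:
    """Genome scan for one trait: per-position LRS and additive coefficient."""

    trait_id: str
    grid: PositionGrid
    lrs: np.ndarray
    additive: np.ndarray
    saturated: np.ndarray
    n_strains: int

    def peak(self) -> pd.Series:
        """Peak position (ties broken by lowest chromosome, then position)."""
        k = int(np.argmax(self.lrs))
        row = self.grid.positions.iloc[k]
        return pd.Series(
            {
                "chrom": row["chrom"],
                "cm": row["cm"],
                "mb": row["mb"],
                "lrs": float(self.lrs[k]),
                "lod": float(self.lrs[k] / LN10_2),
                "additive": float(self.additive[k]),
                "saturated": bool(self.saturated[k]),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.positions[["chrom", "cm", "mb"]].copy()
        out.insert(0, "trait_id", self.trait_id)
        out["lrs"] = self.lrs
        out["additive"] = self.additive
        return out


def _scan_core(y: np.ndarray, dosage: np.ndarray):
    """Vectorized complete-data HK regression of one trait on all positions.

    Returns (lrs, additive, saturated) arrays over positions.
    """
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)
    dc = dosage - dosage.mean(axis=0)
    sdd = np.einsum("ij,ij->j", dc, dc)
    sdy = yc @ dc
    ok = sdd > 0
    beta = np.zeros(dosage.shape[1])
    beta[ok] = sdy[ok] / sdd[ok]
    rss1 = np.full(dosage.shape[1], syy)
    rss1[ok] = syy - sdy[ok] ** 2 / sdd[ok]
    floor = RSS_FLOOR * syy
    saturated = rss1 < floor
    rss1 = np.maximum(rss1, floor)
    lrs = n * np.log(syy / rss1)
    lrs[~ok] = 0.0
    return lrs, beta, saturated


def hk_scan(trait: pd.Series, grid: PositionGrid, trait_id: str | None = None) -> ScanResult:
    """Haley-Knott genome scan of one per-strain trait.

    ``trait`` is indexed by strain id; strains missing from the grid are
    ignored and strains with missing trait values are dropped. Positions
    with missing dosage drop those strains pairwise. Requires >= 8 strains
    with data and a non-constant trait.
    """
    trait_id = trait_id or str(trait.name or "trait")
    y_full = trait.reindex(grid.strains).to_numpy(dtype=float)
    keep = ~np.isnan(y_full)
    y = y_full[keep]
    dosage = grid.dosage[keep]
    if len(y) < MIN_STRAINS:
        raise ValidationError(f"fewer than {MIN_STRAINS} strains with trait data")
    if np.var(y) == 0:
        raise ValidationError(f"constant trait {trait_id!r}")

    if not np.isnan(dosage).any():
        lrs, beta, sat = _scan_core(y, dosage)
    else:
        g = dosage.shape[1]
        lrs = np.zeros(g)
        beta = np.zeros(g)
        sat = np.zeros(g, dtype=bool)
        complete = ~np.isnan(dosage).any(axis=0)
        if complete.any():
            lrs[complete], beta[complete], sat[complete] = _scan_core(y, dosage[:, complete])
        for j in np.flatnonzero(~complete):
            m = ~np.isnan(dosage[:, j])
            if m.sum() < MIN_STRAINS or np.var(y[m]) == 0:
                continue
            lj, bj, sj = _scan_core(y[m], dosage[m, j][:, None])
            lrs[j], beta[j], sat[j] = lj[0], bj[0], sj[0]
    return ScanResult(trait_id, grid, lrs, beta, sat, int(len(y)))


@dataclass
class NullDistribution:
    """Permutation sample of genome-wide maximum LRS for one trait."""

    n_perm: int
    max_lrs: np.ndarray
    seed: int

    def threshold(self, alpha: float = 0.05) -> float:
        """Genome-wide LRS threshold at nominal level ``alpha``."""
        if not 0 < alpha < 1:
            raise InvalidParameterError("alpha must be in (0,1)")
        return float(np.quantile(self.max_lrs, 1.0 - alpha))


def permutation_null(
    trait: pd.Series, grid: PositionGrid, n_perm: int, seed: int = 0
) -> NullDistribution:
    """Permutation null of the genome-wide max LRS (strain labels shuffled).

    Trait values are permuted over strain labels without replacement while
    dosages stay fixed; a full-genome scan is run per permutation and the
    genome-wide maximum recorded. Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise InvalidParameterError("need at least 100 permutations")
    y_full = trait.reindex(grid.strains).to_numpy(dtype=float)
    keep = ~np.isnan(y_full)
    y = y_full[keep]
    dosage = grid.dosage[keep]
    if len(y) < MIN_STRAINS:
        raise ValidationError(f"fewer than {MIN_STRAINS} strains with trait data")
    if np.var(y) == 0:
        raise ValidationError("constant trait")

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, len(y)))
    for i in range(n_perm):
        perms[i] = rng.permutation(y)

    if not np.isnan(dosage).any():
        maxima = _max_lrs_many(perms, dosage)
    else:
        maxima = np.empty(n_perm)
        for i in range(n_perm):
            res = hk_scan(pd.Series(perms[i], index=np.array(grid.strains)[keep]), grid)
            maxima[i] = res.lrs.max()
    return NullDistribution(n_perm, maxima, seed)


def _max_lrs_many(traits: np.ndarray, dosage: np.ndarray, chunk_elems: int = 20_000_000):
    """Genome-wide max LRS for many traits at once (complete data).

    ``traits`` is (T x strains); returns length-T maxima. Chunked so the
    intermediate correlation matrix stays within a modest memory budget.
    """
    n = dosage.shape[0]
    dc = dosage - dosage.mean(axis=0)
    sdd = np.einsum("ij,ij->j", dc, dc)
    ok = sdd > 0
    dc = dc[:, ok]
    sdd = sdd[ok]
    yc = traits - traits.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)

    t = traits.shape[0]
    g = dc.shape[1]
    out = np.empty(t)
    rows = max(1, chunk_elems // max(g, 1))
    for s in range(0, t, rows):
        e = min(s + rows, t)
        sdy = yc[s:e] @ dc  # (rows x g)
        r2 = sdy**2 / (syy[s:e, None] * sdd[None, :])
        r2 = np.minimum(r2, 1.0 - RSS_FLOOR)
        out[s:e] = (-n * np.log1p(-r2)).max(axis=1)
    return out


def empirical_p(observed_max: float, null: NullDistribution) -> float:
    """Genome-wide empirical p-value with the plus-one rule.

    p = (#{null maxima >= observed} + 1) / (n_perm + 1), so p is never zero;
    the smallest attainable value is 1/(n_perm + 1).
    """
    if null.n_perm == 0 or len(null.max_lrs) == 0:
        raise InvalidParameterError("empty null distribution")
    return float((np.sum(null.max_lrs >= observed_max) + 1) / (null.n_perm + 1))
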