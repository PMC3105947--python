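"""Synthetic BXD-like recombinant-inbred panels with planted ground truth.

Genotypes are simulated as fixed homozygous B/D mosaics: along each
chromosome the allele sequence is a two-state Markov chain whose
adjacent-marker transition probability is the sib-mating RI-scale
recombination fraction R = 4r/(1+6r), with r obtained from the Haldane map
function of the inter-marker distance. Residual heterozygosity is ignored
(RI strains are homozygous at almost every locus).

Expression is generated on the log2 scale and exponentiated so the raw
signals have realistic multiplicative skew:

    log2 signal = baseline(probe)
                + a * genotype(strain, locus)          cis/trans/Mendelian effects
                + loading * driver(module, strain)     latent cell-proportion modules
                + sex_effect * [strain is female]      Xist-like probes
                + strain effect (shared by replicates) heritable noise
                + array noise                          replicate noise

Every planted structure is recorded in a :class:`TruthTable` so downstream
recovery can be tested without external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    CHROMOSOMES,
    UNMAPPED,
    B_CODE,
    D_CODE,
    ExpressionPanel,
    GenotypeMatrix,
    InvalidParameterError,
    MarkerMap,
)
from .linkage import ri_recombination_fraction


@dataclass
class TruthTable:
    """Planted simulation structure, keyed by probe id.

    ``cis_effects``/``trans_effects``: (probe_id, marker_id, additive effect
    size in normalized ≈ log2 units). ``module_members`` maps module id to its
    probe ids; ``module_driver`` holds the latent per-strain factor values.
    ``h2_targets`` records the intended heritability fraction per probe.
    """

    cis_effects: list[tuple[str, str, float]] = field(default_factory=list)
    trans_effects: list[tuple[str, str, float]] = field(default_factory=list)
    module_members: dict[str, list[str]] = field(default_factory=dict)
    module_driver: pd.DataFrame | None = None
    sex_probes: list[str] = field(default_factory=list)
    mendelian_probes: list[str] = field(default_factory=list)
    h2_targets: dict[str, float] = field(default_factory=dict)

    def effect_locus(self, probe_id: str) -> str | None:
        for pid, mid, _ in self.cis_effects + self.trans_effects:
            if pid == probe_id:
                return mid
        return None


@dataclass
class SimulationConfig:
    """Settings for :func:`simulate_expression_panel`.

    Defaults emulate the statistical structure of a BXD lung expression
    study at desk scale: a mix of strong cis effects, weaker trans effects,
    two latent immune-cell-proportion modules, a handful of sex-specific
    (Xist-like) and Mendelian bimodal probes, and background probes whose
    heritability spans nearly the full (0, 1) range.
    """

    n_probes: int = 1000
    replicates: int = 2
    n_cis: int = 30
    cis_effect_size: float = 1.5
    n_trans: int = 30
    trans_effect_size: float = 0.8
    n_modules: int = 2
    module_size: int = 20
    module_driver_share: float = 0.90  # latent driver's share of a member's total SD
    module_strain_sd: float = 0.3
    module_noise_sd: float = 0.6
    n_sex_probes: int = 5
    sex_effect: float = 4.0  # log2 units added in females (Xist-like)
    n_mendelian: int = 5
    mendelian_effect: float = 3.0
    mendelian_noise_sd: float = 0.15
    noise_sd: float = 0.5  # per-array residual SD, log2 units
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    h2_range: tuple[float, float] = (0.05, 0.95)
    unmapped_fraction: float = 0.02
    include_f1: bool = False

    def n_structured(self) -> int:
        return (
            self.n_mendelian
            + self.n_cis
            + self.n_trans
            + self.n_sex_probes
            + self.n_modules * self.module_size
        )

    def validate(self) -> None:
        if self.n_probes < self.n_structured():
            raise InvalidParameterError(
                f"n_probes={self.n_probes} smaller than planted structure "
                f"({self.n_structured()} probes)"
            )
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        if not 0 < self.module_driver_share < 1:
            raise InvalidParameterError("module_driver_share must be in (0,1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")


def make_marker_map(
    n_chromosomes: int,
    chrom_length_cm: float,
    marker_spacing_cm: float,
    mb_per_cm: float = 2.0,
    seed: int = 0,
    jitter: float = 0.2,
) -> MarkerMap:
    """Build an evenly spaced marker map with optional position jitter.

    One chromosome is labelled X when ``n_chromosomes`` >= 2 (the rest are
    autosomes 1, 2, ...). Physical positions are tied linearly to genetic
    positions (``mb = cm * mb_per_cm``); the default of 2 Mb per cM matches
    the mouse genome-wide average. ``jitter`` is the fraction of the spacing used as uniform
    positional noise for interior markers (0 gives an exact grid).

    Raises
    ------
    InvalidParameterError
        If spacing or lengths are not positive, or jitter >= 0.5.
    """
    if marker_spacing_cm <= 0:
        raise InvalidParameterError("marker spacing must be positive")
    if chrom_length_cm <= 0:
        raise InvalidParameterError("chromosome length must be positive")
    if n_chromosomes < 1:
        raise InvalidParameterError("need at least one chromosome")
    if n_chromosomes > len(CHROMOSOMES):
        raise InvalidParameterError(f"at most {len(CHROMOSOMES)} chromosomes supported")
    if not 0 <= jitter < 0.5:
        raise InvalidParameterError("jitter must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    if n_chromosomes == 1:
        labels = ["1"]
    else:
        labels = [str(i) for i in range(1, n_chromosomes)] + ["X"]

    rows = []
    for chrom in labels:
        base = np.arange(0.0, chrom_length_cm + 1e-9, marker_spacing_cm)
        cm = base.copy()
        if jitter > 0 and len(base) > 2:
            cm[1:-1] += rng.uniform(-jitter, jitter, size=len(base) - 2) * marker_spacing_cm
        for i, pos in enumerate(cm):
            rows.append((f"m{chrom}_{i:04d}", chrom, float(pos), float(pos * mb_per_cm)))
    table = pd.DataFrame(rows, columns=["marker_id", "chrom", "cm", "mb"])
    return MarkerMap(table)


def simulate_ri_genotypes(marker_map: MarkerMap, n_strains: int, seed: int = 0) -> GenotypeMatrix:
    """Simulate fixed RI strains as Markov B/D mosaics along each chromosome.

    The first marker of each chromosome is B or D with probability 1/2; the
    allele then switches between adjacent markers with probability
    R = 4r/(1+6r) (sib-mating RI map expansion of the Haldane meiotic
    fraction r). Marginal allele frequency is 1/2 at every marker, and the
    adjacent-marker discordance frequency matches R in expectation.
    """
    if marker_map.n_markers == 0:
        raise InvalidParameterError("marker map is empty")
    if n_strains < 2:
        raise InvalidParameterError("need at least 2 strains")

    rng = np.random.default_rng(seed)
    strains = [f"RIS{i + 1:03d}" for i in range(n_strains)]
    cols: dict[str, np.ndarray] = {}
    for chrom, sub in marker_map.table.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy()
        ids = sub["marker_id"].tolist()
        g = np.empty((n_strains, len(ids)))
        g[:, 0] = rng.choice([B_CODE, D_CODE], size=n_strains)
        rr = ri_recombination_fraction(np.diff(cm))
        for j in range(1, len(ids)):
            flip = rng.random(n_strains) < rr[j - 1]
            g[:, j] = np.where(flip, -g[:, j - 1], g[:, j - 1])
        for j, mid in enumerate(ids):
            cols[mid] = g[:, j]
    calls = pd.DataFrame(cols, index=strains)[marker_map.marker_ids]
    return GenotypeMatrix(calls, marker_map)


def _place_probes_uniform(rng, marker_map: MarkerMap, n: int):
    """Random probe locations proportional to chromosome physical length."""
    chroms = marker_map.chromosomes
    spans = np.array([marker_map.chromosome_span_mb(c) for c in chroms])
    probs = spans / spans.sum()
    picks = rng.choice(len(chroms), size=n, p=probs)
    mbs = rng.uniform(0, spans[picks])
    return [chroms[k] for k in picks], mbs


def _h2_to_strain_sd(h2: float, noise_sd: float) -> float:
    """Strain-effect SD giving heritability h2 against the given array noise."""
    if h2 >= 1:
        raise InvalidParameterError("h2 target must be < 1")
    return noise_sd * np.sqrt(h2 / (1.0 - h2))


def simulate_expression_panel(
    genotypes: GenotypeMatrix,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[ExpressionPanel, TruthTable]:
    """Generate a raw expression panel with planted, recorded structure.

    Probe categories are assigned in order: Mendelian, cis, trans,
    sex-specific, module members, background. Cis (and Mendelian) probes are
    annotated within 2 Mb of their effect marker; trans loci are drawn on a
    different chromosome from the probe. Replicate arrays share the strain
    effect, so the intended heritability is achieved in expectation.
    """
    config = config or SimulationConfig()
    config.validate()
    if genotypes.n_strains == 0:
        raise InvalidParameterError("genotype matrix has no strains")

    rng = np.random.default_rng(seed)
    mm = genotypes.map
    strains = genotypes.strains
    n_s = len(strains)
    n_p = config.n_probes
    truth = TruthTable()

    probe_ids = [f"p{str(i + 1).zfill(5)}_at" for i in range(n_p)]
    chrom_anno = [UNMAPPED] * n_p
    mb_anno = np.zeros(n_p)
    symbols = [f"Gene{i + 1}" for i in range(n_p)]

    # per-probe model pieces
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_p)
    h2_target = rng.uniform(*config.h2_range, size=n_p)
    noise_sd = np.full(n_p, config.noise_sd)
    strain_sd = np.array([_h2_to_strain_sd(h, config.noise_sd) for h in h2_target])
    effect_size = np.zeros(n_p)
    effect_marker: list[str | None] = [None] * n_p
    loading = np.zeros(n_p)
    module_of = np.full(n_p, -1)
    sex_fx = np.zeros(n_p)

    map_t = mm.table
    idx = 0

    def _pick_marker() -> int:
        return int(rng.integers(0, len(map_t)))

    def _cis_place(i: int, size: float, max_offset_mb: float = 2.0) -> None:
        k = _pick_marker()
        row = map_t.iloc[k]
        span = mm.chromosome_span_mb(row["chrom"])
        chrom_anno[i] = str(row["chrom"])
        offset = rng.uniform(-max_offset_mb, max_offset_mb)
        mb_anno[i] = float(np.clip(row["mb"] + offset, 0, span))
        effect_marker[i] = row["marker_id"]
        effect_size[i] = size

    # Mendelian bimodal probes: extreme cis effects, near-zero noise. They sit
    # essentially on top of their cognate locus so the nearest marker carries
    # the driving genotype (these probes double as strain-identity controls).
    for _ in range(config.n_mendelian):
        _cis_place(idx, config.mendelian_effect, max_offset_mb=0.2)
        strain_sd[idx] = 0.0
        noise_sd[idx] = config.mendelian_noise_sd
        truth.mendelian_probes.append(probe_ids[idx])
        truth.cis_effects.append((probe_ids[idx], effect_marker[idx], float(effect_size[idx])))
        idx += 1

    # cis effects
    for _ in range(config.n_cis):
        _cis_place(idx, config.cis_effect_size)
        truth.cis_effects.append((probe_ids[idx], effect_marker[idx], float(effect_size[idx])))
        idx += 1

    # trans effects: probe annotated away from its locus (different chromosome)
    for _ in range(config.n_trans):
        k = _pick_marker()
        row = map_t.iloc[k]
        other = [c for c in mm.chromosomes if c != row["chrom"]]
        chrom = other[int(rng.integers(0, len(other)))] if other else str(row["chrom"])
        span = mm.chromosome_span_mb(chrom)
        chrom_anno[idx] = chrom
        mb_anno[idx] = float(rng.uniform(0, span))
        effect_marker[idx] = row["marker_id"]
        effect_size[idx] = config.trans_effect_size
        truth.trans_effects.append((probe_ids[idx], row["marker_id"], float(effect_size[idx])))
        idx += 1

    # sex-specific probes (female-high, Xist-like): the sex effect dominates,
    # residual strain variation is minor
    sex_chroms, sex_mbs = _place_probes_uniform(rng, mm, config.n_sex_probes)
    for j in range(config.n_sex_probes):
        chrom_anno[idx] = sex_chroms[j]
        mb_anno[idx] = sex_mbs[j]
        sex_fx[idx] = config.sex_effect
        strain_sd[idx] = 0.3
        truth.sex_probes.append(probe_ids[idx])
        idx += 1

    # correlated modules sharing a latent per-strain driver
    s = config.module_driver_share
    lam = (s / np.sqrt(1 - s**2)) * np.sqrt(
        config.module_strain_sd**2 + config.module_noise_sd**2
    )
    drivers = rng.normal(size=(n_s, config.n_modules))
    for m in range(config.n_modules):
        members = []
        for _ in range(config.module_size):
            c, mb = _place_probes_uniform(rng, mm, 1)
            chrom_anno[idx] = c[0]
            mb_anno[idx] = float(mb[0])
            loading[idx] = lam
            module_of[idx] = m
            strain_sd[idx] = config.module_strain_sd
            noise_sd[idx] = config.module_noise_sd
            members.append(probe_ids[idx])
            idx += 1
        truth.module_members[f"module{m + 1}"] = members
    truth.module_driver = pd.DataFrame(
        drivers, index=strains, columns=[f"module{m + 1}" for m in range(config.n_modules)]
    )

    # background probes; a fraction is left unannotated
    n_bg = n_p - idx
    bg_chroms, bg_mbs = _place_probes_uniform(rng, mm, n_bg)
    unmapped = rng.random(n_bg) < config.unmapped_fraction
    for j in range(n_bg):
        if not unmapped[j]:
            chrom_anno[idx] = bg_chroms[j]
            mb_anno[idx] = float(bg_mbs[j])
        else:
            mb_anno[idx] = np.nan
        idx += 1

    # strain-level pieces
    strain_sex = pd.Series(rng.choice(["F", "M"], size=n_s), index=strains)
    dosage = np.zeros((n_s, n_p))
    for i, mid in enumerate(effect_marker):
        if mid is not None:
            dosage[:, i] = genotypes.calls[mid].to_numpy()

    strain_effect = rng.normal(size=(n_s, n_p)) * strain_sd[None, :]
    driver_part = np.zeros((n_s, n_p))
    for i in range(n_p):
        if module_of[i] >= 0:
            driver_part[:, i] = loading[i] * drivers[:, module_of[i]]
    female = (strain_sex == "F").to_numpy().astype(float)

    strain_level = (
        baseline[None, :]
        + effect_size[None, :] * dosage
        + driver_part
        + sex_fx[None, :] * female[:, None]
        + strain_effect
    )

    # intended heritability: between-strain variance over total
    vg = np.nanvar(dosage, axis=0)
    between = effect_size**2 * vg + loading**2 + strain_sd**2 + sex_fx**2 * 0.25
    truth.h2_targets = {
        probe_ids[i]: float(between[i] / (between[i] + noise_sd[i] ** 2))
        if between[i] + noise_sd[i] ** 2 > 0
        else 0.0
        for i in range(n_p)
    }

    # replicate arrays
    sample_rows = []
    log2_rows = []
    for si, strain in enumerate(strains):
        for r in range(config.replicates):
            sample_rows.append((f"{strain}_r{r + 1}", strain, strain_sex[strain], False))
            log2_rows.append(strain_level[si] + rng.normal(size=n_p) * noise_sd)

    if config.include_f1:
        # reciprocal F1 hybrids: heterozygous everywhere (dosage 0), no driver
        for f1, sex in (("B6D2F1", "F"), ("D2B6F1", "M")):
            base_f1 = baseline + sex_fx * (1.0 if sex == "F" else 0.0)
            lvl = base_f1 + rng.normal(size=n_p) * strain_sd
            for r in range(config.replicates):
                sample_rows.append((f"{f1}_r{r + 1}", f1, sex, True))
                log2_rows.append(lvl + rng.normal(size=n_p) * noise_sd)

    samples = pd.DataFrame(
        sample_rows, columns=["array_id", "strain_id", "sex", "is_f1"]
    ).set_index("array_id")
    probes = pd.DataFrame(
        {"symbol": symbols, "chrom": chrom_anno, "mb": mb_anno},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    signals = pd.DataFrame(
        np.exp2(np.vstack(log2_rows)), index=samples.index, columns=probes.index
    )

    panel = ExpressionPanel(samples, probes, signals)
    _check_truth(truth, panel, mm)
    return panel, truth


def _check_truth(truth: TruthTable, panel: ExpressionPanel, mm: MarkerMap) -> None:
    """Enforce TruthTable invariants (cis loci within 10 Mb, trans outside)."""
    pos = mm.table.set_index("marker_id")
    for pid, mid, _ in truth.cis_effects:
        p = panel.probes.loc[pid]
        m = pos.loc[mid]
        if str(p["chrom"]) != str(m["chrom"]) or abs(p["mb"] - m["mb"]) > 10:
            raise ValueError(f"planted cis effect for {pid} not within 10 Mb of {mid}")
    for pid, mid, _ in truth.trans_effects:
        p = panel.probes.loc[pid]
        m = pos.loc[mid]
        if str(p["chrom"]) == str(m["chrom"]) and abs(p["mb"] - m["mb"]) <= 10:
            raise ValueError(f"planted trans effect for {pid} lies within 10 Mb of {mid}")
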