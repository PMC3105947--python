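"""End-to-end orchestration: simulate a dataset, or run the full analysis.

``run_pipeline`` executes read -> normalize -> QC -> strain summary ->
heritability -> dosage grid -> transcriptome scan -> cis/trans counts ->
correlation network (-> optional seeded signature) and writes every table
plus a run manifest into one output directory. A rerun with the same config
is byte-identical: the manifest records the config hash, seed and package
version, never wall-clock time, and every table carries the manifest hash
in a header comment.

The master seed fans out to independent per-stage child seeds through
``numpy.random.SeedSequence`` so any stage can be re-run in isolation.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as fio
from .coexpression import correlation_pairs, pc_signature
from .core import ValidationError
from .eqtl import peaks_to_frame, threshold_counts, transcriptome_scan
from .heritability import heritability_table
from .linkage import expected_dosage, permutation_null
from .preprocess import fold_range_histogram, normalize_panel, run_qc, summarize_by_strain
from .simulate import SimulationConfig, make_marker_map, simulate_expression_panel, simulate_ri_genotypes

logger = logging.getLogger(__name__)

def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the master seed.

    Stage names are hashed stably (sha256), so the fan-out does not depend
    on the process hash seed and any stage can be re-run independently.
    """
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SimulateSettings:
    """Scale and structure of a simulated dataset (defaults: BXD-like panel).

    57 strains, 19 autosomes plus X of ~80 cM each at 0.42 cM marker spacing
    (~3,820 markers) and 2 Mb per cM; expression settings come from
    :class:`SimulationConfig`.
    """

    n_strains: int = 57
    n_chromosomes: int = 20
    chrom_length_cm: float = 80.0
    marker_spacing_cm: float = 0.42
    mb_per_cm: float = 2.0
    seed: int = 0
    expression: SimulationConfig = field(default_factory=SimulationConfig)


def run_simulate(settings: SimulateSettings, out_dir) -> dict:
    """Write a complete synthetic dataset (four TSV dialects + truth + config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mm = make_marker_map(
        settings.n_chromosomes,
        settings.chrom_length_cm,
        settings.marker_spacing_cm,
        settings.mb_per_cm,
        seed=stage_seed(settings.seed, "simulate_geno"),
    )
    genotypes = simulate_ri_genotypes(mm, settings.n_strains, seed=stage_seed(settings.seed, "simulate_geno"))
    panel, truth = simulate_expression_panel(
        genotypes, settings.expression, seed=stage_seed(settings.seed, "simulate_expr")
    )
    fio.write_genotypes(genotypes, out / "genotypes.tsv")
    fio.write_expression(panel, out / "signals.tsv", out / "samples.tsv", out / "probes.tsv")
    fio.write_truth(truth, out / "truth.json")
    cfg = asdict(settings)
    fio.write_config(cfg, out / "simulation_config.yaml")
    logger.info(
        "simulated %d strains x %d markers, %d arrays x %d probes -> %s",
        genotypes.n_strains, mm.n_markers, panel.n_arrays, panel.n_probes, out,
    )
    return {
        "n_strains": genotypes.n_strains,
        "n_markers": mm.n_markers,
        "n_arrays": panel.n_arrays,
        "n_probes": panel.n_probes,
        "out_dir": str(out),
    }


@dataclass
class PipelineConfig:
    """Everything the full analysis needs; ``seed`` drives every stochastic stage."""

    genotypes: str = ""
    signals: str = ""
    samples: str = ""
    probes: str = ""
    out_dir: str = "results"
    seed: int = 0
    step_cm: float = 1.0
    n_perm: int = 1000
    per_probe_p: bool = False
    per_probe_n_perm: int = 100
    lrs_thresholds: tuple[float, ...] = (12.0, 16.0, 20.0, 30.0, 50.0)
    cis_window_mb: float = 10.0
    correlation_threshold: float = 0.8
    correlation_method: str = "pearson"
    min_variance: float = 1e-8
    pair_min_variance: float = 0.0
    female_marker_probes: tuple[str, ...] = ()
    male_marker_probes: tuple[str, ...] = ()
    mendelian_probes: tuple[str, ...] = ()
    signature_seeds: tuple[str, ...] = ()
    strict_qc: bool = False

    def validate(self) -> None:
        if self.step_cm <= 0 or self.cis_window_mb <= 0:
            raise ValidationError("step_cm and cis_window_mb must be positive")
        if any(t <= 0 for t in self.lrs_thresholds):
            raise ValidationError("LRS thresholds must be positive")

    def hash(self) -> str:
        """Hash of the analysis-relevant config (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mh = config.hash()
    comments = (f"manifest: {mh}",)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": mh,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    t0 = time.perf_counter()

    try:
        genotypes = fio.read_genotypes(config.genotypes)
        panel = fio.read_expression(config.signals, config.samples, config.probes)
    except Exception as err:  # abort with a stage-named message
        raise RuntimeError(f"stage read: {err}") from err
    unknown = set(panel.samples.loc[~panel.samples["is_f1"], "strain_id"]) - set(genotypes.strains)
    if unknown:
        warnings.warn(f"expression strains without genotypes (excluded from mapping): {sorted(unknown)[:5]}")
    t0 = _stage("read", t0)

    norm = normalize_panel(panel)
    manifest["stages"]["normalize"] = {"arrays": norm.n_arrays, "probes": norm.n_probes}
    t0 = _stage("normalize", t0)

    qc = run_qc(
        norm,
        genotypes,
        female_marker_probes=list(config.female_marker_probes),
        male_marker_probes=list(config.male_marker_probes),
        mendelian_probes=list(config.mendelian_probes),
    )
    flagged = qc.flagged_arrays
    if flagged:
        msg = f"QC flagged arrays: {flagged}"
        if config.strict_qc:
            raise RuntimeError(f"stage qc: {msg}")
        warnings.warn(msg)
    qc_frame = qc.to_frame()
    if len(qc_frame):
        fio.write_table(qc_frame, out / "qc_report.tsv", comments)
    manifest["stages"]["qc"] = {"flagged": flagged}
    t0 = _stage("qc", t0)

    summary = summarize_by_strain(norm)
    mappable = [s for s in summary.strains if s in set(genotypes.strains)]
    summary.values = summary.values.loc[mappable]
    fio.write_table(fold_range_histogram(summary), out / "fold_range_histogram.tsv", comments)
    manifest["stages"]["summary"] = {"strains": summary.n_strains}
    t0 = _stage("summary", t0)

    counts = norm.samples.loc[~norm.samples["is_f1"], "strain_id"].value_counts()
    if (counts >= 2).any() and len(counts) >= 2:
        herit = heritability_table(norm)
        fio.write_table(herit, out / "heritability.tsv", comments)
        manifest["stages"]["heritability"] = {"probes": len(herit)}
    else:
        warnings.warn("no replicate arrays; heritability skipped")
        manifest["stages"]["heritability"] = {"probes": 0}
    t0 = _stage("heritability", t0)

    grid = expected_dosage(genotypes, step_cm=config.step_cm)
    manifest["stages"]["grid"] = {"positions": grid.n_positions}
    t0 = _stage("grid", t0)

    if config.n_perm >= 100:
        rng = np.random.default_rng(stage_seed(config.seed, "threshold"))
        null_trait = pd.Series(rng.normal(size=len(mappable)), index=mappable)
        null = permutation_null(null_trait, grid, config.n_perm, seed=stage_seed(config.seed, "threshold"))
        thr = {f"lrs_{int(a * 100):02d}": null.threshold(a) for a in (0.05, 0.63)}
        fio.write_table(
            pd.DataFrame(
                {"alpha": [0.05, 0.63], "lrs_threshold": [thr["lrs_05"], thr["lrs_63"]],
                 "n_perm": config.n_perm}
            ),
            out / "significance_thresholds.tsv",
            comments,
        )
        manifest["stages"]["threshold"] = thr
        t0 = _stage("threshold", t0)

    records = transcriptome_scan(
        summary,
        grid,
        min_variance=config.min_variance,
        n_perm=config.per_probe_n_perm if config.per_probe_p else None,
        seed=stage_seed(config.seed, "scan"),
        cis_window_mb=config.cis_window_mb,
    )
    fio.write_table(peaks_to_frame(records), out / "peak_catalog.tsv", comments)
    tc = threshold_counts(records, config.lrs_thresholds)
    fio.write_table(tc, out / "threshold_counts.tsv", comments)
    manifest["stages"]["scan"] = {
        "probes": len(records),
        "cis": int(sum(r.classification == "cis" for r in records)),
        "trans": int(sum(r.classification == "trans" for r in records)),
    }
    t0 = _stage("scan", t0)

    pairs = correlation_pairs(
        summary,
        method=config.correlation_method,
        threshold=config.correlation_threshold,
        min_variance=config.pair_min_variance,
    )
    fio.write_table(pairs, out / "correlation_pairs.tsv", comments)
    manifest["stages"]["network"] = {"pairs": len(pairs)}
    if config.signature_seeds:
        sig = pc_signature(summary, list(config.signature_seeds), threshold=config.correlation_threshold)
        fio.write_table(sig.members, out / "signature.tsv", comments)
        manifest["stages"]["signature"] = {"members": len(sig.members)}
    t0 = _stage("network", t0)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
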