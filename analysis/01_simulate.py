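#!/usr/bin/env python
"""Simulate the study panel: a BXD-like family of 57 RI strains.

Generates the full synthetic dataset the downstream analyses consume:
19 autosomes + X (~80 cM each) carrying ~3,820 markers at 0.42 cM spacing,
fixed homozygous B/D mosaic genotypes for 57 strains, and a raw expression
panel (default 800 probe sets, 2 replicate arrays per strain, plus
reciprocal F1 hybrids) with planted cis/trans effects, two latent
immune-cell modules, sex-specific and Mendelian bimodal transcripts.
Everything planted is recorded in truth.json for later recovery checks.

Writes genotypes/signals/samples/probes TSVs + truth.json under --out-dir.
"""
import argparse
from pathlib import Path

from bxdeqtl import SimulateSettings, SimulationConfig, run_simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--n-probes", type=int, default=800)
    args = ap.parse_args()

    settings = SimulateSettings(
        seed=args.seed,
        expression=SimulationConfig(
            n_probes=args.n_probes,
            replicates=2,
            n_cis=30,
            n_trans=30,
            n_modules=2,
            module_size=20,
            n_sex_probes=5,
            n_mendelian=5,
            include_f1=True,
        ),
    )
    info = run_simulate(settings, args.out_dir)
    print(
        f"Simulated panel: {info['n_strains']} RI strains x {info['n_markers']} markers; "
        f"{info['n_arrays']} arrays x {info['n_probes']} probe sets -> {info['out_dir']}"
    )
    print("Planted: 30 cis eQTLs (1.5 units), 30 trans eQTLs (0.8 units), "
          "2 x 20-gene modules, 5 sex-specific and 5 Mendelian probes.")


if __name__ == "__main__":
    main()
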