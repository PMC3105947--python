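# bxdeqtl

Expression-QTL mapping and co-expression signature extraction for BXD-like
recombinant-inbred (RI) mouse panels.

In an RI family such as BXD, every strain is a fixed homozygous mosaic of the
two parental genomes (B = C57BL/6J, D = DBA/2J), so the expression level of
each transcript can be mapped as a quantitative trait. This package implements
that analysis chain end to end, for people who work with strain-panel
transcriptomes or want a tested reference implementation of its statistics:

* **Normalization** — offset +1, log2, quantile normalization across arrays,
  per-array 2Z+8 rescaling (every array ends at mean 8, SD 2; one unit ≈
  a two-fold expression difference), plus sex and strain-identity QC from
  Xist-like and Mendelian bimodal transcripts.
* **Heritability** — one-way ANOVA with strain as the factor,
  h² = b/(b+w) with b the variance of strain means and w the pooled
  within-strain variance.
* **Interval mapping** — Haley–Knott regression of strain means on expected
  D-allele dosage at 1 cM steps; LRS = n·ln(RSS0/RSS1), LOD = LRS/(2·ln10);
  RI map expansion R = 4r/(1+6r) for sib-mated lines; genome-wide significance
  by strain-label permutation of the trait.
* **eQTL cataloguing** — transcriptome-wide peaks, cis/trans classification
  (cis = peak within 10 Mb of the gene on the same chromosome), threshold
  tabulation, and cis-candidate lookup inside phenotype QTL intervals.
* **Co-expression** — all-pairs correlation networks and seeded signatures:
  the first principal component of a few cell-type marker genes is used as a
  latent cell-proportion score and expanded to every correlated transcript.
* **Synthetic panels** — a generator producing BXD-scale genotypes and
  expression with planted, recorded ground truth (cis/trans effects, latent
  cell modules, sex-specific and Mendelian transcripts), so the whole chain is
  testable without external data.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
57-strain panel (~3,820 markers, 800 probe sets, 2 replicate arrays per
strain, reciprocal F1s) and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1      # writes results/data/
python analysis/02_normalize_qc.py
python analysis/03_heritability.py
python analysis/04_map_eqtls.py --seed 1
python analysis/05_networks.py
```

Output from the run above:

```
Normalized 118 arrays: per-array mean 8.000000000, SD 2.000000000 (identical across arrays).
Sex check: 0 of 118 arrays mismatch their declared sex.
Strain identity: 0 arrays flagged (F1 arrays skipped: 4).
...
h2 range: 0.21 .. 1.00; median 0.65.
Planted vs estimated h2 (all 800 probes): Spearman rho = 0.953.
...
Genome-wide significance: LRS 16.2 at p<0.05 (suggestive 10.7 at p<0.63; 1000 permutations).
cis/trans eQTL counts by LRS threshold:
  LRS >=   12:  36 cis, 319 trans
  LRS >=   16:  35 cis,  92 trans
  LRS >=   20:  35 cis,  41 trans
  LRS >=   30:  35 cis,  23 trans
  LRS >=   50:  33 cis,  18 trans
Planted cis effects recovered (peak within 10 Mb, correct class): 35/35
Planted trans effects recovered (peak within 10 Mb, correct class): 29/30
...
389 probe pairs correlate above 0.8 across 57 strains; 80 above 0.9.
PC1 signature seeded with ['p00071_at', ...]: 20 members at |r| >= 0.8; recovered 16/16
of the remaining planted module genes.
```

Reading these numbers: the normalization invariant (mean 8, SD 2) holds
exactly on every array; the permutation threshold on a BXD-scale panel lands
near the conventional LRS-18 significance line; planted cis effects are
recovered essentially perfectly with correct classification while trans counts
decay faster with increasing threshold (cis effects are stronger, as in real
panels); and four seed genes suffice to pull back the full planted 20-gene
cell module at |r| ≥ 0.8.

The library surface mirrors the scripts; `run_pipeline(PipelineConfig(...))`
(or `bxdeqtl all`) executes the whole chain with one seed and writes a
manifest that makes reruns byte-identical.

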