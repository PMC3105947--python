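# Methods

`bxdeqtl` implements the analysis chain used for expression genetics in
recombinant-inbred (RI) mouse panels of the BXD type: every strain is a fixed
homozygous mosaic of two parental genomes (B = C57BL/6J, D = DBA/2J), each
transcript's expression is treated as a quantitative trait, and linkage between
expression and genotype is scanned genome-wide. This note records the models,
the defaults and why they were chosen, and what the synthetic panel does and
does not emulate.

## Normalization

Raw probe-set signals are transformed in a fixed order: add an offset of 1,
take log2, quantile-normalize across the full array set, then rescale each
array's Z scores as 2·Z + 8. After the chain every array has mean 8 and
population SD 2 exactly (the Z step uses the n denominator so the invariant is
exact, not asymptotic), all values are positive, and one unit corresponds to
roughly a two-fold difference in expression.

Two choices were genuinely open:

* **Z per array vs pooled.** Z scores are computed per array (across probes),
  the convention used by GeneNetwork-style pipelines. The switch is a one-line
  change; the per-array variant is what makes the mean-8/SD-2 invariant hold
  array-wise.
* **Quantile-normalization ties.** Tied values within an array all receive the
  mean of the rank-mean reference values over the ranks they occupy. This keeps
  the transform single-valued and rank-preserving (ties may merge, never cross).

## Heritability

Per transcript, one-way ANOVA with strain as the single factor:

    h² = b / (b + w)

where `b` is the variance of the strain means, Σ(ȳᵢ − ȳ̄)²/(k−1), and `w` is the
pooled within-strain (replicate) variance with Σ(nᵢ−1) degrees of freedom. Both
components are nonnegative, so h² ∈ [0, 1]; b = w = 0 returns 0 by convention.

Defining `b` as the variance **of strain means** (rather than the classical
between mean square, which is n times larger in a balanced design) is
deliberate: it makes the estimator converge to σb²/(σb²+σe²) as replicates
grow, keeps the h²=1 (identical replicates, distinct strains) and h²=0
(constant) limits exact, and matches how strain-panel heritabilities are
conventionally summarized. With n replicates the estimator has a small upward
bias of σe²/n in the numerator, under 0.1 for n ≥ 10 anywhere in [0, 1].

## Genotype model and interval mapping

**RI map expansion.** For two loci separated by d cM, the meiotic
recombination fraction is Haldane's r = (1 − e^(−2d/100))/2 and the RI-scale
fraction for sib-mated lines is R = 4r/(1+6r) — the probability that a fixed
line is recombinant between the loci. The test suite verifies R against a
forward simulation of brother-sister mating to fixation.

**Synthetic genotypes** are simulated marker-to-marker as a two-state Markov
chain with transition probability R between adjacent markers, no residual
heterozygosity. This reproduces the marginal allele frequency (1/2), the
adjacent-marker discordance (R), and the expected junction count per
chromosome, but not long-range non-Markovian correlations of a real pedigree —
for linkage mapping these are second-order.

**Scan grid.** Pseudomarkers every 1 cM (configurable) between the first and
last marker of each chromosome, with all observed marker positions included.
Expected D-dosage at a pseudomarker is P(D|flanks) − P(B|flanks) under the
Markov model, conditioning on the nearest non-missing marker on each side
(single-flank conditioning at chromosome ends; a strain with no informative
markers on a chromosome gets NaN and is dropped pairwise). This
nearest-informative-flank rule is an approximation to a full multipoint HMM,
adequate at BXD-level missingness; it is exact when data are complete. The X
chromosome is scanned like the autosomes on dosage codes; Y and the
mitochondrial genome are outside the map's label set.

**Haley–Knott regression.** At each position the trait is regressed on
expected dosage (intercept + slope); LRS = n·ln(RSS0/RSS1), LOD = LRS/(2·ln10),
and the additive coefficient is the slope — positive means the D allele raises
the trait. RSS1 is floored at 1e−12·RSS0, capping the LRS at n·ln(1e12) with a
saturation flag, so perfect fits are finite. Positions with zero dosage
variance report LRS 0. Peak ties resolve to the lowest chromosome, then lowest
position.

**Permutation significance.** Trait values are permuted over strain labels
without replacement (dosages fixed); the genome-wide maximum LRS per
permutation forms the null; thresholds are quantiles of that sample and
empirical p-values use the plus-one rule (#{null ≥ obs}+1)/(n+1). On the
default panel scale (57 strains, ~3,820 markers over 19 autosomes + X of
80 cM) the 5% threshold lands near LRS 17 ± 1, consistent with the LRS-18
rule of thumb for BXD-sized panels. Permutation scans reuse the exact same
regression core as the observed scan.

## eQTL classification and tabulation

A peak is **cis** when it lies on the probe's own chromosome within 10 Mb of
the probe's annotated position, boundary inclusive; **trans** otherwise;
**unclassified** when the probe is unmapped. Distance is measured from the
probe's single annotated point position (gene start/end conventions differ
between annotation sources; a point position is the only one the probe sheet
carries). Threshold tabulation counts cis/trans peaks at LRS ≥ {12, 16, 20,
30, 50}; candidate lookup returns cis records whose gene lies inside a closed
Mb interval with peak LRS above a floor, reporting probe, symbol, location,
mean expression (grand mean of strain means) and peak LRS.

## Co-expression and signatures

All-pairs correlation uses Pearson or Spearman as the gating statistic with
both reported; constant probes are excluded with a warning. P-values use the
exact-under-normality t transform t = r·√(n−2)/√(1−r²) (the same transform is
applied to Spearman's ρ, a documented approximation).

Seeded signatures standardize the seed probes across strains
(correlation-matrix PCA), take the first principal axis scores per strain, and
orient them so the mean seed loading is positive. Membership is gated on
|r| ≥ threshold (default 0.8) or optionally on p ≤ cutoff; gating on the
absolute correlation makes the member set invariant to sign flips of seed
probes, which the orientation rule alone cannot guarantee.

## Synthetic panel: what it emulates, and what it does not

Defaults are the study-scale conditions: 57 strains, 20 chromosomes × 80 cM at
0.42 cM spacing (~3,820 markers, ~2 Mb/cM), 2 replicate arrays per strain.
Expression is generated on the log2 scale —

    baseline + a·genotype + loading·driver + sex effect + strain effect + noise

— and exponentiated, so the raw signals have multiplicative skew and the
normalization chain does real work. Baselines are N(8, 2²) so the panel-wide
log2 SD is near 2 and the "1 unit ≈ 2-fold" calibration carries through the Z
rescaling approximately unchanged. Replicates share the strain effect, making
intended heritability achievable in expectation; background probes draw
h² targets uniformly from (0.05, 0.95) against an array-noise SD of 0.5.
Planted structure: cis effects of 1.5 units placed within 2 Mb of their marker;
trans effects of 0.8 units (weaker, reflecting the empirical pattern that
trans-eQTLs are much less significant than cis) with loci on a different
chromosome; latent per-strain module drivers with loadings set from a target
driver share of member SD (default 0.90); female-high sex probes (+4 units,
Xist-like, with small residual strain variance); Mendelian probes as extreme
cis effects (±3 units, noise SD 0.15) annotated within 0.2 Mb of their locus so
they double as strain-identity controls. Replicate-array noise is a free
parameter: the pooling of animals in real designs makes within-strain variance
unknowable a priori.

What the generator does **not** emulate: probe-level (CEL) structure, the real
marker map or probe annotation, array batch effects, and the empirical
abundance distribution — synthetic probes are uniformly "interesting"
(heritable, variable), so the fold-range histogram skews to larger ranges than
a real panel in which most probes barely vary. Passing tests therefore
demonstrate correctness of the estimators and recovery machinery under the
generative model, not performance on real arrays.

## QC checks

Sex is called per array by the difference between female- and male-marker
means, split by exact 1-D two-means (all pairwise splits scored by within-SS);
the high cluster is female; constant marker input yields "indeterminate", all
flagged. Strain identity splits each Mendelian probe low/high the same way,
maps the high class to whichever allele maximizes overall concordance with the
genotype at the marker nearest the probe, and flags arrays below 0.8 mean
concordance. Probes whose split silhouette falls below 0.7 are excluded as
not bimodal (a unimodal Gaussian's best split scores ≈ 0.55–0.6; clean
bimodal ≈ 0.95).

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; the pipeline fans a master seed
out to per-stage child seeds via `SeedSequence` with stable sha256 stage tags,
so reruns are byte-identical (the manifest records config hash, seed and
version, never timestamps). The bundled analyses and tests run at desk scale
by design: 800–1,000 probes stand in for the 45,101 on a real array, 1,000
permutations for the up-to-a-million a production run would use; the
statistics being checked (thresholds, recovery rates, calibration) are stable
at these sizes.

## Known limitations

* No kinship/variance-component correction; RI strains are treated as
  exchangeable under permutation.
* No composite interval mapping or epistasis scans.
* The missing-genotype dosage rule conditions on single flanks, not the full
  marker chain.
* Correlation p-values assume approximate normality of strain means.
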