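# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `seasonomics`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`. GFF3 input
(1-based closed) and per-cytosine tables (1-based positions) are converted
at the I/O boundary and converted back on write; round-trip identity is
enforced by tests. Peak files are narrowPeak-style BED6+4; the summit is
`start + offset`, with offset −1 meaning "no summit". Contact matrices are
intra-chromosomal only and symmetrized on read by the elementwise maximum
of the two triangles. The TSS of a gene is `start` on the + strand and
`end − 1` on the − strand; a promoter window extends `upstream` bases to
the 5′ side and `downstream` to the 3′ side of the TSS (default ±3000 bp,
configurable), strand-aware.

## Differential tests

* **Expression.** Counts are normalized to log2-CPM with pseudocount 0.5 on
  *size-factor-corrected* libraries (median-of-ratios factors over features
  observed in every sample, rescaled to geometric mean 1). Plain
  total-count CPM is compositionally biased when a minority of
  high-abundance genes moves strongly between seasons — exactly the
  situation in seasonal leaves — and that bias systematically mislabels
  flat genes as monotone. FPKM keeps its textbook definition
  (`10⁹·count/(library·length)`) since it is reported, not tested on.
  Per-gene significance is a two-sided Welch t-test on log2-CPM between
  seasons; BH correction runs over all tested genes (genes with summed raw
  counts below `de_min_count = 10` are excluded from testing). A gene is a
  DEG iff FDR < 0.05 (strict) and |log2FC| > 1 (strict). Note that at n = 3
  the Welch degrees of freedom can collapse toward 2 under variance
  heterogeneity, so even large fold changes have p-values near 10⁻³; BH
  behaves sensibly only because seasonal data carries substantial signal
  mass (see the generator section).
* **Accessibility.** Same normalization on the peak × sample count matrix
  over a shared consensus peak set (union of per-sample peaks merged at
  ≥ 1 bp overlap). A peak is a DAR iff |log2FC| ≥ 0.58 (inclusive) and raw
  p ≤ 0.01 (inclusive) — raw p by design, not FDR, mirroring the
  accessibility-analysis convention the thresholds come from.
* **Metabolites.** Welch test on log2(content + 0.01) with BH; a DAM needs
  q < 0.05 and |log2FC| ≥ 1, where log2FC is taken on group means with the
  same pseudocount. The contrasting screen intersects metabolites *down*
  in spring→summer with those *up* in summer→autumn.
* **Methylation (DMRs).** Sites of one context covered ≥ 4× in both
  samples are matched by position; 100 bp windows advanced by 50 bp with
  ≥ 5 shared sites are tested by a 1-df Pearson chi-square on the pooled
  2×2 methylated/unmethylated counts; BH runs across all tested windows.
  A window is called when |Δlevel| ≥ 0.1 (CG/CHG) or ≥ 0.05 (CHH) and
  q < 0.05; overlapping or adjacent called windows merge, and a merged
  region is reported only when supported by ≥ 2 called windows
  (`min_windows`). The support requirement is the caller's minimum-evidence
  rule: isolated single-window calls at ~30× pooled coverage are dominated
  by sampling noise, and requiring two overlapping windows (which share
  half their sites) removes most of them at no cost in recall. The pooled
  chi-square models binomial sampling only; under site-level biological
  overdispersion it is anti-conservative, which is visible in the
  genome-scale synthetic data as a diffuse load of small-Δ calls
  (concentrated in CHH, where the Δ threshold is lowest). A
  replicate-aware beta-binomial test would fix this and is a known
  limitation, not implemented because the transparent pooled test is the
  intended, oracle-testable design.

## Hi-C compartments

Per chromosome and season, replicate matrices are summed, masked (all
zero-marginal bins plus the `floor(0.02·n)` lowest-marginal bins — at 20
bins per chromosome this masks nothing, which is the intended behaviour of
a low-coverage filter on well-covered toy matrices), then balanced by
symmetric Sinkhorn iteration until every marginal is within 10⁻⁵ (relative)
of the common target; non-convergence raises an error carrying the
residual. Each entry is divided by the mean of its |i−j| diagonal over
unmasked pairs (observed/expected); the leading eigenvector of the Pearson
correlation matrix of the O/E map gives the compartment signal. Its sign is
arbitrary, so it is oriented to correlate positively with per-bin gene
density; bins with positive oriented values are A (active, gene dense),
negative B, masked NaN. Labels are invariant to positive scaling of the
contact matrix. Three-season labels concatenate into switch strings
(`A2A2B` = A in spring and summer, B in autumn); genes inherit the label of
the bin containing their TSS.

## Candidate screen

TF–target edges are Pearson correlations of log2-CPM across all nine
replicate samples (configurable to the three season means), kept when
|r| > 0.8 (strict) to at least one anthocyanin structural gene. For each
network TF four flags are computed: expression contrast (DEG down
spring→summer and up summer→autumn), accessibility contrast (promoter DAR
loss then gain), methylation contrast (promoter DMR hyper in spring→summer
*and* hypo in summer→autumn — i.e. methylation peaking in summer, any
context), and A-compartment stability (label A in all three seasons; NaN
counts as failure with an explanatory note). Layers not supplied are
reported missing (NA), not false. Candidates are ranked by number of layers
passed, then maximum |r|, then TF id — fully deterministic.

## The synthetic study

The generator emulates a three-stage seasonal design (SPS spring, SUS
summer, AUS autumn; three biological replicates per assay, two Hi-C
replicates per season) on a toy genome of 2 × 1 Mb chromosomes, 300
non-overlapping genes (30 flagged as TFs across MYB/WRKY/ERF/bHLH/NAC
families), and 50 kb Hi-C bins arranged in alternating 5-bin A/B blocks
with gene density ~2.5× higher in A blocks (so the orientation rule has
signal to work with).

*Counts* (RNA and ATAC) are negative-binomial via a Poisson–gamma mixture
with per-gene lognormal baselines and per-sample depth factors drawn from
U(0.7, 1.3). The default dispersion is 0.01, reflecting tightly
reproducible biological replicates. *Methylation* is beta-binomial per
cytosine (precision ν = 100, coverage ~Poisson(20)) with context baselines
CG 0.60 > CHG 0.35 > CHH 0.08, a global upward shift across the year
(+0, +0.02, +0.04 for spring/summer/autumn), and a Gaussian accessibility
footprint that depresses methylation around peak summits. *Hi-C* counts
are Poisson around block means (within 200, between 40) with 1/(1+d)
distance decay.

Seasonal structure has three tiers:

1. **Planted features** (recorded in the truth manifest): three structural
   genes plus the MYB-like master regulator are 8× lower in summer; the
   master and the structural genes lose 4× promoter accessibility in
   summer; the master gains +0.3 CG/CHG promoter methylation in summer
   (the F3′H-like structural gene +0.3 in CG); the master sits in a
   stable-A bin. A WRKY-like TF shares the expression trend only; an
   ERF-like TF is 8× *higher* in summer. Five compartment-switch bins
   (three A2A2B, two B2A2B, matching the predominant switch classes in
   seasonal leaves) are planted away from the reserved gene chunk.
2. **A seasonally responsive background**: 30% of genes carry independent
   per-season log2 effects of scale 1.0. Real leaves remodel thousands of
   genes between seasons, and this signal mass is what makes BH correction
   behave as it does on real data; without it a 300-gene study with six
   true signals cannot push any Welch p-value at n = 3 past FDR < 0.05.
3. **Cross-layer coupling**: each gene's seasonal expression effect e
   drives its promoter accessibility (+0.8·e in log2) and its promoter
   methylation (−0.08·e in level units). This produces the genome-wide
   positive expression–accessibility and negative expression–methylation
   fold-change correlations expected of an active chromatin program. The
   remaining genes carry only a small modulation (log2 sd 0.1), far below
   every calling threshold; zero-effect configurations set all of this to
   zero and yield only nominal false-positive rates.

The 87-compound metabolite panel uses the eight canonical anthocyanin
classes with sizes (24, 23, 11, 8, 7, 6, 6, 2); malvidins and petunidins
are drawn at trace levels (< 1 µg·g⁻¹ typically). Fifteen contrasting
metabolites (7 cyanidins including the C3G-like pigment, 5 delphinidins,
2 pelargonidins, 1 peonidin) are 20× lower in summer — 300× for the
C3G-like pigment. Replicate noise is lognormal with CV 10%. Calibration
standards span 0.01–5000 ng·ml⁻¹ in 14 levels with *constant* detector
noise (σ = 2 response units): with homoscedastic noise the specified
unweighted OLS calibration is the right estimator. Real targeted assays
show response-proportional noise and would use 1/x- or 1/x²-weighted fits;
with unweighted OLS and proportional noise the intercept becomes unstable
enough to corrupt low-abundance quantification, which is why the generator
does not model it. Instrument responses for samples are back-computed
through the content formula with V = 500 µl and m = 0.05 g.

Determinism: one `numpy` Generator seeded from `SimulationConfig.seed`
drives every draw in a fixed order; a fixed seed reproduces every output
file byte for byte.

## Benchmarks and what they show

* **Regulator recovery.** On the default study the planted master is the
  unique TF passing all four layers and ranks first; across 20 independent
  seeds it ranks first in ≥ 18. The occasional competitor is a responsive
  background TF that genuinely acquires the full four-layer signature —
  a realistic failure mode, since the screen has no way (and no reason) to
  distinguish a true summer-contrast TF from the planted one.
* **Type-I control.** Null simulations (no effects; 2000 genes, 1000
  peaks, 1000 metabolites, 3 vs 3, dispersion 0.05) keep the fraction of
  calls at or below nominal plus three Monte-Carlo standard errors for all
  three tests.
* **DMR benchmark.** Twenty 300 bp CG regions at 0.8-vs-0.2 methylation
  and 30× coverage on a 200 kb chromosome (mean site spacing 12 bp,
  binomial sampling noise) are recovered with region-level precision and
  recall ≥ 0.9 (a called DMR counts as correct when it overlaps a planted
  region; base-pair precision is intrinsically bounded near 0.65 by the
  window/step geometry, since boundary windows extend calls up to one
  window past the true edges).
* **Compartments.** Planted block labels are recovered at ≥ 95% of
  unmasked bins per season (in practice 100% at the default depth) and all
  planted switch bins receive their exact transition strings.
* **Coupling signs.** On default data the Spearman correlation of per-gene
  spring→summer fold changes is positive between expression and promoter
  accessibility and negative between expression and promoter methylation,
  with 95% confidence intervals excluding zero.

Problem sizes above (300 genes, 1 Mb chromosomes, 20 bins, 20 seeds) are
the package defaults, chosen so a full end-to-end screen runs in seconds
on a laptop; all are configurable upward.

## What passing tests do and do not show

The generator's counts are exchangeable across replicates (no batch
effects, no library-preparation artifacts), its methylation sites are
independent given the regional mean, its Hi-C model has a single
compartment scale (no TADs, loops, or trans contacts), and its planted
effects are step functions of season. Passing the recovery benchmarks
therefore shows the *inference chain* is correct and well calibrated under
its stated model — it does not certify performance on real sequencing
data, where dispersion estimation, mapping artifacts, replicate batch
structure, and the anti-conservativeness of the pooled DMR test under
overdispersion (see above) all matter. The thresholds themselves
(FDR < 0.05, |log2FC| > 1; |log2FC| ≥ 0.58, p ≤ 0.01; |r| > 0.8) follow
the printed inequalities exactly, including their strict/inclusive
boundaries.
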