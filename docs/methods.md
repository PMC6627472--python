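# Methods

This note documents the statistical models implemented in `methdev`,
the design decisions taken where the procedure was genuinely open, the
construction of the synthetic-data generator, and what the tests do and
do not establish about real data.

## Coordinates and data model

All intervals are 0-based half-open; conversions to/from 1-based
formats (cytosine reports, GFF3) happen only in `io_formats`. Cytosine
sites are kept per strand — the two cytosines of a CpG dyad are separate
records. Whether the original analyses pooled the symmetric pair is not
determinable from the procedure description; both behaviours are
supported (`merge_symmetric_cpgs`), with unpooled the default. Stage
labels form an ordered vocabulary (`MY < PR < FB`); transitions are the
consecutive pairs, and "phase 1"/"phase 2" name the two transitions on
the expression side.

## mCG calling

With background non-conversion rate `p₀` (default 0.003), a site with
`k` of `n` reads methylated gets the exact upper tail
`p = Σ_{j≥k} C(n,j) p₀^j (1-p₀)^{n-j}` (regularised incomplete beta, no
normal approximation). Decisions:

* "more than four reads" is implemented as `n ≥ 5`.
* BH runs per sample (each species × stage methylome is called
  independently), over all depth-filtered sites jointly.
* Strict inequalities: `q < 0.01`, level `> 0.05`, applied to the raw
  level `k/n` (no shrinkage).
* Ties in p share a q-value (standard step-up); output order is fixed
  to (chrom, pos, strand) so reruns are byte-identical.

Under a pure null (level 0 everywhere, only non-conversion noise) the
discrete p-values plus BH make rejections essentially impossible at
`q < 0.01`; the acceptance suite measures the realised false-call
fraction at ~0 across 20 seeds.

## DMR detection

Windows `[200k, 200k + 1000)` tile each chromosome, final window
truncated. Eligibility (≥ 10 mCGs in ≥ 1 stage) is counted on mCG
flags, but the test statistic uses *reads*: the 2×2 table pools
methylated vs unmethylated read counts over all covered CG sites in the
window, so deeply covered sites weigh more. Δ is the difference of
pooled levels, later minus earlier. BH runs over the eligible windows
of one transition. Merging requires ≥ 1 bp overlap and identical
direction; book-ended windows stay separate. Merging is performed per
direction, so same-direction DMRs never overlap while a hyper and a
hypo DMR may (they arise from distinct window sets).

The scalar `fisher_exact_2x2` wraps scipy's exact conditional test; the
batch path used for whole-genome window sweeps is a vectorised
log-gamma summation over the hypergeometric support (tables no more
probable than observed), agreeing with enumeration to < 1e-12 and ~10×
faster. Degenerate margins return p = 1 by convention.

MP/MGB differential testing reuses the same machinery with the region
as the unit, eligibility by the MP/MGB density criterion (≥ 10 mCG/kb
in ≥ 1 stage) rather than a raw count — a 1 kb promoter needs 10 mCGs,
a 2 kb gene body 20 — and no merging.

## Feature geography

Promoter = 1 kb strand-upstream of the TSS, truncated at chromosome
bounds; downstream-1kb analogous at the TES; introns = gene minus
exons; exonless genes count as single-exon (with a warning). When
features overlap, a site receives exactly one category by the fixed
precedence exon > intron > promoter > downstream-1kb > TE > intergenic.
The precedence is a documented choice: the category accounting is
gene-centric, so a TE inside a promoter does not mask it; TE-level
analyses (metaprofiles, per-class summaries, methylation–expression
correlation) use the TE annotation directly and ignore the flattening.

Metaprofiles rescale each region to 20 body bins with 10 × 100 bp flank
bins, pool reads per bin (`Σ meth / Σ total`, i.e. site levels weighted
by coverage), and mirror minus-strand regions so bin 0 is always 5'.

Promoter methylation classes for the TE-distance analysis: `none` =
covered promoter that is not an MP; MPs split into low/medium/high
tertiles of their mean pooled level across stages. Expression tertiles
use ranks of `log10(mean TPM + 1)` with ties broken by gene id, giving
deterministic classes of equal size ± 1.

## Expression

TPM: per-sample length-normalised rates scaled to 10⁶; all-zero
columns become NaN with a warning. "Expressed" = replicate-mean
TPM > 1 in at least one stage (strict).

The NB Wald DE test replaces an external count-model fitter so the
pipeline is self-contained: median-of-ratios size factors; per-feature
method-of-moments dispersion `(s² − μ)/μ²` averaged over the two
conditions, shrunk 50/50 toward the transcriptome median of positive
estimates, floored at 0.01; Wald statistic on
`log₂((μ_B + ½)/(μ_A + ½))` with delta-method variance
`(1/μ + α)/n` per condition, normal reference; BH over tested features.
"log-transformed fold change > 1" is read as `|log₂FC| > 1`, two-sided,
with up/down by sign. Null simulations (5 000 NB features, 3 vs 3)
put the fraction of `q < 0.01` calls near 4e-4, and planted 8-fold
changes at mean 200 are detected with power 1.0 — the test is
conservative but far from powerless at this design size. A config hook
accepts an externally produced (feature, log2fc, q) table wherever a
DE result is consumed, so outputs of dedicated DE packages can stand in.

Ortholog filtering is strict (`fraction > 0.70`, `length > 300`);
divergence classes are a pure function of the two statuses (the 9
status pairs map onto the 5 classes, so class counts always sum to the
number of kept pairs).

## Inferential statistics

* Hypergeometric enrichment: upper tail `P(X ≥ k)`, BH over tested
  terms, enriched iff `q < 0.05` and overlap ≥ 5. The universe is
  caller-supplied; the pipeline defaults to the expressed, kept
  ortholog set of the comparison. No GO-DAG propagation.
* Games–Howell: Welch t per pair, Welch–Satterthwaite df, p from the
  studentized-range distribution with `q = |t|·√2` over all k groups
  (numerical CDF); cross-checked against an independent implementation
  in the tests.
* Mann–Whitney: exact by full enumeration of rank assignments for
  `n_x + n_y ≤ 12` (midrank ties); otherwise normal approximation with
  tie and continuity correction, which agrees with the exact path to
  < 0.05 at the crossover sizes.
* Two-count comparison: exact two-sided binomial test of `k₁` in
  `k₁ + k₂` trials at p = ½ (for, e.g., comparing DMR counts between
  transitions).

## The synthetic-data generator

The generator is first-class, tested code defining the study conditions
for every downstream check.

**Genome.** Two chromosomes of 400 kb; 150 non-overlapping genes
(1.5–3.5 kb, 1–5 exons) and 100 TEs (0.5–2 kb) placed by distributing
the free space as multinomial gaps, so placement is exact and
overlap-free by construction. TE classes are drawn from
(Gypsy 0.38, Copia 0.24, LTR-other 0.14, LINE 0.12, DNA 0.12) —
Gypsy + Copia ≈ 62% of repeat content. The second species copies the
first (ortholog gene order preserved, ids renamed) and jitters TE
positions within their free gaps, emulating two genomes with very
similar TE content.

**Methylome.** CpG dyads arrive as a Poisson process with mean spacing
50 bp. Each dyad draws a latent level from a two-component Beta mixture:
low mode 0.02 (effectively unmethylated), high mode 0.90, concentration
100. The high-component weight is structural:

* exons/introns/downstream: 0.03;
* intergenic: 0.70;
* each TE draws its own weight from Beta(2, 0.9) — most elements
  heavily methylated, a minority barely (incomplete TE methylation);
* promoters and gene bodies inherit `w_max · exp(−d/400 bp)` from their
  nearest TE (w_max 0.85 promoters, 0.45 bodies) — methylation
  *spreading*.

Observed data per stage: depth ~ 1 + Poisson(29), methylated reads ~
Binomial(depth, `ℓ(1−ε) + (1−ℓ)ε`) with ε = 0.003; both strands of a
dyad share the latent level but draw reads independently. Planted DMRs
(8 per transition, 1 kb, ≥ 15 dyads, TE/intergenic space) override the
mixture: hyper regions step from a 0.10 baseline by +0.30 in the later
stage, hypo from 0.90 by −0.30; shifts persist into subsequent stages so
each transition's truth table stands alone. One methylome per
species × stage (no WGBS replicates), three RNA replicates per
species × stage, mirroring the single-methylome/triplicate-RNA design
such studies use.

**Expression.** Ortholog base means are lognormal(log 150, 0.8) shared
between species with a mild species factor; promoter methylation
represses multiplicatively by `2^(−8·level)` and TE expression
(lognormal(log 1.5, 1.0) baseline) by `2^(−6·level)` — strong silencing,
consistent with methylation acting as genome defence. Counts are NB
with dispersion 0.1 plus lognormal(0, 0.15) library-size factors.
Divergence classes are planted per phase on disjoint gene subsets
(30 DE1-Pt, 20 DE1-Pe, 10 DE2-identical, 5 DE2-opposite of 150 genes)
as ±8-fold persistent shifts with random signs. The ortholog table
draws consensus fractions from Beta(16, 4) and lengths from
U(250, 1500), so a realistic minority fails the coverage filter.

**What the generator does not emulate:** sequence content (CpG
positions are positional only), read-level artefacts (mapping bias,
duplicates, M-bias), CHG/CHH contexts, TE nesting/fragmentation,
isoform structure, and batch effects. Passing tests therefore establish
the *statistical machinery* — calibration, recovery, direction — not
robustness to alignment-level pathologies of real libraries.

## Scale of the built-in checks

The acceptance checks run at deliberately desk-friendly sizes chosen as
the package's own test conditions: 10⁵-site null methylomes × 20 seeds
for caller calibration; default-scale genomes (≈ 32 k site records) × 10
seeds for DMR recovery at depth 20; ≥ 50 k intergenic dyads for mixture
recovery; 150-ortholog datasets × 10 seeds (both phases) for the
divergence confusion; 5 000-feature NB simulations for DE calibration.
Headline counts from genome-scale studies (absolute numbers of mCGs,
DMRs, orthologs) depend on genome and annotation versions and are not
reproduced here; the suite verifies properties — exactness, error
control, recovery, directionality — that such counts rest on.

## Known limitations

* The NB Wald test has no outlier handling or fold-change shrinkage;
  with 2 replicates per condition the dispersion shrinkage leans
  heavily on the transcriptome median.
* `window_eligibility` counts strand-sites; with symmetric-CpG pooling
  enabled the effective mCG counts halve, and the ≥ 10 threshold then
  bites harder.
* Games–Howell p-values rely on scipy's studentized-range CDF, which is
  slow for many groups (fine at the ≤ 6 groups used here).
* The per-basepair category painting allocates one int8 array per
  chromosome — appropriate for fungal-sized genomes (tens of Mb), not
  for mammalian ones.
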