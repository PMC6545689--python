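# Methods

This note documents the statistical models implemented in `methsig`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Preprocessing

**Detection p-value.** A probe's total intensity T = M + U is compared with
the sample's negative-control probes. The default model is Gaussian:
p = 1 − Φ((T − μ_neg) / σ_neg), with μ_neg, σ_neg the mean and sample
standard deviation of the control totals for that sample. This is the
common practice for background calling on these arrays; an empirical-rank
alternative, p = (#{controls ≥ T} + 1) / (n + 1), is exposed via
`method="empirical"` for heavy-tailed backgrounds. Degenerate controls
(zero σ) raise an error rather than emitting p = 0/1.

**Probe filters.** Six rules, any of which removes a probe: (i) detection
p > 0.01 in more than 5% of samples; (ii) bead count < 3 in more than 5% of
samples; (iii) non-CpG probes; (iv) SNP-overlapping probes; (v) probes
whose sequence maps to multiple genomic locations; (vi) sex-chromosome
probes (chromosome names `chrX`/`chrY`, configurable). All three numeric
inequalities are strict. SNP/multi-mapping status is carried as manifest
flags (on real data these lists come from the array annotation ecosystem;
the generator plants them). The removal report counts each rule's firings
twice: attributed (first rule in i–vi order that fires) and raw; rule order
affects only attribution, never membership.

**Beta values.** β = M / (M + U + 100). The offset of 100 keeps the ratio
stable at background-level intensities. β is strictly increasing in M,
decreasing in U, and bounded in [0, 1] for any non-negative intensities.

**BMIQ normalisation.** The two assay chemistries on the array measure the
same biology with different dynamic ranges; type-II betas are compressed
toward 0.5. Per sample, a three-state (unmethylated / hemimethylated /
methylated) beta mixture is fitted by EM separately to the type-I and
type-II betas, and every type-II beta is mapped through the composition of
the fitted mixture CDFs, β ↦ F_I⁻¹(F_II(β)). Because mixture CDFs are
strictly increasing on (0, 1), the map is strictly monotone (within-sample
type-II ranks are preserved) and is the identity when the two fitted
mixtures coincide; type-I betas are returned unchanged. The mapping is
"state-wise" through the mixtures themselves rather than via hard state
assignments, which avoids discontinuities at posterior boundaries.

EM numerical choices: fixed deterministic initialisation (component means
0.1 / 0.5 / 0.85, variance 0.01, equal weights — no RNG, so results are
reproducible without a seed); weighted method-of-moments M-steps for the
beta shape parameters; components re-sorted by mean each iteration so the
states stay ordered; convergence when the mean per-observation
log-likelihood change falls below 1e-5, with a cap of 500 iterations
(some samples traverse a slow component-separation phase for a few hundred
iterations before settling; the cap accommodates this, and hitting it
still raises an error with diagnostics). A state whose effective count
collapses below 2 observations raises an error. Betas are clipped to
[1e-4, 1 − 1e-4] for fitting, and the inverse CDF is evaluated on a
4001-point grid with linear interpolation. Re-normalising an already
normalised sample changes betas by < 0.01 (the refit mixtures nearly
coincide).

## Differential methylation with negative-control RUV

Model: for each target probe j, β_j = b0 + b1·g + Wα_j + ε, where g is the
group indicator (LTS = 1, STS = 0, so b1 > 0 means hypermethylation in
long-term survivors) and W holds unwanted-variation factors shared across
probes. W is estimated as the leading left singular vectors of the
column-centred negative-control beta matrix: the controls measure no
biology, so their systematic variation identifies batch structure. Each
probe is then fitted by least squares on [1, g, W] with a standard t test
on b1 (df = m − 2 − k). Tests run on beta values directly, not M-values.

**Choice of k.** The number of factors defaults to a permutation-based
parallel-analysis rule: keep singular values of the centred control matrix
exceeding 1.1 × the median of the maximum singular values of ten
column-permuted copies (fixed internal permutation seed, so the choice is
deterministic). With structureless controls this selects k = 0 and the
test reduces *exactly* to ordinary least squares / the equal-variance
t-test; a planted batch factor of realistic size exceeds the threshold by
an order of magnitude and is always found. The saturated variant of
control-based adjustment (k = m − p factors) leaves zero residual degrees
of freedom at 29 samples and requires a control-calibrated variance
estimator in place of per-probe residual variance; we prefer the
data-driven k with exact small-sample t inference, and expose an explicit
`k` override for users who want a fixed count. An upper cap of m − 4
preserves residual degrees of freedom. Zero-variance probes get p = 1 by
convention rather than NaN.

**FDR.** Benjamini–Hochberg step-up (via statsmodels), significance at
q < 0.01 for sites and q < 0.05 for GO terms.

**Signatures.** Hyper-island = significant ∧ Island ∧ Δβ > 0.2;
hypo-open-sea = significant ∧ OpenSea ∧ Δβ < −0.2, with Δβ the difference
of group means (LTS − STS) computed from the same normalised beta matrix
the test used, and the 0.2 threshold strict. The two sets are disjoint by
construction (island vs open sea).

## Annotation

CGI context measures the distance d from the probe position to the nearest
covered CGI base: Island inside, Shore 0 < d ≤ 2000, Shelf
2000 < d ≤ 4000, OpenSea beyond ("within 2000" is read as a closed upper
bound, and likewise for the shelf band). The N_/S_ flank prefix is defined
genomically by default — N_ when the nearest CGI lies at higher
coordinates — with a `cgi_relative` convention that swaps the labels, since
flank-naming conventions differ between annotation sources; equidistant
ties resolve to the lower-coordinate island. TSS context is strand-aware:
TSS200 is 0–200 bases upstream (closed), TSS1500 is 200–1500 (half-open
below, closed above), FirstExon is containment in a first exon, and
multiple transcripts combine by the priority FirstExon > TSS200 > TSS1500 >
Far. Gene assignment is a deliberately simple containment rule — gene body
extended 1500 bases upstream, nearest body wins, ties to the
lexicographically smaller id — because the pipeline only needs a
probe→gene mapping, not a transcript-model annotator.

## Integration analyses

**Histone enrichment.** A site set's enrichment proportion for a mark is
the fraction of its sites covered by at least one of the mark's intervals.
Cells are aggregated by union by default (a site "has" the mark if any cell
shows it); per-cell proportions and their min–max range are also reported,
and a mean-over-cells mode exists, because pooled-versus-averaged
aggregation is a genuinely open choice — both views are emitted. The
reported difference is proportion(significant) − proportion(insignificant)
∈ [−1, 1], with the significant set's proportion also binned into quarters.

**Expression correlation.** Pearson r between a site's β and
log2(FPKM + 1) across shared samples (≥ 3 required), keeping sites with
SD(β) > 0.1 and genes with mean FPKM > 0; a gene with several surviving
sites is assigned the maximum *signed* r (no |r| tie-breaking — the
maximum is over r exactly as defined).

**Mutation association.** A mutation is associated with a probe site when
|mutation pos − probe pos| ≤ 5000 (inclusive at the boundary). For every
(site, mutated-sample) pair — counted once per pair regardless of how many
nearby mutations the sample carries — the sample's β is expressed as a
Z-score against the across-sample mean and SD at that site; zero-SD sites
are dropped with a count. Site-set and background-set Z distributions are
compared by the two-sample Kolmogorov–Smirnov test.

## GO enrichment with probe-count bias correction

Genes with many probes are more likely to enter any probe-derived gene
set. The test therefore draws 1000 random gene sets of the observed size
*without replacement* with per-gene probability proportional to probe
count, and reports the empirical upper tail p = #(resamples with term
count ≥ observed) / 1000, without pseudocount — so a term can genuinely
reach p = 0; a `pseudocount` option gives the conservative
(x + 1)/(n + 1) form. Weighted sampling without replacement uses the
Gumbel-top-n construction, which is equivalent to sequential draws with
probability ∝ weight and vectorises across resamples. With uniform
weights the null is exactly hypergeometric (verified against the
closed-form tail in tests). BH runs over all terms represented in the
universe; flat term sets are assumed (no ancestry propagation).

## Two-score classifier

A sample's two scores are the arithmetic means of its betas over the
hyper-island and hypo-open-sea signature sites; the call is LTS iff both
exceed 0.2 (strict). The geometry of the rule: island sites are nearly
unmethylated in short-term survivors, so the hyper score separates the
groups around 0.2, while the hypo score stays above 0.2 for both groups
and mainly guards against degenerate profiles. Scoring must operate on
*normalised* betas: the type-II chemistry compression drags unmethylated
island betas toward 0.5, so raw betas would push every sample past the
threshold. Signature sites missing from a cohort's probe set are skipped,
with per-signature coverage fractions reported; a sample covering no site
of a signature is an error (uninformative). Cohort evaluation treats LTS
as the positive class. A utility provides complete-linkage hierarchical
clustering orders (Euclidean distance) on both axes for heatmap
rendering, deterministic for a given input order.

## The synthetic-data generator

The generator emulates, from one seed, the structures the analysis relies
on; identical configuration reproduces byte-identical outputs.

* **Genome**: 5 autosomes of 10 Mb plus small chrX/chrY; CpG islands of
  400–1400 bases on a jittered anchor grid spaced so open sea (> 4 kb from
  any island) always exists; genes with strand, TSS and first exon —
  one promoter gene per planted hyper site (probe 100 bases upstream of
  the TSS) plus background genes; 12 histone marks × 3 cells, with
  H3K27ac intervals preferentially covering planted hyper-island sites and
  H3K9me3 covering planted hypo-open-sea sites (85% per cell) over random
  background intervals.
* **Betas**: per-(probe, sample) betas are Beta-distributed around a mean
  with precision κ = 100, so values respect [0, 1] without clipping
  artifacts. Baselines are context-dependent (islands low, open sea high);
  planted hyper sites start at 0.03–0.12 (unmethylated islands) and gain
  +Δβ in LTS; planted hypo sites start at 0.55–0.80 and lose Δβ. The
  defaults — 17 LTS vs 12 STS, 5000 probes, 250 + 250 planted sites,
  Δβ = 0.25 — mirror the discovery design being emulated; 0.25 sits in the
  "moderate difference" range such signatures show.
* **Chemistry**: type-II probes (72% of the array, 450K-like) report
  0.5 + 0.6·(β − 0.5), an affine compression toward 0.5 applied *after*
  biology, so BMIQ has genuine work to do and raw type-II group
  differences are attenuated by 40%.
* **Batch**: one latent factor u ~ N(0, 1) per sample loads on every
  negative control (loading sd 0.06) and on 30% of target probes (sd
  0.04), giving RUV identifiable unwanted variation of realistic size.
* **Intensities**: β is converted to (M, U) around log-normal totals
  (median 3000), negative controls around background totals (≈ 240), so
  detection p-values behave; planted QC failures (background-level
  intensities, bead counts < 3 in 20% of samples) exercise filter rules i
  and ii, plus ~1% random entry-level failures.
* **Expression**: genes promoter-coupled to planted hyper sites follow
  log2(FPKM + 1) = 6 − 4·c·β + noise (c = 0.7, noise sd 0.5 by default);
  with c = 1 and zero noise the relation is exactly affine (r = −1).
  Coupling uses the *biological* betas — chemistry compression is a
  measurement artifact and should not propagate into biology. One in ten
  background genes is silent to exercise the mean-FPKM filter.
* **Mutations**: a Poisson(30)-per-sample uniform background, plus ~2
  mutations within ±4 kb of each planted hypo site whose carrying sample
  is chosen with probability ∝ exp(5·c·z(β)) — high-methylation samples
  preferred at strength c, uniform at c = 0. Mutation-prone regions are
  placed regardless of c so that toggling c changes only the
  methylation preference, not the mutation geography.
* **GO terms**: ~30 random synthetic biological-process terms plus one
  planted term concentrated in the promoter-coupled genes, so the
  end-to-end pipeline has a recoverable enrichment.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genome sequence and realistic CGI/gene geography;
probe-sequence effects beyond the global type-II compression; correlated
multi-factor batch structure (a single factor is planted; the estimator
handles several); copy-number events; tumour purity and cellular
heterogeneity (real betas are purity-diluted mixtures); measurement error
in expression/mutation calls; the GO DAG. Effect recovery on this
generator demonstrates correctness of the machinery under its stated
model, not field performance on clinical cohorts.

## Problem sizes

Default study conditions are 5000 probes × 29 samples with 500 planted
sites; calibration analyses use 2000-probe null studies; validation
cohorts are simulated at 12 LTS + 39 STS (mirroring the external-cohort
evaluation design) or 8 + 8 in the smaller test fixtures. These sizes give
stable Monte-Carlo behaviour for every statistic the package reports while
keeping a full end-to-end run in seconds.

## Known limitations

* The RUV step assumes negative controls are unassociated with the group
  factor; confounding that leaks into controls is absorbed as "unwanted"
  and can remove true signal.
* BMIQ's method-of-moments EM maximises a surrogate of the likelihood;
  fits are adequate for quantile mapping but the mixture parameters are
  not maximum-likelihood estimates.
* The empirical GO p has resolution 1/n_resamples and is superuniform
  under the null near ties; use the pseudocount option when p = 0 is
  unacceptable downstream.
* Gene assignment ignores overlapping transcript models and assigns one
  gene per probe.
* The classifier threshold (0.2) is taken as given, not re-optimised;
  no uncertainty is attached to cohort sensitivity/specificity.
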