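# Methods

This note documents the models implemented in `lymphforge`, the
assumptions behind them, the defaults that matter, and what the
synthetic-data generators do and do not emulate.

## Study design being modelled

Single lymphocytes and HSPCs are expanded into colonies and
whole-genome sequenced at roughly 20×. Because a colony is clonal,
somatic mutations of the founder cell appear at VAF ≈ 0.5 in that
colony's reads, germline variants appear at VAF ≈ 0.5 in *every* colony
of the donor, and library/sequencing artifacts appear at low VAF
independently in all colonies. All per-variant inference in the
filtering stage rests on this three-way contrast.

## Variant filtering

*Genotype rule.* A variant is present in a colony iff it has ≥ 2
alternate reads and VAF ≥ 20%. At depth d with alt ~ Binomial(d, 0.5),
detection probability is the exact binomial tail; at 20× the rule
requires ≥ 4 alt reads, giving sensitivity 0.9987.

*Germline calls.* Two tests: (i) mean VAF across covered colonies
> 0.40 (strict inequality); (ii) pooled one-sided exact binomial test
of Σalt vs Σdepth against p₀ (0.5 autosomes/female X, 0.95 male sex
chromosomes outside pseudoautosomal regions), with failure to reject at
Benjamini–Hochberg q ≥ 10⁻⁶ called germline. The BH correction runs
within donor.

*Overdispersion filter.* Per variant, a beta-binomial with a shared
mean across colonies is fitted by maximising over ρ (the
overdispersion, parameterised as α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ) on a
fixed 30-point geometric grid on [10⁻⁴, 0.999], with μ profiled out by
golden-section search (vectorised across variants). The statistic fed
to valley-finding is −log₁₀ of the boundary-corrected LRT tail
probability (½·χ²₁ tail; ρ = 0 lies on the parameter boundary), capped
at 300. The all-reference variant (Σalt = 0) has ρ̂ = 0 by convention.
The beta-binomial parameterisation and the LRT score construction are
this package's choices; only the test's role (retain highly
over-dispersed variants) is inherited from the design.

*Valley cutoff.* Scores of a donor are density-estimated with a
Gaussian KDE (Silverman bandwidth, 512-point grid). The cutoff is the
deepest local minimum between the two largest modes, ties broken toward
the smaller score. The sample is declared unimodal — and the configured
fallback used, flagged — when there are fewer than two maxima or the
valley density exceeds 0.8× the smaller mode's density; without the
depth condition, KDE wiggle on unimodal samples produces spurious
cutoffs. Requires ≥ 50 scores.

*Hooks.* An external per-variant `subclonal` boolean (from a
subclonality caller) is AND-ed with the overdispersion pass; an
external blacklist removes sites outright. Neither tool is
reimplemented.

## Burden model

*Depth correction.* Mutation recall rises with depth, so burdens are
fitted against depth with the asymptotic curve
f(x) = b₀ + b₁(1 − exp(−exp(lrc)·x)) (least squares; b₁ ≥ 0 keeps the
curve non-decreasing, saturating at b₀ + b₁). Burdens are rescaled
multiplicatively: adjusted = n·f(30)/f(depth), which is exact at the
reference depth and preserves zeros. Reference fits should use the
stable compartment (HSPC colonies; ≤ 50× mean depth) —
`reference_depth_fit` applies the ≤ 50× rule.

*Mixed model.* burden ~ cell type + age:cell type (cell-means coding:
one intercept and one slope per type), donor-by-cell-type random
intercept with variance σ_d², and residual variance σ_t² per cell type.
"Weighted by cell type" is interpreted as per-cell-type residual
variances (variance-function weighting); that interpretation is a
declared choice. Estimation is maximum likelihood: the group covariance
σ_t²I + σ_d²J has closed-form inverse/determinant (compound symmetry),
fixed effects are profiled out by GLS, and the log-variances are
optimised by Nelder–Mead. The age × cell-type interaction is tested by
LRT against a common-slope model (χ², df = K−1), and variance
heterogeneity by LRT against a single residual variance (df = K−1).

*Confidence intervals.* Wald intervals on the ML fit use a t quantile
with containment degrees of freedom (#donors − 2), because age and the
cell-type contrasts vary at the donor level and studies of this design
have only a handful of donors; with a normal quantile the intervals
undercover materially (77–93% observed at 4 donors). Degenerate
noiseless designs are handled by clamping log-σ at a small floor; point
estimates remain exact.

## Signature attribution

Exposures w (simplex) of a fixed catalogue S (rows = signatures,
columns = the 96 trinucleotide channels in canonical order: C>A, C>G,
C>T, T>A, T>C, T>G × 5′ base × 3′ base, pyrimidine-strand convention)
are estimated by EM for the multinomial mixture Multinomial(n, wᵀS).
Uncertainty is a seeded multinomial bootstrap (default 200 refits);
the 90% percentile interval drives the display rule (mask signatures
whose 5th percentile is below 1%). Bootstrap rather than MCMC keeps the
interval deterministic given the seed with no sampler dependency. The
two-pass rule drops signatures below 10% exposure in every sample and
refits on the reduced catalogue.

Attribution: P(s|c) = wₛSₛ[c]/Σₜ wₜSₜ[c]. Fine-bin (10-kb) counts sum
each mutation's posterior under its parent 1-Mb window's exposures, so
per-bin signature counts conserve the raw count exactly; a bin is
included for a signature only when the mean attribution exceeds 1/2
(guards against small attributions riding on locally high mutation
rates). Per-gene enrichment is a two-sided one-sample t-test of a
gene's variant attributions against the genome-wide mean (≥ 2 variants;
degenerate zero-variance genes get p = 1 when equal to background).

The shipped catalogue (`data/synthetic_signatures_96.tsv`) is a
deterministic **synthetic** stand-in: sparse Dirichlet profiles with
pairwise cosine similarity < 0.45, distinguishable by construction.
Users substitute their own catalogue file for real analyses; nothing in
the code depends on the stand-in's specific values.

## Feature regression

Counts per 10-kb bin are regressed on feature tracks with an additive
model: each feature enters through a centred cubic B-spline basis of
dimension 10, and a group-lasso penalty λΣ_f‖β_f‖₂ (FISTA proximal
gradient; Gaussian loss by default, Poisson with backtracking as an
option) selects whole features. λ is chosen on a seeded two-thirds
training split by five-fold cross-validation with the one-standard-error
rule (the sparsest λ within one SE of the CV minimum — the CV-minimum λ
systematically admits noise features); the model is refitted on the
full table at λ*, where R² is reported. Whether R² is training or
held-out is thus resolved as: full-table, with the split documented
here. Individual explanatory power is the R² of a single-feature spline
least-squares fit; constant features score 0 with no error.

Replication-timing preprocessing removes regions with sum signal < 95.
Table assembly appends a seeded without-replacement sample of
zero-mutation bins sized to 10% of the returned table (shortfall
flagged when fewer exist). Internally bins are 0-based half-open;
1-based inclusive on input/output.

## SV motifs

PWMs are built from consensus sequences with probability 0.85 on the
consensus base and 0.05 elsewhere (the real scanning matrices are not
published; this stand-in is declared, reproducible and dependency-free).
Scores are log-odds against a uniform background and the null score
distribution is enumerated exactly by convolving per-position score
distributions, so the p < 10⁻⁴ hit threshold is exact: for the
7-bp heptamer it admits only the perfect match
(tail (1/4)⁷ ≈ 6.1×10⁻⁵). Scans cover both strands of ±50 bp around
each breakpoint (full RSS = heptamer plus nonamer at spacer 12 or 23
± 1 bp); CSR clusters need ≥ 2 exact AGCT/TGCA occurrences with
consecutive gaps ≤ 100 bp within ±1,000 bp. "Within 50 bp of a
breakpoint" means either side of either breakpoint; the
interior/exterior sign is defined only for deletions (+ = interior).

Background: 100 random control sets drawn from the callable mask, each
scanned exactly like real breakpoints; the background rate is the
median per-set hit proportion. Mechanism attribution is
max(p_obs − p_bg, 0). Ig intervals (GRCh37) are built in; TCR intervals
ship as an editable TSV fixture. Non-templated-insertion enrichment is
a two-sided Fisher exact test on insertion presence × RSS-hit status.

## Mutation timing

Each mutation goes to its argmax-posterior signature (ties to the
lexicographically first name, counted); counts are aggregated into 1-Mb
windows, and signatures averaging < 1 mutation per window are flagged
ineligible (no power). For each candidate epigenome, a random forest
(default 300 trees, fixed seed; rankings on the synthetic generator are
stable from ~100 trees, so the family default favours runtime over the
conventional 500) regresses window counts on that epigenome's
histone-mark features (one feature per mark, stacked — how multiple
marks combine into features was an open choice) in ten-fold
cross-validation; the score is the held-out LogCosh distance
mean log cosh(obs − pred), computed stably as
r + log1p(e^{−2r}) − log 2. Windows with zero coverage in any compared
track set are dropped listwise so fold comparisons share a window set.
Epigenomes are compared by paired two-sided Wilcoxon on the 10 fold
distances (p = 1 when identical). The matched-count control subsamples
the larger profile per-window (multivariate hypergeometric, seeded) to
the smaller total before comparing with an unpaired rank-sum test.

## Germinal-centre summary and selection

SHM rate = IGHV variants / gene length (capped at 1 with a flag; the
productive gene length is a per-sample input — no universal constant is
assumed). SBS9 count = exposure × SNV burden; rate = count / callable
genome (3.1 Gb − 383 kb default). density_fold = SHM rate / SBS9 rate
and offtarget_ratio = SBS9 count / IGHV count are plain ratios (NaN
with a flag on zero denominators). Associations are OLS with the
two-sided slope test. dN/dS ω converts to the positively selected
fraction of non-synonymous mutations as max((ω−1)/ω, 0); the Ig loci
(chr14:106304735–107283226, chr2:89160078–90274237,
chr22:22385390–23263607, GRCh37, 1-based inclusive) are masked before
dN/dS because programmed hypermutation violates its neutral-rate
assumptions. The dN/dS machinery itself is consumed, not reimplemented.

## Synthetic-data generators

Defaults are the study conditions the models estimate: slopes
16/15/17/22/25 SNV/cell/year (HSPC, naive B, memory B, naive T,
memory T), offsets 0/110/1034/59/277 SNV vs HSPC, residual s.d.
70/—/820/—/592, donor s.d. 60, depth 20×. Naive-cell residual s.d. is
not separately characterised for this system; 150 (between the
stem-cell and memory scales) was chosen once as realistic. Depth is
Poisson(colony mean) truncated at ≥ 1. Artifacts draw a site-specific
error probability from Uniform(0.01, 0.05) shared across colonies —
low-VAF noise with no between-colony overdispersion, exactly what the
beta-binomial filter must reject. Somatic variants are private to one
colony with probability 0.8 (a free parameter; the true shared/private
split is unknown) and otherwise shared by a random clade, guaranteeing
overdispersion without simulating a full phylogeny. Feature bins are
Poisson with log-additive smooth links on i.i.d. standard-normal
features. References are i.i.d. uniform A/C/G/T with motifs planted
within 50 bp interior (RAG) or 1,000 bp (CSR) of breakpoints; the first
10% of the contig is the designated Ig–TCR region. Epigenome tracks are
exponentiated AR(1) series (autocorrelation 0.95); mutations are
multinomial with probability ∝ exp(z-scored placement track).

What the generators do *not* emulate: read-level data (no BAMs, base
qualities or alignment artifacts), sequencing-error spectra, a real
coalescent phylogeny, real signature vectors, real feature tracks or
real epigenomes, and linkage between stages (each generator is
independent). Passing tests therefore demonstrate that the estimators
recover the generating truth under the stated noise models — not that
real-data artifact modes beyond those modelled are handled.

## Problem sizes and numerical choices

Tests and the acceptance script run at: filtering 30 colonies × 10,000
sites at 20×; burden recovery 100 (tests) / 30 (script) simulated
cohorts of 4 donors × 5 types × 40 colonies; exposure recovery
50,000-mutation catalogues; timing 4 tracks × 2,000 windows × 20,000
mutations with 150 trees; SVs 200 per replicate with 100 control sets;
feature regression 3,000 bins (selection) and 25,000 bins (effect-size
recovery). EM tolerance 10⁻¹⁰; FISTA tolerance 10⁻⁷, 30-point λ path
over three decades; golden-section 25 iterations; KDE grid 512 points;
score cap 300; PWM score rounding 10⁻⁹ with a 10⁻⁶ comparison guard.

## Known limitations

- The beta-binomial score scale and the valley-depth bimodality
  criterion are package choices; a different statistic would shift
  per-donor cutoffs (the confusion-matrix results are robust to this at
  the simulated separation).
- The mixed model assumes Gaussian residuals; burdens are counts, and
  very low burdens with large variance can simulate negative values
  (clamped, flagged, and rare at realistic scales).
- Group-lasso-on-splines approximates the published penalised-GAM
  tooling; selection agreement is exact only in the sparse/strong-signal
  regime the tests probe.
- PWM consensus matrices are stand-ins; absolute hit rates differ from
  scans with empirically trained matrices, though background correction
  removes the first-order effect.
- Per-Mb exposures fitted against a fixed catalogue stand in for the
  original per-window de-novo extraction; equivalence is assumed, not
  established.
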