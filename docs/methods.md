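# Methods

## Coordinate conventions

In-memory intervals are 1-based and fully closed (`length = end − start + 1`);
this is the only convention under which the five BAC probe sizes shipped in
the default panel are reproduced exactly from their coordinates. BED I/O
converts explicitly to the on-disk 0-based half-open convention. Inter-probe
*genomic distance* is the outermost span (max end − min start + 1), not the
gap or midpoint distance: the span is the convention under which the panel's
printed distance classes (1.3 Mb for #2-#3, 2.6 Mb for #1-#4) follow from
the probe coordinates. Labels round half-away-from-zero to one decimal
(2.550425 Mb → 2.6), and any positive overlap gives the 0.0 Mb class.

The default three-loop annotation (chr15: 25,580,000 / 26,700,000 /
28,360,000 / 28,600,000, hg19-like) is a reconstruction: no exact border
coordinates are published, and schematic figures place GABRB3 ambiguously in
one or two loops. We follow the placement with loop a = {ATP10A, GABRB3},
loop b = {GABRA5, GABRG3, OCA2}, loop c = {HERC2}; loop c is the smallest.
Loop membership uses half-open `[B_i, B_{i+1})` spans with the last loop
closed at B3, so positions at shared anchors are owned unambiguously. All
boundaries are configurable.

## FISH generator

Each nucleus is a sphere of radius 3.5 µm (typical human lymphocyte). Per
homolog, the true inter-probe separation is `d = max(0, Normal(µ, τ))`; the
segment center is uniform in the concentric sphere of radius `R − d/2` (both
endpoints stay inside the nucleus), the orientation is uniform on the
sphere, and each endpoint is perturbed by isotropic Gaussian localization
noise with per-axis SD `σ_loc`. The two homolog centers are rejection-sampled
to be ≥ 2 µm apart, mirroring the experimental practice of scoring only spot
pairs unambiguously assignable to one chromosome. The microscope plane is
fixed as xy (an arbitrary but sufficient choice given isotropic orientation).

The µ calibration table (µm) is the set of measured per-condition means for
the 15q12-q13.1 panel: #2-#3 = 2.2/1.8/0.9 and #1-#4 = 1.3/1.4/1.0 for
AA/AG/GG, and #4-#5 = 0.7 for all genotypes (the overlapping pair is
genotype-invariant by construction). These are generator calibration values,
not a mechanistic model of the loop.

**Rigid mode** (τ = 0, σ_loc = 0) is the reference configuration: no
dispersion values for the biological cell-to-cell variability are published,
so distributional claims are made only where geometry alone determines them.
In rigid mode the projected/true ratio has the closed-form CDF
`F(x) = 1 − sqrt(1 − x²)`, which the generator reproduces to
Kolmogorov–Smirnov D < 0.01 at 10⁵ homologs. A biological-variability mode
(τ > 0) exists for qualitative exploration — e.g. non-significant contrasts
between near-equal means emerge only with dispersion — but is not used for
quantitative checks.

One root seed per cohort spawns one deterministic substream per nucleus
(`numpy` `SeedSequence.spawn`), so cohorts are bit-reproducible and
independent of iteration order. By default one homolog measurement per
nucleus enters the analysis (matching "one distance per scored nucleus");
pooling both homologs is a config flag.

What the generator does **not** emulate: microscope image formation and spot
segmentation, chromatic shift, nuclear shape irregularity, chromatin polymer
dynamics, or any genotype mechanism — passing tests validate the estimator's
geometry and the pipeline's statistics, not the biology of the locus.

## Top-k estimator and comparisons

`topk_distances` takes the k = 40 largest of n ≥ 200 distances (fixed count,
not a fraction; ties broken by input order) and reports their mean and SD.
The estimator's justification is quantitative: the mean of the top quintile
of projection factors is `∫ x²/√(1−x²) dx` over the top-20% tail, ≈ 0.9933,
versus π/4 ≈ 0.785 for the full sample; a Monte-Carlo oracle
(`estimator_bias_oracle`) reproduces both limits.

Comparisons use the two-sided **pooled-variance** Student's t-test (the
unqualified "Student's t-test"; not Welch) applied to the two top-40
subsets. The non-iid nature of order statistics is deliberately replicated,
not corrected, because the reported means are themselves top-40 means. No
multiple-testing correction is applied; tiers are reported per comparison
(* p<0.05 … **** p<0.0001). Degenerate zero-variance inputs return p = 1
(equal means) or the p → 0 limit (unequal means). The t statistic is
computed from the textbook pooled formula and cross-checked against
`scipy.stats.ttest_ind` to 1e-10 in the test suite.

`compare_conditions` emits the full cross table — probe pairs within each
genotype and genotypes within each probe pair — plus a per-genotype
`loop_signature` flag marking whether the 1.3 Mb loop-interior pair lies
farther apart in the nucleus than the 2.6 Mb anchor pair (the spatial
signature of an open loop structure; true for AA/AG, absent for GG under the
default calibration).

## Contact-map simulator and domain caller

`C_ij = (|i−j|+1)^(−α) · (1 + e·[same loop]) + a·(|i−j|+1)^(−α)·[anchor corner]`
with defaults α = 1 (Hi-C-like decay), enrichment e = 2, anchor peak a = 5×
the background at that distance, 25 kb bins over the annotated span (last
bin padded). "Poisson noise applied at rate λ" means count sampling:
`C′ = Poisson(λ·C)/λ`, then symmetrization — the standard sequencing-depth
model; λ ≈ 100 at 25 kb bins (≈ 300 expected diagonal counts) corresponds to
a deeply sequenced map.

The insulation score of bin b is the mean contact in the w×w square crossing
it (`i ∈ (b−w, b]`, `j ∈ (b, b+w]`), undefined within w bins of the matrix
edge. The window is specified in bp (default 200 kb = 8 bins at 25 kb) so
the same genomic scale is used at every bin size; at 50 kb bins a fixed
8-bin window would not fit inside the ~61-bin matrix. `call_domains` smooths
the profile with a 3-bin moving average (the usual guard against single-bin
noise dips; it does not move noiseless boundary positions), finds local
minima with prominence ≥ 10% of the profile range, and returns the spans
between {region start, minima, region end}. Domains are counted only inside
the annotated region; flanking background is not a domain.

Validation is internal: the caller is checked against the simulator's own
ground truth (boundaries within ±1 bin at 10/25/50 kb bins; 3-domain calls
stable in ≥ 18/20 noise seeds at deep coverage; invariance to positive
scaling and transpose). At shallower depth (λ = 50) the call is correct in
16/20 seeds — boundary positions remain correct, extra minima occasionally
pass the prominence threshold. No quantitative loop-calling criterion exists
for the real maps, which were inspected visually; this module demonstrates
that the annotated three-loop structure is recoverable from contact data of
that shape, no more.

## Synteny checks

Gene position is the interval midpoint (robust to nested/overlapping
annotations). Orientation concordance between two species requires the same
midpoint order and per-gene strands, either directly or after a whole-region
inversion (order reversed, every strand flipped), which is tolerated and
flagged — the interpretation adopted for "same position and orientation"
across lineages; a single-gene strand flip breaks both matchings. The
head-to-tail test for HERC2→OCA2 requires co-orientation, no intervening
panel gene, and the strand-aware 3′ terminus of HERC2 to be the endpoint
facing OCA2 with transcription continuing across it; it is invariant under
whole-region inversion and translation. A species is *conserved* when it is
order/orientation concordant with human and head-to-tail.

The packaged per-species tables are **synthetic fixtures**: the human table
uses hg19-like gene coordinates; the other seven (chimp, mouse, shrew,
chicken, lizard, xenopus, zebrafish) are constructed by translating,
rescaling (0.35–0.8× intergenic scale for compact genomes) or — for mouse —
mirror-inverting the human arrangement. They emulate the published
cross-vertebrate gene-order comparison and define the module's test
conditions; they are not extracted from genome assemblies.

## Problem sizes and numerical choices

Default cohorts are 200 nuclei per condition (the study's per-condition
floor) with k = 40; the distributional KS check uses 5×10⁴ nuclei (10⁵
homolog measurements); the bias oracle uses 2000 replicates; contact maps
are ~121 bins at 25 kb. A full test run plus the acceptance script completes
in well under two minutes on one CPU. Seeds are explicit everywhere;
derived seeds stay below 2³¹. Rounding of Mb labels is decimal
half-away-from-zero, not banker's rounding.

## Known limitations

- The loop-boundary coordinates are a configurable reconstruction, not
  published values.
- Rigid mode cannot reproduce *non*-significance between near-equal
  condition means (e.g. the GG-genotype pair contrast): with zero biological
  dispersion the top-40 subsets have tiny variance and any mean offset is
  formally significant. Replicating "ns" requires τ > 0, for which no
  published dispersion exists; it is treated as a qualitative property only.
- The contact-map module is a toy: it validates the caller against its own
  generative structure and makes no claims about real Hi-C maps.
- Synteny correctness is defined against the packaged synthetic fixtures
  plus the stated qualitative claims, not against genome databases.
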