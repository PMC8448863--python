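# Methods

This note records the models, numerical choices, and design decisions behind
each analysis stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Adipocyte histomorphometry

**Model.** Bone-marrow adipocytes in H&E sections are lipid-dissolved
("empty") vacuoles: bright, locally smooth, roughly elliptical, bounded by a
thin darker rim, on eosin-pink, cellular (textured) marrow. Segmentation
exploits exactly two local properties — high luminance and low local
variance — rather than colour, so it is robust to stain variation.

**Stages and parameters.**

- *Neighbourhood features.* Luminance (ITU-R 709 weights, 0–255) is filtered
  with a moving median and a moving standard deviation over a (2r+1)² window
  (default r = 3 px; reflected borders), plus their product as a combined
  bright-and-textured channel. The median suppresses shot noise without
  displacing edges; the standard deviation measures texture.
- *Thresholding.* A pixel is adipocyte-candidate when median-luminance ≥
  luminance threshold AND texture ≤ texture threshold, inside the ROI;
  interior holes are filled. `"auto"` thresholds use Otsu's histogram split
  of the channel restricted to the ROI (upper class kept for luminance,
  lower for texture); a constant channel makes Otsu meaningless and raises
  an error asking for a fixed threshold. The texture condition is evaluated
  on the grey-erosion (moving minimum over the same window) of the std
  channel: the raw std channel is inflated in a band of one window radius
  around every object boundary simply because the window straddles the
  edge, and AND-ing it directly would erode each object by that band
  (≈25–30% area bias at typical sizes). The erosion formulation — "a pixel
  is smooth if it belongs to at least one smooth neighbourhood" — keeps the
  boundary where the luminance channel puts it; measured area error on the
  synthetic benchmark is ≈1%.
- *Cluster separation.* Touching vacuoles are split by watershed on the
  negated Euclidean distance transform. Seeds are distance maxima with ≥1 px
  prominence (h-maxima, which removes discretisation plateau maxima inside
  a single convex vacuole) thinned to a minimum separation (default 15 µm);
  a blob whose seeds all merge keeps one label. Watershed regions partition
  the foreground, so total labelled area equals the input mask area exactly.
- *Shape filter.* Objects are kept when min_area ≤ A ≤ max_area (defaults
  200–15,000 µm², bracketing human bone-marrow adipocyte diameters of
  ~15–140 µm) and form factor 4πA/P² ≥ 0.5. Defaults are configuration,
  not constants; all geometry is reported in physical units from the
  image's pixel size (default 0.25 µm/px for ×20 scans when no metadata is
  available).
- *Perimeter estimator.* P is measured on the pixel-boundary ("crack")
  polygon with a turn-local staircase correction: at every 90° turn whose
  adjacent straight runs have minimum length 1 — the signature of a
  digital-line staircase, never of a true corner — the length is reduced by
  ((k+1) − √(k²+1))/2, k being the longer adjacent run. The estimator is
  exact for axis-aligned rectangles (2(w+h)) and for ideal digital straight
  segments of every slope; on rasterised disks r = 10–60 px it yields form
  factors 0.987–1.008. A discretisation tolerance ε = 0.05 is allowed on
  the FF ≤ 1 bound.
- *Morphometry.* Count, size list, and density = count / ROI area (mm²);
  excluded regions never dilute density because the ROI area is the
  denominator. Objects touching the image border are kept by default
  (configurable), since a biopsy ROI rarely coincides with the frame.
- *Group comparison.* Two-sided Mann–Whitney U with mid-rank ties; exact
  p by complete enumeration of the C(n_a+n_b, n_a) assignments when
  n_a+n_b ≤ 12 (two-sided p = 2·min(P[U ≤ u], P[U ≥ u]) capped at 1),
  normal approximation with tie correction otherwise.

## XIC phosphopeptide quantification

- *Extraction window.* |m/z − target|/target ≤ 10 ppm and |rt − apex| ≤
  30 s by default; the chromatography this models produces peaks ~30 s wide
  at the base sampled by ≥10 MS1 points, which motivates both defaults and
  the minimum point count.
- *Peak height.* The maximum point intensity in the trace, reported only
  when the trace has ≥ min_points points; no smoothing and no fitted apex by
  default (an optional 3-point moving average exists). Missing measurements
  stay missing — never imputed.
- *Normalisation.* Each sample's heights are divided by that sample's total
  and rescaled by the mean of the original totals, so per-sample global
  scale factors cancel exactly while magnitudes stay interpretable. The
  rescale choice is cosmetic: fold changes are identical either way. Note
  the inherent composition effect: if regulation is asymmetric (say 10% of
  peptides doubled in one condition), total-intensity normalisation shifts
  every other peptide by the complementary factor (−log₂(1.1) ≈ −0.14).
- *Differential testing.* Fold change = mean(log₂ B) − mean(log₂ A)
  (mean-of-logs, not log-of-mean-ratio); two-sided equal-variance Student t
  on log₂ heights (Welch by flag); tested only with ≥2 present values per
  condition; BH across tested peptides. Zero-variance degenerate rows yield
  NaN p rather than a fabricated value.

## Enrichment statistics

- *Hypergeometric upper tail.* P[X ≥ k], inclusive, computed with
  log-gamma arithmetic summed from the larger tail term; validated against
  exhaustive draw enumeration for all instances with N ≤ 12 and against an
  independent implementation at larger N.
- *Fisher two-sided.* Point-probability rule: sum of all same-margin tables
  whose probability ≤ observed × (1 + 10⁻⁷); the tolerance makes the rule
  robust to floating-point ties.
- *BH.* Step-up q_(i) = min_{j≥i} m·p_(j)/j clipped at 1; the rejection set
  {q ≤ α} provably equals the classical step-up rule, which the tests check
  on random p-vectors.
- *KSEA.* Universe N = peptides mapping to ≥1 substrate set (a flag switches
  to all detected): restricting to annotatable sites avoids inflating N
  with sites no kinase could claim. Significant peptides (raw p < 0.05)
  are split by fold-change sign, each direction tested separately per
  kinase, BH pooled across kinase×direction tests (a flag corrects within
  direction). Peptides annotated to several kinases count for each. The
  z score z = (mean member FC − mean FC)·√m / sd(FC) is isolated in one
  function so the formula can be swapped; classification is inclusive at
  ±1.5.
- *Calibration diagnostic.* The inclusive p of a discrete test is
  super-uniform by construction (for a 30-substrate set in a 1000-peptide
  universe, k takes ~3 likely values, with a large atom at p = 1), so no
  deterministic transform of it can pass a KS uniformity test. The package
  therefore exposes `ksea(p_mode="randomized")`, the randomized PIT
  P[X > k] + U·P[X = k], which is exactly Uniform(0,1) *iff* the null CDF
  and the universe/count construction feeding it are correct — a sharp
  implementation check used in the benchmarks. Inference always uses the
  inclusive tail.

## Pulsed-SILAC co-regulation

- *Filtering.* Sequential removal — decoy (reverse) hits, potential
  contaminants, proteins identified only by modified peptides, then records
  with no valid H/M ratio — with per-rule counts; input = output + Σ
  removals by construction.
- *Normalisation.* log₂ then per-timepoint median-centring (mean-centring
  by flag); multiplying all ratios at one timepoint by a constant changes
  nothing downstream.
- *Classification.* Co-down = centred log₂ < −margin at both timepoints
  (margin 0 by default: sign-based, since no magnitude cutoff is imposed);
  co-up symmetric; discordant = opposite signs; one-timepoint proteins stay
  unclassified. With balanced designs (≈50% regulated) median-centring
  places the cut between the two modes and recovery is essentially exact.
- *Pathway report.* Universe = all proteins surviving the filters; per
  pathway a two-sided Fisher test on (co-down vs not) × (in pathway vs
  not), BH across pathways; the report keeps q ≤ 0.05 AND enrichment
  factor > 2, sorted by enrichment factor — the layout used for
  newly-synthesised-proteome pathway tables.

## Synthetic generators

What they emulate: the statistical structure each stage assumes. Marrow
images: bright low-variance elliptical vacuoles (axis ratio ≤ 1.6, so
planted objects stay above the default form-factor cut), darker 2 px rims,
eosin-pink tissue with spatially correlated cellularity texture (Gaussian
field, σ = 1.5 px, amplitude 14) plus sensor noise (σ = 6), ROI as a
biopsy-core ellipse, optional dark artifact bands excluded from the ROI;
touching pairs overlap by 10–30% of the smaller radius so distance-transform
maxima stay distinct. Sizes are lognormal (median diameter 40 µm, σ_log
0.25) at 1 µm/px. Phospho: Gaussian elution peaks (base width 30 s ≈ 4σ,
12 points at fixed spacing, one point exactly at the apex so zero-noise
recovery is exact), ppm-level m/z jitter, lognormal between-sample amplitude
noise, planted fold changes and kinase substrate sets plus decoy kinases.
SILAC: disjoint flag groups, planted co-down fraction (default 0.3) with
effect −1 and log₂ noise 0.1, planted pathways concentrating 90% of their
members in the co-down truth versus the 30% background, universe ≈ 470
after filtering.

What they do not emulate — and hence what passing tests do not show about
real data: stain/scanner variation, out-of-focus regions, marrow cellularity
gradients, non-adipocyte bright structures (sinusoids, processing tears
inside the ROI); chromatographic tailing, co-eluting isobaric interference,
retention-time drift between runs, intensity-dependent (heteroscedastic)
noise; peptide-to-protein roll-up ambiguity and shared peptides. Recovery
rates measured here are upper bounds for real slides and runs.

**Generators are specifications, not dials**: their defaults define the
benchmark conditions, and the acceptance numbers are measured at those
defaults.

## Reproducibility and numerics

- Every stochastic function takes an explicit seed; there is no global
  random state. Pipeline runs derive per-stage seeds as
  (seed·1000003 + CRC32(stage)) mod 2³¹, so stages can be re-run alone.
- Tabular outputs carry a comment header with the package version and a
  digest of the analysis-relevant config (output paths excluded), making
  re-runs byte-identical.
- Benchmark problem sizes: 20 images × 50 adipocytes for morphometry, 500
  peptides (recovery) and 2,000 peptides (null) for quantification, 100
  simulations for KSEA rank recovery and SILAC pathway detection, 500 for
  the permutation-null uniformity check. The many-replicate enrichment
  simulations use the generator's amplitude layer directly
  (`gen_phospho_matrix`); the chromatographic layer is exercised separately
  by the XIC benchmarks, which verify that the two layers agree exactly at
  zero noise.

## Known limitations

- The neighbourhood-filter protocol is one published interpretation of a
  loosely described commercial pipeline; the original's filter order and
  thresholds are proprietary. All parameters are config-exposed for that
  reason.
- Whether a commercial "size" output means area or diameter is ambiguous;
  area in µm² is reported.
- Watershed separation assumes touching objects keep distinct distance
  maxima; deeply merged vacuoles (overlap ≫ 30% of radius) fuse into one
  object.
- Sum normalisation's composition effect (above) biases unregulated fold
  changes when regulation is strongly asymmetric; the null-calibration
  benchmark uses a symmetric (unregulated) design on purpose.
- The SILAC pathway 2×2 uses the filtered-protein universe; with a
  different universe convention (e.g. only co-regulated proteins) the
  enrichment factors change accordingly.
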