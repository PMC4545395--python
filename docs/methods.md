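# Methods

This note records the models implemented in `cardiofuse`, the assumptions
behind them, the numerical choices, and what the synthetic-data studies do
and do not demonstrate.

## STAPLE label fusion

Binary STAPLE treats the unknown true segmentation as a latent per-pixel
label and each rater's mask as a noisy observation characterized by a
sensitivity *p<sub>j</sub>* and specificity *q<sub>j</sub>*. With decisions
D<sub>ij</sub> and a foreground prior γ<sub>i</sub>, EM alternates

- E-step: W<sub>i</sub> = α<sub>i</sub>/(α<sub>i</sub>+β<sub>i</sub>),
  α<sub>i</sub> = γ<sub>i</sub> ∏<sub>j</sub> p<sub>j</sub><sup>D<sub>ij</sub></sup>(1−p<sub>j</sub>)<sup>1−D<sub>ij</sub></sup>,
  β<sub>i</sub> = (1−γ<sub>i</sub>) ∏<sub>j</sub> q<sub>j</sub><sup>1−D<sub>ij</sub></sup>(1−q<sub>j</sub>)<sup>D<sub>ij</sub></sup>;
- M-step: p<sub>j</sub> = Σ<sub>D<sub>ij</sub>=1</sub> W<sub>i</sub> / Σ W<sub>i</sub>,
  q<sub>j</sub> = Σ<sub>D<sub>ij</sub>=0</sub> (1−W<sub>i</sub>) / Σ (1−W<sub>i</sub>).

Choices, with rationale:

- **2D per slice, stacked.** Short-axis voxels are ~1.25 × 1.25 × 8 mm;
  a 3D neighbourhood mixes slices that are almost independent anatomically.
  Per-slice fusion is the only mode.
- **Initialization** p = q = 0.99 (a conventional "raters are good"
  default); **convergence** when no p or q moves more than 1e-7, at most
  200 iterations. The observed-data log-likelihood is tracked and is
  provably non-decreasing; a final E-step after convergence makes the
  returned posterior consistent with the returned (p, q).
- **Prior γ**: spatially uniform, equal to the mean foreground fraction of
  the rater masks inside the region of interest. Combined with cropping to
  the union bounding box (plus a 2-pixel margin) this makes the fused
  result bit-identical under arbitrary background padding.
- **Ties** at W = 0.5 binarize to background — deterministic and
  conservative about cavity size.
- **Degenerate inputs**: a rater with an empty mask on a slice is excluded
  from that slice's EM (performance reported as NaN) instead of having its
  specificity driven to a boundary; an all-empty slice yields an empty
  consensus flagged degenerate.

## Cardiac indices

Volumes are slice sums: V = Σ (foreground pixels × pixel area) ×
thickness / 1000 ml, with no inter-slice interpolation (contiguous slices,
2D processing). The defaults encode a 320 mm field of view on a 256×256
matrix (1.25 mm pixels) and 8 mm slices. From ED/ES endocardial volumes
and the ED epicardial volume: SV = EDV − ESV, LVEF = SV/EDV,
MM = 1.05 × (EpV − EDV) (myocardial density 1.05 g/ml). LVEF ≤ 0.45 is
flagged as the reduced/pathological regime. ESV > EDV is physically
impossible; such rows are flagged, never silently dropped (an optional
range filter exists for outlier re-analyses, off by default).

Contour rasterization is pixel-center, even-odd, with half-open edges
(y<sub>min</sub> ≤ y<sub>center</sub> < y<sub>max</sub>): the convention
is part of the contour-file contract and is implemented explicitly so that
volumetry is bit-reproducible; library point-in-polygon routines leave
on-edge pixel centers unspecified.

## The eRWT latent-truth model

Assumptions: (1) the true biomarker has finite support, modeled as
Beta(μ, ν) on the unit interval (other biomarkers are affinely mapped to
it via a configured range); (2) each method is linear in the truth with
Gaussian noise; (3) errors are independent across methods. The marginal
likelihood integrates the latent value out; maximizing it over all
(a<sub>k</sub>, b<sub>k</sub>, σ<sub>k</sub>) jointly yields the
parameters, and the figure of merit
F<sub>k</sub> = E[(Θ − a<sub>k</sub>Θ − b<sub>k</sub> − ε)²] is evaluated
in closed form.

Defaults and numerics:

- **Beta shape** defaults to (μ, ν) = (2.85, 3.40); shape refinement
  (`tune_beta_shape`) starts from (4, 5) and minimizes the summed figures
  of merit by Nelder-Mead on (log μ, log ν) with inner warm-started refits
  (tolerance 1e-3 on ΣF).
- **Quadrature**: Gauss-Legendre on (0, 1), 64 nodes by default. The
  integrand's width is of order the smallest σ, so the node count adapts
  upward to ≈ 2.5/σ (estimated from the data, capped at 768) — without
  this, nearly noiseless methods fit with distorted slopes. Resolutions
  below σ ≈ 3·10⁻³ on the unit scale are not attempted; that is the
  practical noise floor of the fit.
- **Optimization**: bounded L-BFGS-B on (a, b, log σ) with an analytic
  gradient (numba-compiled kernel), bounds a ∈ [0.2, 2], b ∈ [−0.5, 0.5],
  σ ∈ [1e-4, 0.5]. The default is a *local* fit from a single moment-based
  identity-anchored start (a = 1, b = 0, σ from per-subject cross-method
  deviations), or from a caller-supplied warm start. σ = 0 is rejected:
  two identical columns make the likelihood unbounded, which is why the
  generator never emits exactly duplicated methods and why σ is bounded
  below.
- **Why not global search.** With the Beta prior fixed and a > 0 enforced
  the model is formally identifiable, but identification of the latent
  *location and scale* rests entirely on the prior. When the cohort is
  multimodal (normal plus reduced-function subgroups — the typical clinical
  structure) and the prior unimodal, the likelihood grows additional modes:
  location-shifted solutions in which every method absorbs a common bias so
  the latent values fit the prior bulk better, and noise-dominated
  solutions that declare closely agreeing methods mostly noise. These can
  exceed the identity-anchored mode in likelihood while scrambling the
  figures of merit, and a common shift is precisely what no truth-free
  method can detect. The fit therefore stays local around the
  consensus-is-unbiased convention; if `multistart > 1` is requested, a
  plausibility guard discards solutions whose median intercept, median
  slope, or noise-to-consensus-residual ratio strays far from that
  anchoring, falling back (with a warning) to the best likelihood only if
  no start passes.

## Bootstrap ranking

N subject-level resamples (default 1000; the same resampled rows for every
method, preserving inter-method dependence) are each refit — warm-started
from the full-data solution, one start, relaxed tolerances, one fixed
quadrature across all draws so FoM spread reflects resampling only. A
Kruskal-Wallis omnibus test runs on the N × K figures of merit; if it
rejects at α = 0.05, all pairs are compared by two-sided Mann-Whitney U at
the Bonferroni level α/(K(K−1)/2). Methods are ordered by median FoM and
adjacent non-significant pairs merge into tie groups (non-adjacent
non-significance is logged, not merged). The omnibus test names the only
test the procedure strictly requires; Mann-Whitney is the natural
rank-based pairwise companion. Because bootstrap columns share resamples,
pairwise p-values are heuristic ordering devices, not calibrated error
rates — every ranking result carries that caution string.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

- **Cohort**: 45 subjects in four subgroups — heart failure ischemic
  (n = 12, LVEF ≈ 0.26) and non-ischemic (n = 12, ≈ 0.32), hypertrophic
  (n = 12, ≈ 0.64), controls (n = 9, ≈ 0.64) — with per-subgroup Beta
  truth regimes (mean/concentration parametrization) and dilated ED
  volumes for the failure subgroups (≈ 210–220 ml vs ≈ 120–130 ml).
- **Masks**: stacked discs whose radii fall off elliptically from base to
  apex (9 slices, 8 mm); end-systole scales all radii by √(1 − LVEF), so
  the rendered ejection fraction matches the latent truth up to
  rasterization error (±0.03 in practice). Papillary muscles are two small
  discs inside the cavity, part of the blood pool by convention.
- **Raters** displace the true boundary along its signed distance field:
  a constant radial bias (mm) plus a smooth angular jitter field (Fourier
  series, 6 harmonics, pointwise SD = the configured jitter). The signed
  distance is measured to the sub-pixel (marching-squares) boundary, not
  to the pixel lattice — otherwise any offset below the 1.25 mm pixel
  pitch would do nothing at all, and sub-millimetre expert jitter would
  silently produce raters identical to the truth (a degenerate input for
  the likelihood). Default profiles: three expert-like raters (|bias| ≤
  0.2 mm, jitter 0.4–0.6 mm) and five automated-like raters (bias −2.0 to
  +2.2 mm, jitter 1.0–1.8 mm, one of which excludes the papillary
  muscles), mirroring the over-/under-delineation patterns automated LV
  methods show.
- **Streams**: every subject × rater pair draws from its own
  `SeedSequence` spawn key, so adding raters or subjects never perturbs
  existing draws; everything is reproducible from one integer seed.

What passing tests show — and do not. The generator produces exactly the
statistical structure the model assumes (linear response, Gaussian noise,
independent errors, star-shaped single-cavity masks). Success on it
validates the inference machinery, not the model's adequacy for real
cine MRI: real contours have non-elliptical cavities, spatially correlated
multi-rater errors, outflow-tract ambiguity at the base, and intensity
artifacts none of which are simulated. The boundary-error model is
illustrative: the spatial error statistics of real automated methods are
not publicly characterized.

## Pipeline and problem sizes

The end-to-end run fuses every subset of ≥ 3 of the 5 automated raters
(10 + 5 + 1 = 16 candidates, named `MS` + member indices), computes LVEF
matrices, the supervised bias report against a configurable reference
rater, and one eRWT bootstrap ranking per candidate (the 8 original raters
plus that candidate — the held-out-candidate protocol). A candidate counts
as "expert level" when its tie group is within or adjacent to the worst
expert's group.

Test-suite and acceptance runs use deliberately desk-scale sizes chosen to
keep each study a few minutes on one CPU while leaving its conclusion
stable across seeds: Monte-Carlo FoM checks at 10⁶ draws; parameter
recovery at P = 500, K = 5; ordering studies at P = 200, K = 3 over 50
replicates; the end-to-end headline at 45 subjects, N = 200 bootstrap
draws, 20 replicates (the full N = 1000 is the library default for real
analyses). The acceptance script repeats the headline at 6 replicates and
the 16-candidate run at N = 60.

## Known limitations

- eRWT assumes error independence across methods (H3). STAPLE candidates
  are built *from* the automated raters, so candidate-vs-component
  comparisons stretch that assumption; this is inherent to the design and
  shared by the ranking protocol itself.
- The σ floor (1e-4) plus quadrature cap means methods better than
  σ ≈ 3·10⁻³ on the unit scale are statistically indistinguishable from
  each other — they tie at the resolution floor rather than being ordered.
- Epicardial simulation is a uniform wall-thickness dilation; MM studies
  on synthetic data therefore exercise plumbing, not anatomy.
- Missing estimate cells are reported, never imputed or marginalized; the
  eRWT fit requires complete matrices.
- Phase selection (which frames are ED/ES) and basal/apical slice-range
  selection are treated as fixed inputs throughout.
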