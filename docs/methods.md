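# Methods

This note records the models behind `fociscreen`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## The assay being modelled

Peripheral blood lymphocytes are split three ways per individual: an
unirradiated control (*preexisting* γH2AX foci), a sample fixed 30 min
after 0.5 Gy ex vivo X-rays (*initial* foci, near the phosphorylation
peak — a low dose, because 2 Gy at 30 min produces uncountably dense
foci), and a sample fixed 24 h after 2 Gy (*remaining*, i.e. unrepaired,
foci — a high dose, because 0.5 Gy leaves too few after repair). Cells
are imaged in five optical planes 0.75 µm apart, flattened by maximum
intensity (lymphocyte nuclei are rounded, so single planes miss foci),
and foci are counted per nucleus. The screening signal is each
individual's mean foci per cell, per condition.

## Synthetic cohort model

Per individual *i*, group *g*, condition *c*, the latent rate is

λ_ic ~ TruncNormal(μ_gc, τ_c²) on [0.05, ∞),

multiplied by the outlier effect on the conditions the individual's
planted class affects, and cell counts are negative-binomial with mean
λ and variance λ(1 + φλ) (φ = 0 recovers Poisson). Defaults:

| parameter | default | rationale |
|---|---|---|
| group sizes | 59 HI, 136 RC | the screening cohort sizes |
| μ (preexisting) | 0.49 / 0.59 foci/cell (HI / RC) | reported group means |
| μ (remaining) | 2.63 / 2.97 foci/cell | reported group means |
| μ (initial) | 5.0 foci/cell, both groups | no mean is reported for this arm; 5 foci/cell after 0.5 Gy at 30 min matches the usual ~10 foci·cell⁻¹·Gy⁻¹ induction rate in lymphocytes. Uncalibrated placeholder; no group difference, as observed |
| τ (between-individual SD) | 0.15 / 1.0 / 0.60 foci/cell (pre / init / rem) | ≈ 25–30 % coefficient of variation on the rate scale, a typical inter-donor spread for this assay; Gaussian on the rate scale because the observed individual-mean histograms are approximately Gaussian |
| φ (within-individual dispersion) | 0.5 | mild overdispersion from field-to-field staining and focus-crowding variation; pure Poisson is available via φ = 0 |
| outlier fraction | 12 % of patients, 0 % of healthy | the observed outlier prevalence |
| outlier effect | ×2.5 on affected conditions | places planted outliers ≈ 6–7 τ above the group mean, the "distinct" separation seen in the real scatter |
| class weights | ⅓ / ⅓ / ⅓ over {preexisting-only, both, remaining-only} | the three observed outlier groups were equally sized (n = 8 each) |
| cells per individual | 1000 | the assay's target score count |

The planted truth (per-individual λ and class) is emitted next to every
table; only tests and benchmark code may read it.

The image generator places non-overlapping nuclei (radius 14–20 px at
0.2 µm/px, i.e. 5–8 µm diameter lymphocyte nuclei) with ≥ 12 px edge
gaps, plants Poisson-distributed foci uniformly inside 80 % of each
radius with ≥ 8 px pairwise separation, and renders: DAPI disks with a
logistic edge profile and mild axial fall-off; each focus as an
isotropic 2-D Gaussian (σ = 1.8 px) at full amplitude on its plane,
attenuated axially with σ_z = 0.9 µm; additive Gaussian read noise on a
constant background; uint16 quantisation. Apoptotic nuclei are rendered
as 3–4 condensed fragments on a ring instead of one disk.

**What this does not emulate:** spatially varying illumination or
staining, focus-intensity variation between foci, overlapping or
clustered foci, densely touching cell monolayers, autofluorescent
debris, and any optics beyond a separable Gaussian PSF. The 8 px focus
separation matters: two diffraction-limited spots closer than roughly
their PSF diameter are not resolvable as distinct foci by any counter,
so the image benchmark certifies the pipeline on resolvable foci only.
Passing tests therefore show the pipeline is correct and calibrated on
clean, resolvable material — not that it would match human scorers on
crowded 2 Gy/30 min images, which the assay itself avoids by design.

## Imaging pipeline choices

The production counting software used in screening practice is
proprietary and unpublished, so the detector here is a standard,
fully-specified choice: scale-normalised Laplacian-of-Gaussian over
σ ∈ [1.2, 3.0] px (five geometric steps, ≈ 0.4–1 µm foci), maximum over
scales, local maxima with ≥ 4 px spacing and prominence above 8× a
robust (MAD-based) estimate of the response's background SD. Prominence
is measured on the LoG response, which is invariant to uniform intensity
offsets — hence counts cannot depend on background level. The 8-SD
default reflects that the smallest LoG scale carries ~1.5× the noise SD
of the pooled response MAD; at the assay's SNR the threshold is
uncritical for true foci.

Counting is deliberately mask-local: the nucleus crop is padded, pixels
outside the mask are replaced by the in-mask median, and peaks are
restricted to the mask, so editing the image anywhere else can never
change a nucleus's count (a tested invariant).

Segmentation applies Otsu thresholding to the projected DAPI channel,
fills holes, drops < 25 px debris, and handles three object types:
components within the nucleus area bounds (derived from a 5–10 µm
nucleus diameter at the configured pixel size) are candidate nuclei;
clusters of ≥ 3 sub-nuclear fragments within a 5 px merge radius are
kept as single multi-fragment objects for the apoptotic QC (they bypass
the area bounds, which describe intact nuclei); smaller fragment groups
are dropped as debris. Touching nuclei are split by distance-transform
watershed, with two guards: only near-convex components are split
(solidity ≥ 0.8 — a concave object is not a touching pair and belongs to
QC), and only distance maxima at least 0.6× the minimum nucleus radius
count as markers (ridge maxima of thin shapes must not trigger splits).
The by-eye apoptotic exclusion of screening practice is replaced by two
objective rules — ≥ 3 fragments ("fragmented") or solidity < 0.8
("low-solidity") — so the exclusion is testable against planted truth.
Whether touching lymphocytes are split or the merged object discarded is
configurable (`split_touching`, default on).

Coordinates are 0-based and pixel-centred; masks are boolean arrays in
half-open bounding boxes.

## Sufficiency statistic

Agreement(n) = 100 × (cumulative mean over the first n cells) / (mean
over the first N cells), N = min(all scored, 1000), evaluated every 200
cells plus at N, in acquisition order (an optional seeded permutation
mode exists for robustness checks). The self-ratio makes agreement(N)
exactly 100 % — the implementation computes the ratio before scaling so
this holds in floating point, and a test asserts exactness. A classical
two-method Bland–Altman plot can be derived from the same curves but no
decision uses it. An individual whose reference mean is zero has
undefined agreement; the curve is flagged and excluded from cohort
aggregation rather than erroring.

Under pure Poisson counts the cumulative-mean ratio at 600 of 1000 cells
has SD ≈ √((1/μ)(1/600 − 1/1000)) — about 1.6 % at μ = 2.63 and 3.7 % at
μ = 0.49 — so essentially every individual sits inside ±15 % by 600
cells. Real cohorts reach only ~75 % at 600, which is therefore a
signature of within-individual heterogeneity, not counting noise; the
package reproduces it qualitatively with strong overdispersion (φ ≈ 20
drops the fraction at 600 cells to ~70–85 %). The 75 %-at-600 /
95 %-at-800 figures are treated as data-dependent observations, not as
constants of the method.

## Cohort statistics

*Fits.* `moment` (sample mean, SD with n−1) is the default: it is
deterministic and assumption-free. `binned-least-squares` reproduces the
histogram-fit procedure (Freedman–Diaconis bin width unless given;
amplitude/μ/σ by `curve_fit` with median/MAD initialisation). The binned
fit locks onto the main mode and is therefore robust to a heavy upper
tail — which is exactly why it is the default *reference* fit for
outlier classification in the pipeline: fitting moments to a cohort that
contains the outliers one is trying to find inflates σ so much that a
2-SD cut loses ~25 % of even 6-σ outliers, while the mode fit keeps the
reference anchored to the unaffected majority.

*Normality.* The KS p-value treats fitted parameters as known (the
classical test, anticonservative with estimation); the Lilliefors test
corrects for estimation with a seeded Monte-Carlo null (default 10⁴
replicates, add-one p-value estimator) rather than table lookup, so any
n is supported and results are exactly reproducible. Calibration is
itself tested: the type-I error at α = 0.05 over 10⁴ null replicates
must lie in [0.04, 0.06].

*Outlier rule.* One-sided, above the mean: k is the largest j ∈ {1,2,3}
with value > μ + jσ. One-sided because the screening question is
elevated damage only, and because observed self-referenced >1 SD rates
sit near the one-sided expectation (15.9 %), not the two-sided (31.7 %).
Exceedance tables are emitted against both the healthy and the patient
reference. The taxonomy uses the patient reference at k ≥ 2 (the 2-SD
cut corresponds to the upper tail beyond the 95 % range) and combines
the preexisting and remaining conditions; the initial condition
participates in fits and group comparison but not in the taxonomy.

*Planted-outlier recovery.* Any k-SD rule flags, besides planted
outliers, the intrinsic Gaussian tail of ordinary individuals —
expectation 1 − (1 − Φ̄(k))² ≈ 4.5 % at k = 2 over two conditions. The
benchmark therefore reports a background-corrected estimate,
p̂ = (raw − p_bg)/(1 − p_bg), the standard correction for a known false-
positive rate, and scores each replicate by whether the realised planted
fraction lies in the estimate's binomial 95 % CI. Uncorrected rates are
reported alongside.

*Multiple testing.* None is applied across the three condition-wise
t-tests by default (matching screening practice); Holm-adjusted p-values
can be derived from the comparison report if desired.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` with explicit
seeds; identical parameters and seed give bit-identical tables, and the
pipeline manifest records seed, config hash and library versions so a
run can be reproduced byte-for-byte (image rendering excluded from
byte-identity; its derived counts included). The benchmark sizes — 10⁵
individuals for the analytic-tail check, 520 rendered nuclei for the
imaging benchmark, 100 replicate cohorts of 136 patients for outlier
recovery, 10⁴ Monte-Carlo replicates for Lilliefors — were chosen so
each statistical tolerance is several standard errors wide at that size.

## Known limitations

- The initial-condition (0.5 Gy/30 min) parameters are uncalibrated
  placeholders; conclusions about that arm are structural only.
- The cohort-dependent observations of the original screening data
  (exceedance percentages, the 12 % outlier prevalence as a measured
  quantity, 75 %-at-600) are not reproduced numerically — the underlying
  per-patient data are unavailable — only structurally, on synthetic
  cohorts with planted truth.
- The imaging benchmark certifies resolvable, well-separated foci at
  high SNR; crowded-foci regimes (high dose, short repair time) are out
  of scope, as they are for the assay itself.
- Whether the original reference mean used all scored cells or exactly
  1000 when more were captured is ambiguous; the default here is all
  scored cells capped at 1000.
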