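# Methods

## The measurement problem

En-face OCT angiography of the choriocapillaris (CC) — the capillary layer
directly beneath the retinal pigment epithelium (RPE) — is quantified by
segmenting *flow deficits* (FDs): regions whose decorrelation signal falls
below a local threshold, interpreted as absent capillary perfusion. In eyes
with geographic atrophy (GA), the FD burden in the tissue immediately
surrounding the lesion is a candidate biomarker for how fast the lesion will
enlarge. The measurement, however, depends on where the en-face slab is
taken: a slab at the anatomically correct CC position (≈11–21 µm below the
RPE-fit centreline) is vulnerable to subtle segmentation error that pulls
RPE/Bruch's-membrane signal into the projection, producing artifactual
hypointensity, while deeper "inner choroid" slabs (21–31, 31–41 µm) are more
robust. This package implements the complete analysis chain and a synthetic
cohort generator that reproduces this slab-dependence so the chain can be
validated end to end.

## Analysis chain

1. **Compensation.** The en-face structural image is inverted on the
   normalized [0, 1] scale (`1 − I`), smoothed with a 3 × 3 truncated
   Gaussian (σ = 0.85 px, reflective boundary), and multiplied into the flow
   image. Where overlying tissue attenuates signal (dark structure), flow is
   boosted; saturated structure suppresses it. The product is rescaled to
   [0, 1] by default (a flag disables this); the threshold constants below
   assume normalized intensities.
2. **Local thresholding.** Phansalkar's rule over a circular window of
   radius 3 px (~17.6 µm on the 6 mm / 1024 px grid), reflective padding:
   `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))` with window mean `m`, population
   standard deviation `s`, and the published constants
   (k, r, p, q) = (0.25, 0.5, 2, 10). Pixels below `t` are deficits. A
   square-window dialect is available behind a flag.
3. **Particle filtering.** Deficits are 8-connected components; each is
   sized by its area-equivalent circular diameter `2·√(area/π)`, and
   components narrower than 24 µm — normal intercapillary spacing — are
   removed globally before any regional statistics. Feret-style alternatives
   were considered and not implemented; equivalent-diameter sizing matches
   the area-based convention of standard particle analysis.
4. **Rings.** Successive 100-µm-wide concentric rings are built around the
   lesion border from the exact Euclidean distance transform of the lesion
   complement. Ring k is the half-open band ((k−1)·w, k·w]; a pixel exactly
   at k·w belongs to ring k (the convention is fixed for bit
   reproducibility). This replaces iterative contour enlargement with a
   better-defined equivalent that admits an analytic oracle (annulus areas
   for circular lesions). Rings clipped by the 6-mm field are retained — FD%
   is a ratio — and the clipped fraction, computed against an enlarged
   virtual field, is reported per ring so heavily clipped rings can be
   excluded. Default 12 rings (1.2 mm), probing well beyond the 600-µm
   window of interest. Inward (intralesional) zones are out of scope.
5. **Growth.** Lesion areas at baseline and follow-up give the square-root
   yearly enlargement rate `yER = (√GA2 − √GA1)/FU` (mm/yr); the transform
   removes the dependence of raw area growth on baseline size. Negative
   rates are flagged, not clamped.
6. **Statistics.** Per (slab, ring): Spearman correlation of FD% with yER
   (average ranks; exact permutation p for n ≤ 9, t-approximation above),
   pairwise deletion of missing rings, α = 0.05 reported per ring without
   multiplicity correction (a Benjamini–Hochberg option exists, off by
   default, matching per-ring reporting conventions). Slab medians are
   compared with the two-sided Wilcoxon signed-rank test — the paired,
   nonparametric choice consistent with median/IQR summaries. Two-grader
   agreement uses ICC(2,1), two-way random effects, absolute agreement,
   single measures, with an F-based 95% CI. Normality screening is not
   gated on: medians/IQRs are used unconditionally.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
fitted per run.

| parameter | default | meaning |
|---|---|---|
| `n_eyes` | 31 | one eye per patient |
| `geometry` | 6 mm / 1024 px | export grid (replication studies use 256 px) |
| `baseline_fd_fraction` | 0.25 | deficit probability far from the lesion |
| `decay_length_um` | 300 | e-folding of the perilesional deficit gradient |
| `severity_median`, `severity_spread` | 0.30, 0.7 | lognormal across-eye severity s_i (median, log-sd) |
| `growth_intercept_mm`, `growth_slope`, `growth_noise_sd` | 0.05, 0.4, 0.035 | planted yER = a + b·s_i + ε, floored at 0 |
| `contamination_level` | 1.0 | shallow-slab artifact amplitude (0 disables) |
| `texture_scale_um` | 30 | correlation length of the capillary texture |
| `lesion_area_median_mm2`, `lesion_area_log_sd` | 0.69, 1.0 | lognormal baseline areas, truncated to [0.1, 5] mm² |
| `fu_years_median`, `fu_years_log_sd` | 1.31, 0.06 | follow-up interval |
| `grader_jitter_um` | 12 | second grader's boundary perturbation (~2 px at 1024) |

Construction, per eye:

* **Lesion**: union of 3–8 random overlapping disks near the field centre,
  morphologically closed, reduced to its largest connected piece, then
  dilated/eroded to the target area by thresholding its signed-distance
  field (exact to one pixel; the spec-level tolerance is 5%).
* **Flow texture**: a stationary Gaussian random field with ~30 µm
  correlation length, mapped through the normal CDF to a spatially
  correlated uniform field `u`; pixels with `u < p(x)` become deficit cores
  (dark, ~0.10) against perfused background (~0.78), with fine speckle on
  both. The deficit probability is
  `p(x) = clip(0.25 + s_i·e^(−d(x)/300 µm), 0.02, 0.92)` with `d` the
  distance to the lesion border. Intralesional flow is attenuated (×0.35)
  and the structural image shows hypertransmission there; both intralesional
  profiles are eroded before smoothing so their ramps stay strictly inside
  the border and plant no spurious perilesional signal.
* **Attenuation**: a gentle vignette plus slow random gain drift multiplies
  the flow image and is mirrored (scaled) in the structural image — this is
  what the compensation stage corrects.
* **Contamination** (shallow slab only): spatially correlated dark blotches
  (~200 µm scale) with per-eye random coverage (median 0.3, lognormal
  spread), *replacing* the capillary signal where they occur, plus
  attenuation of the planted severity gradient
  (retention = e^(−2.5·level) ≈ 0.08 at default level). This models
  inadvertent RPE/BM inclusion: the misplaced slab both shows artifactual
  hypointensity and simply does not contain the CC signal. A purely
  additive artifact bounded in [0, 100] FD% cannot, at any amplitude,
  suppress the rank correlation enough to reproduce the observed loss of
  association in the shallow slab — signal replacement is required, and is
  also the physically sensible mechanism.
* **Growth**: follow-up mask = baseline dilated with smooth angular noise
  (15 µm sd, 100 µm correlation) to match the planted yER under the
  square-root transform (outward-only; exact to one pixel).
* **Graders**: grader 2's masks are the originals displaced by a smooth
  zero-mean normal field of 12 µm sd — the simplest one-knob mechanism for
  duplicate delineations.

Severity, growth and calibration values were set so that the planted cohort
matches the intended operating point: median planted yER
0.05 + 0.4·0.30 = 0.17 mm/yr, median baseline area 0.69 mm², median
follow-up 1.31 yr, and a deep-slab planted association strong enough that
all six 100-µm rings within 600 µm of the border are recoverable at n = 31,
while the contaminated shallow slab loses the association and shows a higher
FD% burden.

## What the generator does and does not emulate

It emulates: the deficit-fraction scale and its perilesional gradient,
slab-dependent artifact with the correct direction (shallow FD% > deep
FD%), severity-driven growth with realistic medians and spread, attenuation
that the compensation stage corrects, and inter-grader boundary
variability. It does **not** emulate OCTA physics (speckle decorrelation,
projection artifacts, A-scan sampling), drusen, real CC spatial statistics
(the 30 µm texture scale is a free parameter; no public measurement
constrains it), multifocal lesions (generated lesions are single blobs,
though the ring machinery handles multifocal masks), or inter-eye
correlation (one eye per patient, so no such structure is needed and no
generalized-estimating-equation adjustment is performed). Passing tests
therefore validate the *analysis chain* under controlled truth, not the
clinical findings themselves.

Two further honest differences from the clinical report. First, the planted
gradient decays exponentially with no sharp cutoff, so adjacent rings just
beyond 600 µm retain some association (rings 7–8 reach significance in a
substantial fraction of replicate cohorts); the clean six-ring window is a
property of the clinical data, not forced here. Second, the two
uncontaminated slabs are generated exchangeably, so the reported
deep-vs-deeper median difference is not reproduced — only the
contaminated-vs-clean contrast is.

## Numerical choices

* Intensities are float64 in [0, 1] regardless of on-disk bit depth (8/16
  bit accepted); masks are exact booleans; physical distances are between
  pixel centres, origin top-left.
* Window statistics use the population standard deviation
  `√(E[x²] − m²)`, clipped at 0 before the square root.
* Area matching selects the N smallest values of a (dithered) signed
  distance field, N = target/pixel-area — monotone, deterministic, exact to
  one pixel; ties on a distance contour are broken by an infinitesimal
  seeded dither.
* Replication experiments (hundreds of cohorts) run at 256 px (23.4 µm
  pitch); the planted effects live at 100-µm-and-larger scales and survive
  this. Note two resolution-dependent behaviours: the 3-*pixel* threshold
  window is physically wider at coarse pitch, and the 24-µm particle filter
  removes nothing once a single pixel already exceeds 24 µm equivalent
  diameter. Single-eye, single-ring FD% carries 3–6 percentage points of
  texture sampling noise (the effective sample size is the ring area over
  the texture cell area, independent of pixel count), so flatness checks
  average over eyes.
* Degenerate inputs raise typed errors rather than returning defaults:
  empty regions (FD% undefined, not 0), constant vectors (no rank
  correlation), all-tied pairs (no signed-rank test), zero between-subject
  variance (no ICC), empty rings (missing, not 0).

## Known limitations

* The contamination model conflates several physical error sources
  (segmentation error, RPE inclusion, shadowing) into one two-parameter
  artifact.
* Ring FD% values of one eye share the global threshold map, so per-eye
  shifts correlate across rings; the per-ring tests are marginal, as in the
  original analysis, and no joint model is attempted.
* ICC confidence intervals come from the standard F approximation and
  inherit its small-sample behaviour.
* The CLI reads whole eyes into memory one at a time; a 1024-px,
  three-slab, two-grader cohort of 31 eyes occupies ~100 MB on disk.
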