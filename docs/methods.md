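# Methods

## Signal model and T1 estimation

The acquisition modelled is a 3 T inversion-prepared gradient-echo (IR-TFE)
protocol: five volumes at inversion delays TI = 150, 350, 750, 1200 and
2300 ms, a fixed shot interval SI = 3000 ms, magnitude reconstruction.
Assuming perfect spoiling and a single effective excitation per shot, the
longitudinal magnetization available at readout follows the steady-state
inversion-recovery expression

    S(TI) = M0 * | 1 - F * exp(-TI/T1) + (F - 1) * exp(-SI/T1) |,

where F in (1, 2] is the inversion factor (F = 2 is a perfect inversion)
and the (F−1)·e^(−SI/T1) term corrects for incomplete longitudinal
relaxation between consecutive shots. F is fixed at 2.0, never fitted.
This closed form is a declared reconstruction from those stated
ingredients, not a transcription of any scanner vendor's sequence code.

The magnitude model is fitted directly in absolute value; no polarity
restoration is attempted. With five TIs this is robust and avoids sign-flip
heuristics, at the cost of local minima near the signal null — addressed by
multi-start initialization (T1 starts 300/800/1500/2500/4000 ms, M0 start
1.2 × max signal, bounds T1 ∈ [50, 8000] ms, M0 > 0).

Two fitters expose the same contract:

* `fit_voxel` — scipy bounded least squares with the multi-start scheme
  above; the reference implementation.
* `fit_map` — for whole volumes. For fixed T1 the model is linear in M0, so
  M0 is profiled out in closed form and the problem becomes one-dimensional:
  a 300-point log-grid over [50, 8000] ms followed by four rounds of
  bracket refinement (21 points per round), vectorized over all voxels.
  Final bracket width is ~10⁻⁵ relative, far below noise. Tests assert the
  two fitters agree.

A fit is *converged* only if the optimum is interior (not at a T1 bound),
M0 > 0, and the model explains ≥ 95% of the signal energy
(rss ≤ 0.05·Σs²). The last condition exists for degenerate inputs — a
constant signal vector, which no IR curve with F = 2 can produce, otherwise
"succeeds" at an interior local minimum with an enormous residual.
Unconverged and unfitted voxels carry NaN through every downstream map;
0 ms is a valid-looking relaxation time and never appears as a sentinel.

**Noise floor.** Magnitude MRI noise is Rician. When the noise scale σ is
known (as in simulation studies), `fit_map(noise_sigma=...)` applies the
second-moment correction s → √max(s² − 2σ², 0) before fitting. This
matters for long T1: at T1 ≈ 4000 ms one TI sits near the signal null,
where the Rician floor otherwise biases the fitted T1 upward by ~2% at
SNR 100. Without a known σ no correction is applied.

**Precision limits.** At SNR 100 the two-parameter Cramér–Rao bound for
this TI schedule gives a per-voxel T1 standard deviation of ≈1.1% at
950 ms, ≈3.4% at 2600 ms and ≈6.9% at 4000 ms; the estimator sits on this
bound (verified in development against Monte-Carlo). Accuracy claims are
therefore about the *center* of the fitted distribution (robust bias
|median − truth|/truth < 2% per tissue), not per-voxel scatter, which no
estimator could reduce below the bound.

## Digital glioma phantom

The phantom emulates a recurrent high-grade glioma on a 64³ isotropic 1 mm
grid: spherical brain (radius 28 mm) with a 3 mm cortical GM shell and a
CSF ventricle; a tumor comprising a necrotic core (4 mm) inside a solid
enhancing rim (outer 9 mm), a subtle-enhancement band (to 11 mm), and an
edema shell (to 16 mm); and a vessel tube tangent to the rim so that naive
region growing would leak into it. Overlapping regions resolve by the fixed
precedence vessels > necrosis > rim > subtle band > edema > GM > WM > CSF
(the WM region carves out the ventricle, which would otherwise be
overpainted, since CSF has the lowest precedence).

Per-tissue pre-contrast T1 (3 T literature-typical values; the tumor range
matches published glioblastoma relaxometry):

| tissue        | pre-T1 (ms)            | post/pre factor | proton density |
|---------------|------------------------|-----------------|----------------|
| WM            | N(950, 50²)            | 1.00            | 0.75           |
| GM            | N(1450, 70²)           | 1.00            | 0.85           |
| CSF           | N(4000, 200²)          | 1.00            | 1.00           |
| edema         | N(1750, 75²)           | 1.00            | 0.90           |
| subtle band   | U(1850, 1995)          | 0.75            | 0.90           |
| enhancing rim | U(2100, 3100)          | 0.35            | 0.90           |
| necrosis      | N(1300, 75²)           | 1.00            | 0.80           |
| vessels       | N(1700, 50²)           | 0.20            | 0.90           |

Normal draws are truncated at > 50 ms; factors at (0, 1.5]. All factors
have small SDs (0.01–0.03). By construction the rim's true ΔqT1 exceeds
50% (factor 0.35 → 65% shortening), the subtle band sits in the
sub-threshold range (25%), and vessels enhance hardest (80%), so the >50%
rule plus vessel exclusion must reproduce the rim exactly on noiseless
data. The subtle band's pre-contrast T1 is uniform up to just below
2000 ms: it models the infiltrative margin between edema and solid tumor
and realizes the study condition that all non-tumor tissue stays strictly
below 2000 ms while tumor starts at 2100 ms — the (2000, 2100) ms gap in
which the recovered ROC cutoff is expected to fall.

Acquisition noise is Rician — magnitude of a complex Gaussian with
per-channel σ relative to M0 = 1, default σ = 0.01 (SNR 100). One
`SeedSequence` per phantom is split into truth / pre-series / post-series
streams; the derived seeds are echoed in the truth manifest, and the same
spec + seed reproduces a bundle bit for bit.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: partial-volume mixing at tissue boundaries, B0/B1
field inhomogeneity, slice profiles, k-space/TFE readout effects, motion,
registration error (all volumes share one grid by construction), and
anatomically realistic tissue geometry. It is a correctness instrument for
the pipeline's statistics, not a realism benchmark.

## Harmonization and subtraction

`nawm_scale` multiplies the post-contrast map by
median(pre WM)/median(post WM) over a user-supplied WM mask (≥ 100 usable
voxels by default). The median, not the mean, is used so stray enhancing or
vessel voxels inside the mask cannot bias the factor. Whether to scale the
pre or the post map is a convention; scaling the post map to the pre map is
the declared one. There is no automatic WM segmentation — the mask is an
input (phantom truth masks in tests).

ΔqT1 = 100·|pre − post|/pre is non-negative by construction, so a T1
*increase* also scores high; segmentation therefore additionally requires
post < pre (true shortening). Enhancing tumor is grown from required seed
voxels as the 26-connected components of the predicate
(ΔqT1 > 50, strict; post < pre) containing the seeds, minus the vessel
mask. A seed that fails the predicate is an error, not silently dropped.
The interactive contour tool such analyses traditionally use is replaced by
this deterministic region growing: the contour evolution was
threshold-driven anyway, and determinism is what makes the stage testable.
The subtle-enhancement mask collects voxels with shortening in
(15%, 50%] (lower bound configurable; no principled value exists for it).

## ROC analysis

Voxel samples pool across patients and time points (one cohort-level
cutoff); a patient-stratified bootstrap (2000 seeded replicates) is
available as an alternative CI route guarding against per-patient voxel
imbalance. "Surroundings" has no canonical operational definition, so it
is a parameter: brain voxels within `band_width_mm` (default 10 mm,
metric, via a Euclidean distance transform) of the tumor, tumor and
vessels excluded.

Conventions, fixed so tests can hold the implementation to them exactly:
thresholds are every distinct sample value plus ±∞ sentinels; the
classifier is "qT1 > t ⇒ tumor" (strict); sensitivity counts tumor voxels
above t, specificity surround voxels at or below t; AUC is the trapezoidal
area traversed in threshold order, which equals the tie-aware normalized
Mann–Whitney statistic (tested to 10⁻¹² against pairwise counting). The
optimal cutoff maximizes Youden's J = sens + spec − 1, ties broken toward
the smallest threshold; only finite thresholds are eligible. At the
cutoff: Clopper–Pearson 95% CIs (exact binomial, via the beta quantile)
for sensitivity and specificity; Hanley–McNeil SE for the AUC with a
normal-approximation two-sided p against AUC = 0.5. Voxel-level binomial
CIs ignore spatial correlation between neighbouring voxels and are
therefore anti-conservative on real images — the stratified bootstrap is
the honest alternative there.

## Overlap, classes, transformation

The headline overlap number is *coverage of the gold standard*,
100·|supra ∩ tumor|/|tumor| — a sensitivity-style reading matching how
such cohorts are tabulated; Dice and Jaccard are attached as supplementary
symmetric measures. Classes apply to the raw percentage (excellent ≥ 90,
moderate 50–89, poor < 50); the value documented "in steps of 10%" uses
half-up rounding (65 → 70) and is reported alongside, not classed.
Transformation of an earlier non-overlapping supra-cutoff area into later
tumor is classed none (< 5%), completely (≥ 95%), else partially with the
10%-binned fraction; the 5/95 cut points are artifact conventions, since
the words none/partially/completely carry no numeric definition. A
pseudoprogression guard is a per-case manifest flag (at least two prior
clean time points), filtered before analysis — it is bookkeeping, not an
image computation.

Cohort aggregation counts patients with ≥ 1 and ≥ 2 excellent time
points, ≥ 1 moderate, "predominantly moderate" (≥ 2 moderate time
points), and ≥ 1 poor. The shipped `data/reference_cohort.csv` is an
externally tabulated 10-patient, 3-time-point recurrent-glioblastoma
cohort (overlap class, transformation class, mean tumor qT1 per case) used
as a worked example; rows marked unevaluable (one motion-degraded
acquisition) are excluded from counts.

## Problem sizes and determinism

Defaults are sized for a laptop-class single core: 64³ phantoms
(~92k brain voxels; a whole-brain map fit takes a few seconds via the
vectorized solver), three-patient cohorts end-to-end in well under a
minute, 10⁴ voxels per tissue for noise studies. Every stochastic stage
takes an explicit seed; `run_all` logs a config hash and reruns reproduce
every number exactly. Grids must match to 10⁻⁴ in the affine before any
voxel-wise operation (`assert_coregistered`); registration itself is out
of scope and inputs are assumed resampled to a common grid upstream.

## Known limitations

* The absolute-value fit discards polarity information; complex or
  phase-restored fitting would lower the Cramér–Rao bound near the null.
* No B1 correction: a real adiabatic inversion has F slightly below 2 and
  spatially varying; F is treated as a fixed acquisition constant.
* Voxel-level CIs understate uncertainty on spatially correlated maps.
* The overlap classes inherit the 10%-step reading tradition of the
  interactive analyses they mirror; voxel counting is the declared
  operationalization where those analyses were read off a screen.
* CSF exceeds any tumor cutoff (~4000 ms); on real data the supra-cutoff
  map needs a brain/ventricle mask or visual reading, as the phantom's
  ventricle illustrates.
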