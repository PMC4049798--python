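# Methods

This note documents the models, the tunable parameters, what the
synthetic generators emulate (and deliberately do not), and the design
choices made where the underlying instrument procedures are proprietary
or unpublished.

## Reference point indentation

A test is a force-controlled sequence of `n_cycles` load–dwell–unload
cycles (defaults: 10 cycles, 2 Hz, 10 N peak) recorded as time, force and
displacement (µm, positive into the bone). Depths are referenced to the
touchdown origin, the displacement at the first sample whose force
exceeds `TOUCHDOWN_THRESHOLD_N` (default 0.1 N, 1 % of peak — above the
modelled noise floor, small enough to catch contact within a fraction of
a micrometre on a stiff initial rise).

Cycle segmentation finds contiguous runs of samples above 90 % of the
trace maximum force (one run per cycle) and places boundaries at the last
index attaining the inter-peak force minimum. Per cycle:

* depth at peak force — depth at first attainment of the cycle maximum;
* indentation distance — maximum depth minus origin;
* creep distance — depth change across the constant-force dwell,
  estimated from a least-squares line through the dwell samples
  (endpoint samples alone would carry the full displacement noise). If no
  dwell is resolvable the creep falls back to the depth change over the
  top-5 %-force window and the cycle is flagged;
* energy dissipated — shoelace polygon area of the raw samples, no
  smoothing (1 N·µm = 1 µJ). Avoiding filters keeps the estimate free of
  filter-parameter arbitrariness and exactly comparable to the analytic
  loop-area oracle;
* unloading slope — the unloading branch between 95 % and 40 % of peak
  force (excludes peak rollover and the low-force tail, the usual
  convention in the indentation literature; neither the study nor the
  instrument manual states a window). Displacement is regressed on force
  and the slope inverted: force is the commanded channel and essentially
  noise-free, so this orientation avoids the ~2 % regression-attenuation
  bias that a force-on-displacement fit would suffer at 0.5 µm noise.

The test summary defines IDI as depth-at-peak(last) − depth-at-peak(first).
The published summary table is internally inconsistent under the
alternative reading (total minus first-cycle indentation distance gives
6.01 µm, not the listed 10.81 µm), so the verbal definition — the change
in depth between the first and final cycle — is the one implemented. Five
sites per animal are averaged arithmetically.

### Synthetic traces

The intra-cycle waveform of the commercial instrument is not public; the
generator uses triangular ramps with a constant-force dwell at peak
(default `dwell_fraction` 0.1 — creep is only definable during a dwell).
Each cycle's loop is an explicit polygon: the loading branch is piecewise
linear in (depth, force) with a steep 0.05 µm contact rise and one free
interior knot; the unloading branch is linear at the requested slope down
to 35 % of peak force, then a linear recovery tail to a free residual
depth. The knot and residual are solved in closed form so the enclosed
area equals `hysteresis_energy_true` exactly, which makes the shoelace
oracle analytic. The residual depth is placed at the forward fixed point
of this geometry so a constant per-cycle energy stays feasible across all
cycles; the price is a larger elastic recovery per cycle than a real
Biodent trace shows (real tests dissipate progressively less per cycle,
which is why the published total energy is ~2.4× the first cycle rather
than 10×). Ground truth for total energy is therefore
`n_cycles × hysteresis_energy_true` by construction. The sample grid hits
every polygon vertex exactly, so the sampled loop area equals the
analytic one to machine precision. Noise is additive Gaussian on
displacement only. Default ground-truth settings are the normal group's
published means.

## AFM Hertz fitting

The withdrawal branch is fit with F = 4E√r δ^{3/2} / (3(1−ν²)), δ the
contact-point-referenced separation, ν = 0.35, r = 50 nm (both
config-overridable). For a fixed contact point the model is linear in E,
so E is profiled out in closed form and the residual sum of squares is
minimised over the contact point alone (200-point grid bracket + bounded
Brent). The contact point uses every sample below 95 % of the peak force,
including the out-of-contact noise floor, which pins it far better than
the high-force window alone and removes most of the joint-fit bias
(median modulus error ≈ 0.4 % at 2 % force noise versus ≈ 1 % for the
pure window fit); the modulus itself is then computed strictly on the
5–95 % force window. Fit failure returns `converged=False` rather than
raising. Curves with pull-off forces beyond 10 % of peak are flagged
adhesive and excluded from aggregation — adhesion is outside the Hertz
model and the study does not state how such curves were handled. Per
animal, all usable indents are averaged; the pooled per-indent moduli are
retained for distribution comparisons (4 grids × 49 indents = 196 per
animal).

Synthetic curves sample separation uniformly from one full-depth height
above contact down to the depth reached at 200 nN (≈ 7 nm at 1 GPa), 200
points per segment; the approach branch carries a small constant force
offset so contact-point detection is genuinely exercised; noise is
Gaussian on force.

## Raman composition

Baseline: piecewise-linear through five anchors at 820, 920, 1010, 1140
and 1750 cm⁻¹ (band-free valleys; the original workflow's anchors are
unpublished and these are config-overridable). Each anchor level is the
median of the five nearest samples, paired with the window's median
wavenumber and linearly extrapolated beyond the outer anchors, so any
linear background is removed exactly. Only the phosphate ν1 band gets a
Gaussian fit (area = height · FWHM · √(π/ln 2)/2; crystallinity =
1/FWHM from the fit, not from raw crossing points); carbonate ν1 and
amide I areas are direct trapezoidal integrals over 1050–1100 and
1620–1700 cm⁻¹ with negatives clipped at zero, matching a workflow that
fits only phosphate and integrates the rest. All three ratios are
invariant to intensity scaling and to any baseline passing through the
anchors. Synthetic spectra are Gaussian bands (defaults: phosphate
958/FWHM 18.52, carbonate 1072/16, amide I 1661/30 cm⁻¹ — the narrower
carbonate/amide widths keep >99.9 % of each band inside its integration
window so analytic areas are recoverable) on a polynomial baseline with
Gaussian count noise.

## Fibril D-periodicity

ROIs and axis angles are operator inputs (automated fibril segmentation
is out of scope; the synthetic generator emits them). The ROI is rotated
so the banding modulation lies along rows, cropped to the valid central
box, and each row is mean-subtracted, Hann-windowed and zero-padded 8×;
row periodograms are averaged. Averaging periodograms rather than rows
keeps the coherent banding peak while flattening incoherent noise, which
makes the signal-to-noise gate sharp: the peak must exceed 3× the median
off-peak power within the 55–75 nm search band or the fibril is rejected.
The peak is refined by three-point parabolic interpolation in log power;
at 512 px / 3.5 µm the native bin spacing near 65 nm corresponds to
≈ 1.2 nm of period, and the refinement brings noiseless accuracy below
0.05 nm (the published between-animal SDs are sub-nanometre, so sub-bin
refinement is not optional). Synthetic images are cosine bandings at the
requested period and axis angle on white roughness; multi-fibril fields
stack horizontal strips with per-fibril periods and phases.

## HPLC crosslinks

Peak areas: local linear baseline between the integration-window
endpoints (5-point median at each end), trapezoidal area above baseline,
clipped at zero — invariant to global signal offsets. Calibration is OLS
of response ratio (analyte area / internal-standard area) on standard
amount with a free intercept (captures integration bias; testable with a
zero-amount standard); r² < 0.98 rejects the curve. Quantitation inverts
the line and floors at zero; a missing internal-standard peak invalidates
the run. Collagen content is hydroxyproline mass × 7.5 / 30 000 g/mol;
crosslinks are reported as mol per mol collagen. Retention-time windows
are configuration, not chemistry: the study gives detector wavelengths,
not retention times, so the synthetic sidecar carries the windows (each
peak ± 5 Gaussian widths). Pentosidine ratios are reported as raw
numbers; the published pentosidine scale sits three orders of magnitude
above the enzymatic crosslinks and its unit label is left to the user.

Noise levels for recovery checks are stated as a fraction of the smallest
analyte peak's mean in-window height (area / window width): "2 % signal
noise" = 0.02 × that height. Referencing noise to the tallest peak
instead would make the 5-point baseline estimate the dominant error term
(≈ 3 % of the largest area regardless of scale) and no integrator of this
family could meet a 3 % recovery bound; real chromatographic noise is in
any case small relative to quantifiable peaks.

## Two-group statistics

Per measure: Shapiro–Wilk per group and classic (mean-centered) Levene
across groups, both at the same α (default 0.05). Both groups normal and
equal variance → Student's t; normal but unequal variance → Welch's t;
any non-normal group → Wilcoxon rank-sum (exact null when both n ≤ 10
and no ties, normal approximation otherwise). The normality gate takes
precedence over the variance gate for doubly-violated data — the
remedies are listed without an order for that case, and the rank-sum test
is the safer of the two. Mean-centered Levene is used because the
median-centered variant is overly conservative at n = 6. Constant-valued
groups route to the rank-sum path with a degeneracy flag; n = 2 groups
cannot be normality-tested (Shapiro–Wilk needs 3) and are treated as not
rejectable. No multiple-testing correction by default (a-priori α per
comparison, as in the study design); Holm step-down is available behind
a flag. Percent difference is (Cy/+ − normal)/normal × 100.

Pooled per-observation samples use the two-sample KS test (asymptotic p).
The heterogeneity panel operationalises "broader distribution" as group
SDs plus the proportion of each group beyond the joint 10th/90th
percentiles: equal-shape groups sit at ≈ 0.10 per tail by construction,
a broader group exceeds it at both ends. The mixture benchmark for this
panel uses a unimodal N(1.0, 0.25 GPa) control versus an equal-mean
0.5/1.5 GPa two-component mixture with 0.12 GPa component SD; these SDs
were set by a power calculation so that both the KS test and the tail
criterion succeed in ≈ 99 % of draws at 196 indents per group, giving
margin over the 95 % reproducibility requirement. The simulated study's
AFM distributions instead use the published SDs (normal: unimodal SD
346 MPa; Cy/+: ±500 MPa components of SD 310, pooled SD ≈ 589 MPa).

Under a 6-vs-6 Gaussian null the full decision tree's rejection rate is
calibrated (0.03–0.07 at α = 0.05; recomputed by the acceptance script at
2000 replicates).

## Study simulation

`generate_group_study` draws per-animal true values from
Normal(group mean, between-animal SD) using the published means, group
shifts and SDs as defaults (an all-zero effect table gives a null study),
then emits the full sampling design per animal: 5 RPI sites, 4 AFM grids
× 49 curves, 5 Raman sites, 4 fibril fields of 12 strips (48 fibrils,
inside the published 40–50), and one fluorescence + one UV chromatogram
against a shared standards set. All randomness descends from a single
`SeedSequence`, so bundles are byte-identical under a fixed seed.
Where a between-animal SD is not itself published (AFM animal means,
within-animal fibril jitter), values were chosen once at a realistic
scale (50 MPa; 1.5 nm) and are not tuned.

What the generators do **not** emulate: reference-probe mechanics and
instrument compliance, peak-force-tapping feedback, cantilever
calibration, cosmic rays and fluorescence in Raman, EDTA/hydrolysis/
derivatization chemistry, co-elution, or any mechanistic bone model.
Passing recovery tests therefore demonstrates correctness of the
analysis chain on idealised signals with the study's geometry and noise
character — not robustness to every instrument artifact of real data.

## Problem sizes and numerics

Default problem sizes were chosen so the full test suite and the
acceptance script each run in well under a minute of compute per
modality on one CPU: 1200 samples per indentation cycle (loop-area
agreement is exact because grid points hit the polygon vertices), 200
samples per force-curve segment and 1000-curve Monte-Carlo recovery,
1501-point spectra, 512² rasters, 0.01-min chromatogram steps, 2000-rep
null calibration, 60-seed heterogeneity reproducibility. Numerical
tie-breaks worth knowing: cycle boundaries take the *last* index of an
inter-peak force minimum (full unloads hold zero force over several
samples); the dwell is identified at 10⁻³ relative force tolerance;
parabolic peak refinement is clamped to ±0.5 bin; Hertz fits clip
negative indentations to zero force; band integrands and quantified
amounts are floored at zero.

## Known limitations

* The RPI generator's per-cycle energy is constant, so synthetic total
  energy does not reproduce the decaying per-cycle dissipation of real
  traces (first-cycle and difference metrics are unaffected).
* The published IDI/TID inconsistency is documented, not resolved; the
  instrument's proprietary definitions may differ from both readings.
* Welch routing at n = 2 per group is forced (Levene undefined there).
* The pentosidine unit question is deliberately left open; values are
  reported on the generator's own consistent scale.
* D-spacing ROIs must be operator-supplied; there is no fibril detector.
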