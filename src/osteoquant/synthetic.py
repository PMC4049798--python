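"""Synthetic instrument-signal generators with known ground truth.

Every analysis stage in this package is testable by parameter recovery:
each generator emits a raw signal of the same shape the instrument would
produce, together with the exact values the matching analysis module
should recover.  Five signal families are covered:

* multi-cycle reference-point-indentation force-displacement traces
  (10 cycles at 2 Hz to 10 N by default),
* AFM Hertzian force-separation curves (loaded to 200 nN),
* bone Raman spectra (phosphate/carbonate/amide bands on a sloping
  baseline),
* banded collagen-fibril topography images (D about 65-66 nm),
* HPLC chromatograms with analyte and internal-standard peaks.

Noise is additive Gaussian on the measured channel only (displacement for
indentation, force for AFM, counts for Raman, height for images, signal
for chromatograms).  All randomness flows from an explicit per-call seed;
no global random state is touched.

The RPI cycle waveform is triangular load/unload with a constant-force
dwell inserted at the peak (creep is only definable during a dwell).  The
loading branch is piecewise linear in force-displacement with one interior
knot, and the unloading branch is linear at the requested slope through
the slope-fit window with a free low-force recovery tail; knot and
residual depth are solved in closed form each cycle so the enclosed loop
area equals the requested per-cycle energy exactly, giving an analytic
shoelace oracle for the energy metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .afm import DEFAULT_POISSON, DEFAULT_TIP_RADIUS, ForceCurve, hertz_force
from .exceptions import ParameterError
from .fibril import TopographyImage
from .hplc import Chromatogram
from .raman import GAUSS_AREA_FACTOR, RamanSpectrum
from .rpi import SLOPE_FIT_WINDOW, IndentationTrace

# --------------------------------------------------------------------------
# Reference point indentation
# --------------------------------------------------------------------------

#: fractions of peak force at which the loading branch has its fixed early
#: knee (steep surface contact) and its free interior knot
_LOAD_CONTACT_FRACTION = 0.05
_LOAD_KNOT_FRACTION = 0.50
#: force fraction below which the unloading tail (shape-free recovery) runs;
#: chosen below the slope-fit window so the fitted slope is untouched
_UNLOAD_TAIL_FRACTION = 0.35
#: displacement of the steep initial contact rise, µm
_CONTACT_RISE_UM = 0.05


@dataclass
class RPITraceParams:
    """Ground-truth settings for one synthetic indentation test.

    Defaults are the protocol values (10 cycles, 2 Hz, 10 N) with the
    normal-group mean outcome measures as ground truth.
    """

    n_cycles: int = 10
    peak_force: float = 10.0  # N
    frequency: float = 2.0  # Hz
    dwell_fraction: float = 0.1  # fraction of the cycle spent at peak force
    first_depth: float = 83.38  # µm, first-cycle indentation distance
    idi_true: float = 10.81  # µm, last-minus-first depth at peak force
    creep_true: float = 6.08  # µm, depth gained during each dwell
    hysteresis_energy_true: float = 275.53  # µJ dissipated per cycle
    unloading_slope_true: float = 0.47  # N/µm
    noise_sd: float = 0.0  # µm, displacement channel
    samples_per_cycle: int = 1200
    seed: int = 0

    def validate(self):
        if self.n_cycles < 2:
            raise ParameterError("n_cycles must be >= 2")
        if self.peak_force <= 0:
            raise ParameterError("peak_force must be positive")
        if self.idi_true < 0:
            raise ParameterError("idi_true must be >= 0")
        if not 0 <= self.dwell_fraction < 1:
            raise ParameterError("dwell_fraction must be in [0, 1)")
        if self.creep_true < 0:
            raise ParameterError("creep_true must be >= 0")
        if self.unloading_slope_true <= 0:
            raise ParameterError("unloading_slope_true must be positive")
        if self.first_depth <= self.creep_true:
            raise ParameterError("first_depth must exceed creep_true")
        if self.hysteresis_energy_true <= 0:
            raise ParameterError("hysteresis_energy_true must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class RPITruth:
    """Sidecar ground truth for one generated trace."""

    first_cycle_indentation_distance: float
    first_cycle_energy_dissipation: float
    first_cycle_unloading_slope: float
    first_cycle_creep_distance: float
    indentation_distance_increase: float
    total_indentation_distance: float
    total_energy_dissipation: float
    cycle_starts: list[int] = field(default_factory=list)
    contact_index: int = 0


def _solve_cycle_geometry(
    x_start: float,
    xp: float,
    creep: float,
    energy: float,
    peak: float,
    slope: float,
    xp_next: float,
) -> tuple[float, float, float]:
    """Closed-form knot/residual solution for one cycle's loop polygon.

    Loading vertices (depth, force): (x_start, 0) -> (x_start + rise,
    f_c) -> (x_knot, f_k) -> (xp, P); dwell to (xp + creep, P); unloading
    linear at ``slope`` down to the tail fraction, then linear tail to
    (x_res, 0).  The enclosed area is ``integral(U dF) - integral(L dF)``;
    both integrals are linear in the unknowns (x_knot, x_res), so we pick
    the residual depth at the forward fixed point (keeping the same energy
    feasible for the next, slightly deeper cycle) and solve the knot
    exactly, falling back to solving the residual when the knot clamps.

    Returns (x_knot, x_res, knee_x).
    """
    P = peak
    f_c = _LOAD_CONTACT_FRACTION * P
    f_k = _LOAD_KNOT_FRACTION * P
    f_t = _UNLOAD_TAIL_FRACTION * P
    rise = _CONTACT_RISE_UM

    knee_x = xp + creep - (P - f_t) / slope
    if knee_x <= 0:
        raise ParameterError(
            "unloading_slope_true too small for the requested depths"
        )

    def load_integral(xs: float, xk: float) -> float:
        return (
            (2.0 * xs + rise) / 2.0 * f_c
            + (xs + rise + xk) / 2.0 * (f_k - f_c)
            + (xk + xp) / 2.0 * (P - f_k)
        )

    upper = (xp + creep + knee_x) / 2.0 * (P - f_t)

    def unload_integral(x_res: float) -> float:
        return upper + (knee_x + x_res) / 2.0 * f_t

    B = (P - f_c) / 2.0  # d(load_integral)/d(x_knot)
    D = f_t / 2.0  # d(unload_integral)/d(x_res)

    # forward fixed point for the residual depth: next cycle reloads from
    # x_res with its knot just above it and unloads back to the same
    # residual; linear in R
    margin = 1.0  # µm between reload start and its knot
    dxp = xp_next - xp
    knee_n = knee_x + dxp
    upper_n = (xp_next + creep + knee_n) / 2.0 * (P - f_t)
    # energy = upper_n + (knee_n + R)/2 * f_t - load_integral(R, R + margin)
    # collect R terms: D*R - [f_c + (f_k - f_c)/2 + B] * R
    coef = D - (f_c + (f_k - f_c) / 2.0 + B)
    const = (
        upper_n
        + knee_n / 2.0 * f_t
        - (rise / 2.0 * f_c + (rise + margin) / 2.0 * (f_k - f_c)
           + (margin + xp_next) / 2.0 * (P - f_k))
    )
    r_star = (energy - const) / coef
    r_star = float(np.clip(r_star, 0.0, knee_x))

    # exact solve for the knot at this cycle
    xk = (unload_integral(r_star) - energy - load_integral(x_start, 0.0)) / B
    lo = x_start + rise + 1e-6
    hi = xp - 1e-6
    if lo < xk < hi:
        return xk, r_star, knee_x
    # clamp the knot, solve the residual instead
    xk = min(max(xk, lo + margin * 0.01), hi)
    x_res = (energy + load_integral(x_start, xk) - upper) / D - knee_x
    if not 0.0 <= x_res <= knee_x:
        raise ParameterError(
            "hysteresis_energy_true infeasible for the requested "
            "depth/slope geometry"
        )
    return xk, x_res, knee_x


def generate_rpi_trace(params: RPITraceParams) -> tuple[IndentationTrace, RPITruth]:
    """Generate one multi-cycle indentation trace plus its ground truth."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    P = p.peak_force
    s = p.unloading_slope_true
    c = p.creep_true
    E = p.hysteresis_energy_true
    n = p.n_cycles

    xp_first = p.first_depth - c  # depth at first attainment of peak force
    step = p.idi_true / (n - 1)
    xps = [xp_first + step * i for i in range(n)]

    cycle_t = 1.0 / p.frequency
    t_dwell = p.dwell_fraction * cycle_t
    t_ramp = (cycle_t - t_dwell) / 2.0
    n_dwell = max(int(round(p.samples_per_cycle * p.dwell_fraction)), 12)
    n_ramp = max((p.samples_per_cycle - n_dwell) // 2, 50)

    f_c = _LOAD_CONTACT_FRACTION * P
    f_k = _LOAD_KNOT_FRACTION * P
    f_t = _UNLOAD_TAIL_FRACTION * P
    rise = _CONTACT_RISE_UM

    times, forces, disps = [], [], []
    cycle_starts = []
    t0 = 0.0

    # pre-contact approach: force zero, displacement rising to the surface
    n_pre = max(n_ramp // 5, 20)
    t_pre = 0.1 * cycle_t
    tt = np.linspace(0.0, t_pre, n_pre, endpoint=False)
    times.append(tt)
    forces.append(np.zeros(n_pre))
    disps.append(np.linspace(-1.0, 0.0, n_pre, endpoint=False))
    t0 = t_pre
    contact_index = n_pre  # first loading sample exceeds the threshold soon after

    x_start = 0.0
    for i in range(n):
        xp = xps[i]
        xp_next = xps[i + 1] if i + 1 < n else xps[i] + step
        xk, x_res, knee_x = _solve_cycle_geometry(
            x_start, xp, c, E, P, s, xp_next
        )
        cycle_starts.append(sum(a.size for a in times))

        # loading: displacement follows the vertex polyline in force; the
        # grid hits every vertex exactly so the sampled polygon equals the
        # analytic one (the shoelace oracle is then exact)
        f_grid = np.linspace(0.0, P, n_ramp, endpoint=False)
        f_grid = np.unique(np.concatenate([f_grid, [f_c, f_k]]))
        f_grid = f_grid[f_grid < P]
        x_load = np.interp(
            f_grid,
            [0.0, f_c, f_k, P],
            [x_start, x_start + rise, xk, xp],
        )
        times.append(np.linspace(t0, t0 + t_ramp, f_grid.size, endpoint=False))
        forces.append(f_grid)
        disps.append(x_load)
        t0 += t_ramp

        # dwell at peak force; creep linear in time (the exact peak point
        # (xp, P) opens the dwell, (xp + c, P) opens the unloading)
        tt = np.linspace(0.0, t_dwell, n_dwell, endpoint=False)
        times.append(t0 + tt)
        forces.append(np.full(n_dwell, P))
        disps.append(xp + (tt / t_dwell) * c)
        t0 += t_dwell

        # unloading: down to exactly zero force at the residual depth
        f_grid = np.linspace(P, 0.0, n_ramp)
        f_grid = np.unique(np.concatenate([f_grid, [f_t]]))[::-1]
        x_unload = np.interp(
            f_grid,
            [0.0, f_t, P],
            [x_res, knee_x, xp + c],
        )
        times.append(np.linspace(t0, t0 + t_ramp, f_grid.size, endpoint=False))
        forces.append(f_grid)
        disps.append(x_unload)
        t0 += t_ramp

        x_start = x_res

    time = np.concatenate(times)
    force = np.concatenate(forces)
    disp = np.concatenate(disps)
    if p.noise_sd > 0:
        disp = disp + rng.normal(0.0, p.noise_sd, disp.size)

    trace = IndentationTrace(time=time, force=force, displacement=disp)
    truth = RPITruth(
        first_cycle_indentation_distance=p.first_depth,
        first_cycle_energy_dissipation=E,
        first_cycle_unloading_slope=s,
        first_cycle_creep_distance=c,
        indentation_distance_increase=p.idi_true,
        total_indentation_distance=p.first_depth + p.idi_true,
        total_energy_dissipation=n * E,
        cycle_starts=cycle_starts,
        contact_index=contact_index,
    )
    return trace, truth


# --------------------------------------------------------------------------
# AFM Hertz curves
# --------------------------------------------------------------------------


@dataclass
class HertzCurveParams:
    """Ground truth for one synthetic AFM force curve."""

    modulus_true: float = 962.99e6  # Pa (normal-group mean)
    poisson: float = DEFAULT_POISSON
    tip_radius: float = DEFAULT_TIP_RADIUS  # m
    max_force: float = 200e-9  # N
    contact_offset: float = 20e-9  # m, separation of first contact
    noise_sd: float = 0.0  # N, force channel
    n_points: int = 200  # per segment
    approach_force_offset: float = 2e-9  # N
    seed: int = 0

    def validate(self):
        if self.modulus_true <= 0:
            raise ParameterError("modulus_true must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ParameterError("poisson must be in [0, 0.5)")
        if self.tip_radius <= 0:
            raise ParameterError("tip_radius must be positive")
        if self.max_force <= 0:
            raise ParameterError("max_force must be positive")
        if self.n_points < 40:
            raise ParameterError("n_points must be >= 40")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def hertz_depth_at_force(
    force: float,
    modulus: float,
    tip_radius: float = DEFAULT_TIP_RADIUS,
    poisson: float = DEFAULT_POISSON,
) -> float:
    """Indentation depth at a given force (inverse of the forward model)."""
    return (
        3.0 * force * (1.0 - poisson**2) / (4.0 * modulus * np.sqrt(tip_radius))
    ) ** (2.0 / 3.0)


def generate_hertz_curve(params: HertzCurveParams) -> tuple[ForceCurve, dict]:
    """Generate one force-separation curve plus its ground-truth sidecar."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    delta_max = hertz_depth_at_force(
        p.max_force, p.modulus_true, p.tip_radius, p.poisson
    )
    z0 = p.contact_offset
    # separation sweeps from above the surface down past contact
    sep = np.linspace(z0 + 2.0 * delta_max + 10e-9, z0 - delta_max, p.n_points)
    delta = np.maximum(z0 - sep, 0.0)
    f_clean = hertz_force(delta, p.modulus_true, p.tip_radius, p.poisson)

    f_approach = f_clean + p.approach_force_offset
    f_withdraw = f_clean.copy()
    if p.noise_sd > 0:
        f_approach = f_approach + rng.normal(0.0, p.noise_sd, sep.size)
        f_withdraw = f_withdraw + rng.normal(0.0, p.noise_sd, sep.size)

    separation = np.concatenate([sep, sep[::-1]])
    force = np.concatenate([f_approach, f_withdraw[::-1]])
    segment = np.array(
        ["approach"] * p.n_points + ["withdraw"] * p.n_points
    )
    curve = ForceCurve(separation=separation, force=force, segment=segment)
    truth = {
        "modulus_true": p.modulus_true,
        "contact_offset": z0,
        "delta_max": float(delta_max),
        "max_force": p.max_force,
    }
    return curve, truth


# --------------------------------------------------------------------------
# Raman spectra
# --------------------------------------------------------------------------


@dataclass
class SpectrumParams:
    """Forward model for a bone Raman spectrum: Gaussian bands + baseline."""

    bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (958.0, 1000.0, 18.52),  # phosphate nu1 (center, height, fwhm)
            (1072.0, 160.0, 16.0),  # carbonate nu1
            (1661.0, 180.0, 30.0),  # amide I
        ]
    )
    baseline_coeffs: tuple[float, ...] = (50.0, 0.02)  # low->high order
    wavenumber_start: float = 300.0
    wavenumber_stop: float = 1800.0
    wavenumber_step: float = 1.0
    noise_sd: float = 0.0  # counts
    seed: int = 0

    def validate(self):
        if self.wavenumber_stop <= self.wavenumber_start:
            raise ParameterError("wavenumber range is empty")
        for center, height, fwhm in self.bands:
            if fwhm <= 0:
                raise ParameterError("band fwhm must be positive")
            if not self.wavenumber_start < center < self.wavenumber_stop:
                raise ParameterError(
                    f"band center {center} outside the wavenumber grid"
                )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def spectrum_params_for_ratios(
    mineral_to_matrix: float = 2.539,
    carbonate_substitution: float = 0.618,
    crystallinity: float = 0.054,
    phosphate_height: float = 1000.0,
    **kwargs,
) -> SpectrumParams:
    """Build band settings that realise target compositional ratios.

    The phosphate FWHM is 1/crystallinity; carbonate and amide I heights
    are chosen so the analytic Gaussian band areas hit the requested
    ratios exactly.
    """
    if crystallinity <= 0:
        raise ParameterError("crystallinity must be positive")
    fwhm_p = 1.0 / crystallinity
    area_p = phosphate_height * fwhm_p * GAUSS_AREA_FACTOR
    fwhm_c, fwhm_a = 16.0, 30.0
    height_c = carbonate_substitution * area_p / (fwhm_c * GAUSS_AREA_FACTOR)
    height_a = (area_p / mineral_to_matrix) / (fwhm_a * GAUSS_AREA_FACTOR)
    return SpectrumParams(
        bands=[
            (958.0, phosphate_height, fwhm_p),
            (1072.0, height_c, fwhm_c),
            (1661.0, height_a, fwhm_a),
        ],
        **kwargs,
    )


def generate_spectrum(params: SpectrumParams) -> tuple[RamanSpectrum, dict]:
    """Generate one Raman spectrum plus its ground-truth sidecar."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    w = np.arange(p.wavenumber_start, p.wavenumber_stop + p.wavenumber_step,
                  p.wavenumber_step)
    y = np.polynomial.polynomial.polyval(w - w[0], p.baseline_coeffs)
    y = np.asarray(y, dtype=float) + np.zeros_like(w)
    areas = {}
    names = ["phosphate", "carbonate", "amide_i"]
    for name, (center, height, fwhm) in zip(names, p.bands):
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = y + height * np.exp(-0.5 * ((w - center) / sigma) ** 2)
        areas[name] = height * fwhm * GAUSS_AREA_FACTOR
    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, w.size)
    truth = {
        "areas": areas,
        "phosphate_fwhm": p.bands[0][2],
        "crystallinity": 1.0 / p.bands[0][2],
    }
    if {"phosphate", "carbonate", "amide_i"} <= set(areas):
        truth["mineral_to_matrix"] = areas["phosphate"] / areas["amide_i"]
        truth["carbonate_substitution"] = (
            areas["carbonate"] / areas["phosphate"]
        )
    return RamanSpectrum(wavenumber=w, intensity=y), truth


# --------------------------------------------------------------------------
# Fibril topography images
# --------------------------------------------------------------------------


@dataclass
class FibrilImageParams:
    """Forward model for a banded-fibril topography image."""

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 3500.0 / 512.0  # nm/pixel (3.5 µm scan, 512 px)
    d_spacing_true: float = 65.641  # nm (normal-group mean)
    fibril_axis_angle: float = 0.0  # degrees
    banding_amplitude: float = 1.0  # height units
    background_roughness_sd: float = 0.0  # height units
    seed: int = 0

    def validate(self):
        if min(self.image_size) < 64:
            raise ParameterError("image_size must be at least 64x64")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.d_spacing_true <= 2.0 * self.pixel_size:
            raise ParameterError(
                "d_spacing_true must exceed 2 pixels (Nyquist)"
            )
        if self.background_roughness_sd < 0:
            raise ParameterError("background_roughness_sd must be >= 0")


def generate_fibril_image(
    params: FibrilImageParams,
) -> tuple[TopographyImage, dict]:
    """Generate a banded topography image plus its ground-truth sidecar.

    The banding is a cosine modulation of period ``d_spacing_true`` along
    the fibril axis direction, on a white-noise background roughness.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    theta = np.deg2rad(p.fibril_axis_angle)
    u = xx * np.cos(theta) + yy * np.sin(theta)  # pixels along the axis
    period_px = p.d_spacing_true / p.pixel_size
    height = p.banding_amplitude * np.cos(2.0 * np.pi * u / period_px)
    if p.background_roughness_sd > 0:
        height = height + rng.normal(0.0, p.background_roughness_sd, (h, w))
    image = TopographyImage(height=height, pixel_size=p.pixel_size)
    truth = {
        "d_spacing_true": p.d_spacing_true,
        "fibril_axis_angle": p.fibril_axis_angle,
        "roi": (0, 0, w, h),
    }
    return image, truth


def generate_fibril_field(
    d_spacings: list[float],
    pixel_size: float = 3500.0 / 512.0,
    image_size: tuple[int, int] = (512, 512),
    banding_amplitude: float = 1.0,
    background_roughness_sd: float = 0.1,
    seed: int = 0,
) -> tuple[TopographyImage, list[tuple[tuple[int, int, int, int], float]]]:
    """One image field containing several horizontal fibril strips.

    Each strip carries its own banding period (modulation along x).
    Returns the image plus a list of (roi, d_true) pairs, one per fibril,
    emulating an operator's per-fibril ROI table.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    n = len(d_spacings)
    if n == 0:
        raise ParameterError("need at least one fibril strip")
    strip_h = h // n
    if strip_h * pixel_size < 30.0:
        raise ParameterError("too many strips for the image height")
    height = rng.normal(0.0, background_roughness_sd, (h, w)) \
        if background_roughness_sd > 0 else np.zeros((h, w))
    x = np.arange(w, dtype=float)
    rois = []
    for i, d in enumerate(d_spacings):
        period_px = d / pixel_size
        phase = rng.uniform(0.0, 2.0 * np.pi)
        band = banding_amplitude * np.cos(2.0 * np.pi * x / period_px + phase)
        y0, y1 = i * strip_h, (i + 1) * strip_h
        height[y0:y1, :] += band[None, :]
        rois.append(((0, y0, w, y1 - y0), float(d)))
    image = TopographyImage(height=height, pixel_size=pixel_size)
    return image, rois


# --------------------------------------------------------------------------
# HPLC chromatograms
# --------------------------------------------------------------------------


@dataclass
class ChromatogramParams:
    """Forward model for one chromatographic run.

    ``peaks`` maps analyte name -> (retention_time min, true_amount,
    response_factor signal*min per unit amount, width = Gaussian sigma in
    min).  The internal standard is a constant-amount peak of the same
    form.
    """

    peaks: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    internal_standard: tuple[str, float, float, float, float] = (
        "pyridoxine", 10.0, 1.0, 1000.0, 0.08,
    )  # name, rt, amount, response_factor, width
    baseline_level: float = 5.0
    noise_sd: float = 0.0
    run_time: float = 35.0  # min
    time_step: float = 0.01  # min
    channel: str = "fluorescence"
    seed: int = 0

    def validate(self):
        rts = [rt for rt, *_ in self.peaks.values()]
        rts.append(self.internal_standard[1])
        widths = [wd for *_, wd in self.peaks.values()]
        widths.append(self.internal_standard[4])
        for rt, wd in zip(rts, widths):
            if wd <= 0:
                raise ParameterError("peak width must be positive")
            if not 0 < rt < self.run_time:
                raise ParameterError("retention time outside the run")
        rts_sorted = np.sort(rts)
        if rts_sorted.size > 1 and np.min(np.diff(rts_sorted)) < 8.0 * max(widths):
            raise ParameterError(
                "retention times not distinct beyond peak widths"
            )
        for _rt, amount, rf, _wd in self.peaks.values():
            if amount < 0:
                raise ParameterError("peak amounts must be >= 0")
            if rf <= 0:
                raise ParameterError("response factors must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def generate_chromatogram(
    params: ChromatogramParams,
) -> tuple[Chromatogram, dict]:
    """Generate one chromatogram plus its ground-truth sidecar.

    Each peak is a Gaussian of area ``amount * response_factor``.  The
    sidecar carries per-analyte integration windows (rt +- 5 sigma) and
    true amounts.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.run_time + p.time_step, p.time_step)
    y = np.full_like(t, float(p.baseline_level))
    windows = {}
    amounts = {}

    def add_peak(name, rt, amount, rf, width):
        area = amount * rf
        y_add = area / (width * np.sqrt(2.0 * np.pi)) * np.exp(
            -0.5 * ((t - rt) / width) ** 2
        )
        windows[name] = (rt - 5.0 * width, rt + 5.0 * width)
        amounts[name] = amount
        return y_add

    for name, (rt, amount, rf, width) in p.peaks.items():
        y = y + add_peak(name, rt, amount, rf, width)
    is_name, is_rt, is_amount, is_rf, is_width = p.internal_standard
    y = y + add_peak(is_name, is_rt, is_amount, is_rf, is_width)
    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, t.size)
    chrom = Chromatogram(retention_time=t, signal=y, channel=p.channel)
    truth = {
        "amounts": amounts,
        "windows": windows,
        "internal_standard": is_name,
    }
    return chrom, truth


# --------------------------------------------------------------------------
# Two-group study bundles
# --------------------------------------------------------------------------

#: per-metric study conditions: (normal mean, Cy/+ - normal shift,
#: between-animal SD) in the units of each analysis module
STUDY_METRICS = {
    "rpi_first_depth": (83.38, 4.86, 3.15),
    "rpi_energy": (275.53, 22.41, 14.00),
    "rpi_slope": (0.47, -0.02, 0.02),
    "rpi_creep": (6.08, 1.09, 0.43),
    "rpi_idi": (10.81, 1.90, 0.92),
    "afm_modulus_mpa": (962.99, 33.74, 50.0),
    "raman_crystallinity": (0.054, 0.001, 0.0008),
    "raman_carbonate_sub": (0.618, -0.010, 0.030),
    "raman_mineral_to_matrix": (2.539, 0.160, 0.20),
    "fibril_d_nm": (65.641, 0.223, 0.646),
    "hplc_pyd": (0.60, -0.06, 0.14),
    "hplc_dpd": (0.37, 0.00, 0.05),
    "hplc_pe": (878.0, 43.0, 150.0),
}

#: pooled single-indent modulus SD of the healthy group, MPa
AFM_INDENT_SD_NORMAL = 345.98
#: Cy/+ indents are drawn from a symmetric two-component mixture around the
#: animal mean: component offset and component SD chosen so the pooled SD
#: is ~589 MPa with a visibly broader distribution
AFM_MIXTURE_OFFSET = 500.0
AFM_MIXTURE_COMPONENT_SD = 310.0

#: per-fibril D-spacing jitter within an animal, nm
FIBRIL_WITHIN_SD = 1.5

#: sampling design per animal
N_RPI_SITES = 5
N_AFM_GRIDS = 4
N_AFM_CURVES_PER_GRID = 49
N_RAMAN_SITES = 5
N_FIBRIL_FIELDS = 4
N_FIBRILS_PER_FIELD = 12


@dataclass
class AnimalData:
    """All raw synthetic signals for one animal."""

    animal_id: str
    group_label: str
    rpi: list[tuple[IndentationTrace, RPITruth]]
    afm: list[tuple[ForceCurve, dict]]
    raman: list[tuple[RamanSpectrum, dict]]
    fibril_fields: list[
        tuple[TopographyImage, list[tuple[tuple[int, int, int, int], float]]]
    ]
    hplc_fluor: tuple[Chromatogram, dict]
    hplc_uv: tuple[Chromatogram, dict]
    truth: dict


@dataclass
class StudyBundle:
    """A complete synthetic two-group study."""

    animals: list[AnimalData]
    hplc_standards: dict
    seed: int

    def group(self, label: str) -> list[AnimalData]:
        return [a for a in self.animals if a.group_label == label]


def _hplc_standard_set(rng: np.random.Generator, channel: str):
    """Calibration standards (amount, chromatogram) per analyte."""
    if channel == "fluorescence":
        analytes = {
            "pyd": (18.0, 2.0e-7, 5e9, 0.10),
            "dpd": (22.0, 1.2e-7, 5e9, 0.10),
            "pe": (28.0, 3.0e-4, 2e6, 0.10),
        }
        internal = ("pyridoxine", 10.0, 1.0, 800.0, 0.08)
    else:
        analytes = {
            "hyp": (8.0, 1.5e-3, 8e5, 0.10),  # amounts in g
            "pro": (12.0, 1.0e-2, 1e5, 0.10),
        }
        internal = ("aaba", 16.0, 1.0, 900.0, 0.08)
    levels = np.array([0.25, 0.5, 1.0, 1.5, 2.0])
    standards: dict[str, list[tuple[float, Chromatogram]]] = {
        name: [] for name in analytes
    }
    windows = {}
    for name, (rt, nominal, rf, width) in analytes.items():
        windows[name] = (rt - 0.5, rt + 0.5)
    is_name, is_rt, is_amount, is_rf, is_width = internal
    windows[is_name] = (is_rt - 0.4, is_rt + 0.4)
    for level in levels:
        peaks = {
            name: (rt, float(level * nominal), rf, width)
            for name, (rt, nominal, rf, width) in analytes.items()
        }
        cp = ChromatogramParams(
            peaks=peaks,
            internal_standard=internal,
            channel=channel,
            noise_sd=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        chrom, _ = generate_chromatogram(cp)
        for name in analytes:
            standards[name].append((peaks[name][1], chrom))
    return {
        "standards": standards,
        "windows": windows,
        "internal_standard": is_name,
        "analytes": analytes,
        "internal": internal,
    }


def generate_group_study(
    n_per_group: int = 6,
    group_effects: dict[str, float] | None = None,
    seed: int = 0,
    noise: dict[str, float] | None = None,
    n_rpi_sites: int = N_RPI_SITES,
    n_afm_grids: int = N_AFM_GRIDS,
    n_afm_curves_per_grid: int = N_AFM_CURVES_PER_GRID,
    n_raman_sites: int = N_RAMAN_SITES,
    n_fibril_fields: int = N_FIBRIL_FIELDS,
    n_fibrils_per_field: int = N_FIBRILS_PER_FIELD,
) -> StudyBundle:
    """Generate a full two-group study with per-animal raw signals.

    ``group_effects`` maps metric names (keys of :data:`STUDY_METRICS`) to
    the additive shift of the Cy/+ group mean relative to normal; the
    default is the study's observed shifts; an all-zero table yields a
    null study.  ``noise`` overrides the default measurement-noise levels
    (keys: rpi_um, afm_frac, raman_counts, image_height, hplc_signal).
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    effects = {k: v[1] for k, v in STUDY_METRICS.items()}
    if group_effects is not None:
        unknown = set(group_effects) - set(STUDY_METRICS)
        if unknown:
            raise ParameterError(f"unknown group-effect metrics: {unknown}")
        effects.update(group_effects)
    nz = {
        "rpi_um": 0.2,
        "afm_frac": 0.02,
        "raman_counts": 5.0,
        "image_height": 0.1,
        "hplc_signal": 2.0,
    }
    if noise:
        nz.update(noise)

    root = np.random.SeedSequence(seed)
    std_rng = np.random.default_rng(root.spawn(1)[0])
    hplc_fluor_std = _hplc_standard_set(std_rng, "fluorescence")
    hplc_uv_std = _hplc_standard_set(std_rng, "uv")

    animals = []
    for g_idx, group in enumerate(("normal", "cyplus")):
        for a_idx in range(n_per_group):
            a_seed = root.spawn(1)[0]
            rng = np.random.default_rng(a_seed)
            animal_id = f"{group}_{a_idx + 1:02d}"

            def draw(metric: str) -> float:
                mean, _shift, sd = STUDY_METRICS[metric]
                if group == "cyplus":
                    mean = mean + effects[metric]
                return float(rng.normal(mean, sd))

            truth = {m: draw(m) for m in STUDY_METRICS}
            # keep drawn values physical
            truth["rpi_idi"] = max(truth["rpi_idi"], 0.5)
            truth["rpi_creep"] = max(truth["rpi_creep"], 0.5)
            truth["hplc_pyd"] = max(truth["hplc_pyd"], 0.01)
            truth["hplc_dpd"] = max(truth["hplc_dpd"], 0.01)
            truth["hplc_pe"] = max(truth["hplc_pe"], 1.0)

            rpi_data = [
                generate_rpi_trace(RPITraceParams(
                    first_depth=truth["rpi_first_depth"],
                    idi_true=truth["rpi_idi"],
                    creep_true=truth["rpi_creep"],
                    hysteresis_energy_true=truth["rpi_energy"],
                    unloading_slope_true=truth["rpi_slope"],
                    noise_sd=nz["rpi_um"],
                    seed=int(rng.integers(2**31 - 1)),
                ))
                for _ in range(n_rpi_sites)
            ]
            for trace, _t in rpi_data:
                trace.animal_id = animal_id
                trace.group_label = group

            afm_data = []
            mean_mpa = truth["afm_modulus_mpa"]
            for grid in range(n_afm_grids):
                for k in range(n_afm_curves_per_grid):
                    if group == "normal":
                        e_mpa = rng.normal(mean_mpa, AFM_INDENT_SD_NORMAL)
                    else:
                        off = AFM_MIXTURE_OFFSET * (1 if rng.random() < 0.5 else -1)
                        e_mpa = rng.normal(
                            mean_mpa + off, AFM_MIXTURE_COMPONENT_SD
                        )
                    e_mpa = max(e_mpa, 50.0)
                    cp = HertzCurveParams(
                        modulus_true=e_mpa * 1e6,
                        noise_sd=nz["afm_frac"] * 200e-9,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    curve, ctruth = generate_hertz_curve(cp)
                    curve.grid_position = (grid, k)
                    curve.animal_id = animal_id
                    curve.group_label = group
                    afm_data.append((curve, ctruth))

            raman_data = []
            for _ in range(n_raman_sites):
                sp = spectrum_params_for_ratios(
                    mineral_to_matrix=truth["raman_mineral_to_matrix"],
                    carbonate_substitution=truth["raman_carbonate_sub"],
                    crystallinity=truth["raman_crystallinity"],
                    noise_sd=nz["raman_counts"],
                    seed=int(rng.integers(2**31 - 1)),
                )
                spec, struth = generate_spectrum(sp)
                spec.animal_id = animal_id
                spec.group_label = group
                raman_data.append((spec, struth))

            fibril_data = []
            for _ in range(n_fibril_fields):
                ds = rng.normal(
                    truth["fibril_d_nm"], FIBRIL_WITHIN_SD,
                    n_fibrils_per_field,
                )
                ds = np.clip(ds, 57.0, 73.0)
                img, rois = generate_fibril_field(
                    ds.tolist(),
                    background_roughness_sd=nz["image_height"],
                    seed=int(rng.integers(2**31 - 1)),
                )
                img.animal_id = animal_id
                img.group_label = group
                fibril_data.append((img, rois))

            # HPLC: one fluorescence + one UV run per animal
            hyp_mass = 1.3e-3  # g of hydroxyproline in the assayed half
            collagen_mol = hyp_mass * 7.5 / 30000.0
            fa = hplc_fluor_std["analytes"]
            fluor_peaks = {
                "pyd": (fa["pyd"][0], truth["hplc_pyd"] * collagen_mol,
                        fa["pyd"][2], fa["pyd"][3]),
                "dpd": (fa["dpd"][0], truth["hplc_dpd"] * collagen_mol,
                        fa["dpd"][2], fa["dpd"][3]),
                "pe": (fa["pe"][0], truth["hplc_pe"] * collagen_mol,
                       fa["pe"][2], fa["pe"][3]),
            }
            fluor, ftruth = generate_chromatogram(ChromatogramParams(
                peaks=fluor_peaks,
                internal_standard=hplc_fluor_std["internal"],
                channel="fluorescence",
                noise_sd=nz["hplc_signal"],
                seed=int(rng.integers(2**31 - 1)),
            ))
            fluor.animal_id = animal_id
            ua = hplc_uv_std["analytes"]
            uv_peaks = {
                "hyp": (ua["hyp"][0], hyp_mass, ua["hyp"][2], ua["hyp"][3]),
                "pro": (ua["pro"][0], 8.0e-3, ua["pro"][2], ua["pro"][3]),
            }
            uv, utruth = generate_chromatogram(ChromatogramParams(
                peaks=uv_peaks,
                internal_standard=hplc_uv_std["internal"],
                channel="uv",
                noise_sd=nz["hplc_signal"],
                seed=int(rng.integers(2**31 - 1)),
            ))
            uv.animal_id = animal_id
            truth["hplc_hyp_mass"] = hyp_mass

            animals.append(AnimalData(
                animal_id=animal_id,
                group_label=group,
                rpi=rpi_data,
                afm=afm_data,
                raman=raman_data,
                fibril_fields=fibril_data,
                hplc_fluor=(fluor, ftruth),
                hplc_uv=(uv, utruth),
                truth=truth,
            ))
    return StudyBundle(
        animals=animals,
        hplc_standards={
            "fluorescence": hplc_fluor_std,
            "uv": hplc_uv_std,
        },
        seed=seed,
    )
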