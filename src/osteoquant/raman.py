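"""Raman compositional analysis of bone.

Bone Raman spectra carry a phosphate nu1 band (~958 cm-1, the apatite
mineral), a carbonate nu1 band (~1070 cm-1, type B carbonate substituting
in the apatite lattice) and the amide I band (~1660 cm-1, the collagen
matrix).  Three standard compositional metrics are derived:

* mineral-to-matrix ratio  = area(phosphate nu1) / area(amide I)
* carbonate substitution   = area(carbonate nu1) / area(phosphate nu1)
* crystallinity            = 1 / FWHM(phosphate nu1)

Processing order: a multi-point piecewise-linear baseline correction
(anchors in band-free valleys, anchor intensity taken as a local 5-point
median), a single-Gaussian fit to the phosphate nu1 band (its FWHM defines
crystallinity), and direct trapezoidal integration of the three band
windows.  Only phosphate is fit with a Gaussian; carbonate and amide I
areas are integrated numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit.models import GaussianModel

from .exceptions import ParameterError, UndefinedRatioError

#: default baseline anchors (cm-1), chosen in band-free valleys
BASELINE_ANCHORS = (820.0, 920.0, 1010.0, 1140.0, 1750.0)

#: default integration windows (cm-1)
BAND_WINDOWS = {
    "phosphate": (930.0, 990.0),
    "carbonate": (1050.0, 1100.0),
    "amide_i": (1620.0, 1700.0),
}

#: Gaussian area = amplitude * fwhm * sqrt(pi / ln 2) / 2 (amplitude = height)
GAUSS_AREA_FACTOR = 0.5 * np.sqrt(np.pi / np.log(2.0))


@dataclass
class RamanSpectrum:
    """Intensity vs wavenumber for one acquisition site."""

    wavenumber: np.ndarray  # cm-1, strictly increasing
    intensity: np.ndarray  # counts
    site_id: str = ""
    animal_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.size != self.intensity.size:
            raise ParameterError("wavenumber/intensity lengths differ")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ParameterError("wavenumber must be strictly increasing")
        if self.wavenumber[0] > 800.0 or self.wavenumber[-1] < 1750.0:
            raise ParameterError("spectrum must cover at least 800-1750 cm-1")


@dataclass
class PhosphateFit:
    """Single-Gaussian fit to the phosphate nu1 band."""

    center: float
    amplitude: float  # peak height, counts
    fwhm: float  # cm-1
    area: float  # counts * cm-1
    ok: bool


@dataclass
class CompositionResult:
    """Band areas, phosphate FWHM and the three compositional ratios."""

    phosphate_area: float
    carbonate_area: float
    amide_i_area: float
    phosphate_fwhm: float
    mineral_to_matrix: float
    carbonate_substitution: float
    crystallinity: float


def baseline_correct(
    spectrum: RamanSpectrum,
    anchors: tuple[float, ...] = BASELINE_ANCHORS,
) -> RamanSpectrum:
    """Subtract a piecewise-linear baseline through the anchor points.

    The baseline value at each anchor is the median of the 5 samples
    nearest the anchor wavenumber, which keeps single-sample noise out of
    the baseline.  Beyond the outermost anchors the baseline extends
    flat.
    """
    w, y = spectrum.wavenumber, spectrum.intensity
    if len(anchors) < 2:
        raise ParameterError("need at least 2 baseline anchors")
    levels, positions = [], []
    for a in anchors:
        if a < w[0] or a > w[-1]:
            raise ParameterError(f"anchor {a} cm-1 outside spectrum range")
        i = int(np.argmin(np.abs(w - a)))
        lo, hi = max(i - 2, 0), min(i + 3, w.size)
        # the median level is paired with the window's median wavenumber so
        # a linear background is reproduced exactly even at range edges
        levels.append(float(np.median(y[lo:hi])))
        positions.append(float(np.median(w[lo:hi])))
    positions = np.asarray(positions)
    levels = np.asarray(levels)
    order = np.argsort(positions)
    positions, levels = positions[order], levels[order]
    baseline = np.interp(w, positions, levels)
    # linear extrapolation beyond the outermost anchors (np.interp is flat)
    left = w < positions[0]
    if left.any() and positions[1] > positions[0]:
        slope = (levels[1] - levels[0]) / (positions[1] - positions[0])
        baseline[left] = levels[0] + slope * (w[left] - positions[0])
    right = w > positions[-1]
    if right.any() and positions[-1] > positions[-2]:
        slope = (levels[-1] - levels[-2]) / (positions[-1] - positions[-2])
        baseline[right] = levels[-1] + slope * (w[right] - positions[-1])
    return RamanSpectrum(
        wavenumber=w.copy(),
        intensity=y - baseline,
        site_id=spectrum.site_id,
        animal_id=spectrum.animal_id,
        group_label=spectrum.group_label,
    )


def fit_phosphate_peak(
    spectrum: RamanSpectrum,
    window: tuple[float, float] = BAND_WINDOWS["phosphate"],
) -> PhosphateFit:
    """Least-squares single-Gaussian fit to the phosphate nu1 band.

    Expects a baseline-corrected spectrum.  A failed fit is returned with
    ``ok=False`` (the site is then excluded from averages) rather than
    raised.
    """
    w, y = spectrum.wavenumber, spectrum.intensity
    lo, hi = window
    if lo < w[0] or hi > w[-1]:
        raise ParameterError("phosphate window outside spectrum range")
    m = (w >= lo) & (w <= hi)
    if m.sum() < 8:
        raise ParameterError("phosphate window contains too few samples")
    model = GaussianModel()
    try:
        params = model.guess(y[m], x=w[m])
        out = model.fit(y[m], params, x=w[m])
        height = float(out.params["height"].value)
        fwhm = float(out.params["fwhm"].value)
        center = float(out.params["center"].value)
    except Exception:
        return PhosphateFit(np.nan, np.nan, np.nan, np.nan, ok=False)
    ok = (
        np.isfinite(fwhm)
        and fwhm > 0
        and height > 0
        and lo <= center <= hi
        and out.success
    )
    area = height * fwhm * GAUSS_AREA_FACTOR
    return PhosphateFit(center=center, amplitude=height, fwhm=fwhm,
                        area=area, ok=bool(ok))


def band_areas(
    spectrum: RamanSpectrum,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Trapezoidal band areas within named windows, negatives clipped at 0."""
    if bands is None:
        bands = BAND_WINDOWS
    w, y = spectrum.wavenumber, spectrum.intensity
    out = {}
    for name, (lo, hi) in bands.items():
        if lo < w[0] or hi > w[-1]:
            raise ParameterError(f"band window {name!r} outside spectrum range")
        m = (w >= lo) & (w <= hi)
        out[name] = float(np.trapezoid(np.clip(y[m], 0.0, None), w[m]))
    return out


def composition_ratios(
    areas: dict[str, float], phosphate_fwhm: float
) -> CompositionResult:
    """Assemble the three compositional ratios from band areas and FWHM."""
    p = areas["phosphate"]
    c = areas["carbonate"]
    a = areas["amide_i"]
    if p <= 0 or a <= 0:
        raise UndefinedRatioError(
            "phosphate and amide I areas must be positive"
        )
    if phosphate_fwhm <= 0:
        raise UndefinedRatioError("phosphate FWHM must be positive")
    return CompositionResult(
        phosphate_area=p,
        carbonate_area=c,
        amide_i_area=a,
        phosphate_fwhm=phosphate_fwhm,
        mineral_to_matrix=p / a,
        carbonate_substitution=c / p,
        crystallinity=1.0 / phosphate_fwhm,
    )


def analyze_spectrum(
    spectrum: RamanSpectrum,
    anchors: tuple[float, ...] = BASELINE_ANCHORS,
    bands: dict[str, tuple[float, float]] | None = None,
) -> CompositionResult:
    """Baseline-correct, fit phosphate, integrate bands, form ratios.

    Raises :class:`ParameterError` if the phosphate Gaussian fit fails
    (callers aggregating several sites should catch and exclude the site).
    """
    corrected = baseline_correct(spectrum, anchors)
    windows = BAND_WINDOWS if bands is None else bands
    fit = fit_phosphate_peak(corrected, windows["phosphate"])
    if not fit.ok:
        raise ParameterError("phosphate peak fit failed for this site")
    areas = band_areas(corrected, windows)
    return composition_ratios(areas, fit.fwhm)


def aggregate_composition(
    results: list[CompositionResult],
) -> CompositionResult:
    """Arithmetic mean of every field across sites (per-animal value)."""
    if not results:
        raise ParameterError("no composition results to aggregate")
    from dataclasses import fields as _fields

    vals = {
        f.name: float(np.mean([getattr(r, f.name) for r in results]))
        for f in _fields(CompositionResult)
    }
    return CompositionResult(**vals)
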