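"""HPLC quantitation of collagen crosslinks.

Fluorescence chromatograms carry the enzymatic crosslinks pyridinoline
(Pyd) and deoxypyridinoline (Dpd) and the glycation crosslink pentosidine
(PE), normalised against a constant-amount pyridoxine internal standard.
A second, UV-detected channel quantifies hydroxyproline (internal standard
alpha-amino-butyric acid), from which collagen content follows as

    collagen (mol) = hydroxyproline mass (g) * 7.5 / 30000

(hydroxyproline is 13-14 % of type I collagen by mass; 30,000 Da is the
collagen molecular weight used for the mol conversion).  Crosslink results
are reported as mol analyte per mol collagen.

Peak areas use a local linear baseline drawn between the integration
window endpoints (5-point median at each end) with the area above the
baseline integrated trapezoidally and clipped at zero.  Calibration is
ordinary least squares of response ratio (analyte area / internal-standard
area) against standard amount, with a free intercept; curves with
r^2 < 0.98 are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .exceptions import (
    CalibrationError,
    InvalidRunError,
    ParameterError,
    UndefinedRatioError,
)

#: hydroxyproline-to-collagen mass factor (collagen is ~13.3 % hyp by mass)
HYP_TO_COLLAGEN_MASS = 7.5
#: collagen molecular weight used for the mol conversion, g/mol
COLLAGEN_MW = 30000.0
#: minimum calibration r-squared
CALIBRATION_R2_MIN = 0.98


@dataclass
class Chromatogram:
    """Detector signal vs retention time for one run."""

    retention_time: np.ndarray  # min
    signal: np.ndarray  # detector units
    channel: str = "fluorescence"  # "fluorescence" | "uv"
    animal_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.retention_time = np.asarray(self.retention_time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.retention_time.size != self.signal.size:
            raise ParameterError("retention_time/signal lengths differ")
        if np.any(np.diff(self.retention_time) <= 0):
            raise ParameterError("retention_time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal contains non-finite values")


@dataclass
class CalibrationCurve:
    """OLS response-ratio calibration for one analyte."""

    analyte: str
    standard_amounts: np.ndarray
    response_ratios: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass
class CrosslinkResult:
    """Per-animal crosslink content, mol per mol collagen."""

    pyd_per_collagen: float
    dpd_per_collagen: float
    pe_per_collagen: float
    collagen_amount: float  # mol
    hydroxyproline_mass: float  # g


def integrate_peak(
    chromatogram: Chromatogram, window: tuple[float, float]
) -> float:
    """Baseline-subtracted trapezoidal peak area within a retention window.

    A straight baseline is drawn between the window endpoints (each
    endpoint level is the median of the 5 samples nearest the endpoint);
    signal below the baseline is clipped to zero before integration.
    Invariant to any constant offset added to the whole signal.
    """
    rt, y = chromatogram.retention_time, chromatogram.signal
    lo, hi = window
    if lo >= hi:
        raise ParameterError("integration window is empty")
    if lo < rt[0] or hi > rt[-1]:
        raise ParameterError("integration window outside the run time")
    m = (rt >= lo) & (rt <= hi)
    if m.sum() < 5:
        raise ParameterError("integration window contains too few samples")
    idx = np.flatnonzero(m)

    def _edge_level(i: int) -> float:
        a, b = max(i - 2, 0), min(i + 3, y.size)
        return float(np.median(y[a:b]))

    y0 = _edge_level(idx[0])
    y1 = _edge_level(idx[-1])
    baseline = np.interp(rt[m], [rt[idx[0]], rt[idx[-1]]], [y0, y1])
    above = np.clip(y[m] - baseline, 0.0, None)
    return float(np.trapezoid(above, rt[m]))


def build_calibration(
    standards: Sequence[tuple[float, Chromatogram]],
    analyte_window: tuple[float, float],
    is_window: tuple[float, float],
    analyte: str = "",
    r2_min: float = CALIBRATION_R2_MIN,
) -> CalibrationCurve:
    """OLS line of response ratio vs standard amount.

    ``standards`` is a list of (amount, chromatogram) pairs sharing a
    constant internal-standard amount.  Raises :class:`CalibrationError`
    when r^2 falls below ``r2_min``.
    """
    if len(standards) < 3:
        raise ParameterError("need at least 3 calibration standards")
    amounts = np.array([a for a, _ in standards], dtype=float)
    if np.unique(amounts).size < 3:
        raise ParameterError("calibration standards must have distinct amounts")
    ratios = []
    for _a, chrom in standards:
        area_a = integrate_peak(chrom, analyte_window)
        area_is = integrate_peak(chrom, is_window)
        if area_is <= 0:
            raise InvalidRunError(
                "internal-standard peak missing in a calibration run"
            )
        ratios.append(area_a / area_is)
    ratios = np.asarray(ratios, dtype=float)
    fit = sstats.linregress(amounts, ratios)
    r2 = float(fit.rvalue**2)
    if r2 < r2_min:
        raise CalibrationError(
            f"calibration for {analyte or 'analyte'} rejected: "
            f"r^2 = {r2:.4f} < {r2_min}"
        )
    if fit.slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return CalibrationCurve(
        analyte=analyte,
        standard_amounts=amounts,
        response_ratios=ratios,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
    )


def quantify_analyte(
    sample: Chromatogram,
    cal: CalibrationCurve,
    analyte_window: tuple[float, float],
    is_window: tuple[float, float],
) -> float:
    """Amount of analyte in a sample run via the calibration curve.

    amount = (response ratio - intercept) / slope, floored at zero.
    Raises :class:`InvalidRunError` when the internal-standard peak is
    absent (normalisation impossible).
    """
    area_a = integrate_peak(sample, analyte_window)
    area_is = integrate_peak(sample, is_window)
    if area_is <= 0:
        raise InvalidRunError("internal-standard peak missing in sample run")
    ratio = area_a / area_is
    amount = (ratio - cal.intercept) / cal.slope
    return max(amount, 0.0)


def collagen_from_hydroxyproline(hyp_mass: float) -> float:
    """Collagen amount (mol) from hydroxyproline mass (g): m * 7.5 / 30000."""
    if hyp_mass < 0:
        raise ParameterError("hydroxyproline mass must be non-negative")
    return hyp_mass * HYP_TO_COLLAGEN_MASS / COLLAGEN_MW


def crosslink_ratios(
    amounts: dict[str, float], collagen_mol: float, hyp_mass: float = np.nan
) -> CrosslinkResult:
    """Normalise per-analyte amounts (mol) by collagen content (mol)."""
    if collagen_mol <= 0:
        raise UndefinedRatioError("collagen amount must be positive")
    return CrosslinkResult(
        pyd_per_collagen=amounts.get("pyd", np.nan) / collagen_mol,
        dpd_per_collagen=amounts.get("dpd", np.nan) / collagen_mol,
        pe_per_collagen=amounts.get("pe", np.nan) / collagen_mol,
        collagen_amount=collagen_mol,
        hydroxyproline_mass=hyp_mass,
    )
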