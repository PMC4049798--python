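"""Hertzian analysis of AFM force curves.

Each nanoindentation yields a force-separation curve; the withdrawal branch
is fit with the classic Hertz model of a rigid sphere contacting an elastic
half-space,

    F = 4 E sqrt(r) delta^(3/2) / (3 (1 - v^2)),

equivalently E = 3 F (1 - v^2) / (4 r^(1/2) delta^(3/2)), where delta is the
indentation depth (contact-point-referenced separation), r the tip radius
and v the sample Poisson ratio.  The modulus and the contact point are fit
jointly by least squares restricted to samples whose force lies between 5 %
and 95 % of the withdrawal peak force.

The fit profiles out the modulus: for a fixed contact point the model is
linear in E, so E has a closed form, and the residual sum of squares is
minimised over the contact point alone by a bounded 1-D search.  This is
fast enough for thousands of curves and cannot diverge; failures are
reported as ``converged=False`` rather than raised.

Curves whose withdrawal branch shows a pull-off (adhesion) force larger
than 10 % of the peak force are flagged ``adhesive`` and excluded from
aggregation: adhesion is not part of the Hertz model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import CurveRejectedError, NoConvergedFitsError, ParameterError

#: default Poisson's ratio of bone tissue
DEFAULT_POISSON = 0.35
#: default nominal tip radius, m
DEFAULT_TIP_RADIUS = 50e-9
#: force-fraction fit window (low, high) on the withdrawal branch
FIT_WINDOW = (0.05, 0.95)
#: pull-off force threshold (fraction of peak) above which a curve is adhesive
ADHESION_FRACTION = 0.10


@dataclass
class ForceCurve:
    """AFM force vs tip-sample separation with approach/withdraw labels."""

    separation: np.ndarray  # m
    force: np.ndarray  # N
    segment: np.ndarray  # "approach" | "withdraw" per sample
    grid_position: tuple[int, int] = (0, 0)
    animal_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (
            self.separation.size == self.force.size == self.segment.size
        ):
            raise ParameterError("separation/force/segment lengths differ")
        if not np.any(self.segment == "withdraw"):
            raise ParameterError("withdraw segment is empty")

    def withdraw(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == "withdraw"
        return self.separation[m], self.force[m]


@dataclass
class HertzFit:
    """Result of a Hertz fit to one force curve."""

    modulus: float  # Pa
    contact_point: float  # m (separation of first contact)
    poisson: float
    tip_radius: float
    fit_window: tuple[float, float]
    residual_rms: float  # N
    converged: bool
    adhesive: bool = False
    animal_id: str = ""
    group_label: str = ""


def hertz_force(
    delta: np.ndarray | float,
    modulus: float,
    tip_radius: float = DEFAULT_TIP_RADIUS,
    poisson: float = DEFAULT_POISSON,
) -> np.ndarray | float:
    """Forward Hertz model: force at indentation depth ``delta`` (m)."""
    d = np.maximum(np.asarray(delta, dtype=float), 0.0)
    out = 4.0 * modulus * np.sqrt(tip_radius) * d**1.5 / (3.0 * (1.0 - poisson**2))
    return float(out) if np.isscalar(delta) else out


def hertz_modulus_pointwise(
    force: float,
    delta: float,
    tip_radius: float = DEFAULT_TIP_RADIUS,
    poisson: float = DEFAULT_POISSON,
) -> float:
    """Closed-form modulus from a single (force, depth) pair.

    Direct algebraic inversion: E = 3 F (1 - v^2) / (4 r^(1/2) delta^(3/2)).
    """
    if delta <= 0:
        raise ParameterError("indentation depth must be positive")
    return 3.0 * force * (1.0 - poisson**2) / (4.0 * np.sqrt(tip_radius) * delta**1.5)


def fit_hertz(
    curve: ForceCurve,
    poisson: float = DEFAULT_POISSON,
    tip_radius: float = DEFAULT_TIP_RADIUS,
    fit_window: tuple[float, float] = FIT_WINDOW,
) -> HertzFit:
    """Fit the Hertz model to the withdrawal branch of one force curve.

    Samples with force between ``fit_window`` fractions of the withdrawal
    peak are used.  Returns ``converged=False`` (never raises) when the
    optimiser cannot produce a positive modulus; raises
    :class:`CurveRejectedError` only for structurally degenerate curves.
    """
    if not 0 <= poisson < 0.5:
        raise ParameterError("poisson must be in [0, 0.5)")
    if tip_radius <= 0:
        raise ParameterError("tip_radius must be positive")
    sep, force = curve.withdraw()
    if sep.size < 20:
        raise CurveRejectedError("withdraw segment has fewer than 20 samples")
    fmax = float(np.max(force))
    if fmax <= 0:
        raise CurveRejectedError("withdraw segment has no positive force")

    adhesive = float(np.min(force)) < -ADHESION_FRACTION * fmax

    lo, hi = fit_window
    sel = (force >= lo * fmax) & (force <= hi * fmax)
    if sel.sum() < 10:
        raise CurveRejectedError("too few samples inside the fit window")
    s, f = sep[sel], force[sel]

    # prefactor: F = E * scale * delta^(3/2)
    scale = 4.0 * np.sqrt(tip_radius) / (3.0 * (1.0 - poisson**2))

    # contact point is estimated on every sample below the window cap --
    # the out-of-contact noise floor (model force = 0) pins z0 far better
    # than the high-force window alone and removes most of the joint-fit
    # bias; the modulus is then computed on the 5-95 % window only
    sel_z = force <= hi * fmax
    s_z, f_z = sep[sel_z], force[sel_z]

    def rss(z0: float) -> float:
        x = np.maximum(z0 - s_z, 0.0) ** 1.5
        sxx = float(np.dot(x, x))
        if sxx <= 0.0:
            return float(np.dot(f_z, f_z))
        k = float(np.dot(x, f_z)) / sxx
        r = f_z - k * x
        return float(np.dot(r, r))

    # coarse grid over the plausible range, then Brent refinement
    z_lo = float(np.min(s_z))
    z_hi = float(np.max(sep)) + (float(np.max(sep)) - z_lo)
    grid = np.linspace(z_lo, z_hi, 200)
    vals = [rss(z) for z in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(rss, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-13})
    z0 = float(res.x)

    x = np.maximum(z0 - s, 0.0) ** 1.5
    sxx = float(np.dot(x, x))
    converged = sxx > 0.0
    modulus = np.nan
    rms = np.nan
    if converged:
        k = float(np.dot(x, f)) / sxx
        modulus = k / scale
        rms = float(np.sqrt(np.mean((f - k * x) ** 2)))
        if not np.isfinite(modulus) or modulus <= 0:
            converged = False
    return HertzFit(
        modulus=modulus,
        contact_point=z0,
        poisson=poisson,
        tip_radius=tip_radius,
        fit_window=fit_window,
        residual_rms=rms,
        converged=converged,
        adhesive=adhesive,
        animal_id=curve.animal_id,
        group_label=curve.group_label,
    )


def usable(fit: HertzFit) -> bool:
    """A fit that enters aggregation: converged and not adhesive."""
    return fit.converged and not fit.adhesive


def aggregate_moduli(
    fits: Sequence[HertzFit],
    scheme: Literal["per-animal-mean", "pooled"] = "per-animal-mean",
) -> dict[str, float] | np.ndarray:
    """Aggregate converged fits.

    ``per-animal-mean``: arithmetic mean modulus over each animal's usable
    fits (dict animal_id -> mean Pa).  ``pooled``: flat array of all usable
    moduli, retained for distribution comparisons.
    """
    good = [f for f in fits if usable(f)]
    if scheme == "pooled":
        return np.array([f.modulus for f in good], dtype=float)
    if scheme != "per-animal-mean":
        raise ParameterError(f"unknown aggregation scheme {scheme!r}")
    animals: dict[str, list[float]] = {}
    for f in fits:
        animals.setdefault(f.animal_id, [])
        if usable(f):
            animals[f.animal_id].append(f.modulus)
    out = {}
    for animal, vals in animals.items():
        if not vals:
            raise NoConvergedFitsError(
                f"no converged Hertz fits for animal {animal!r}"
            )
        out[animal] = float(np.mean(vals))
    return out
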