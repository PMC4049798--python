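"""Reference point indentation (RPI) cycle analysis.

Cyclic microindentation of bone (Biodent-style protocol: repeated force
cycles to a fixed peak force through a probe resting on the bone surface)
produces a force-displacement trace per test site.  This module segments a
multi-cycle trace into its cycles and computes the seven standard outcome
measures:

* first cycle indentation distance (ID1, µm)
* first cycle energy dissipation (ED1, µJ)
* first cycle unloading slope (US1, N/µm)
* first cycle creep indentation distance (CID1, µm)
* indentation distance increase (IDI, µm) -- extra depth at peak force of
  the last cycle relative to the first; higher IDI marks tissue more prone
  to damage under repeated loading
* total indentation distance (TID, µm)
* total energy dissipation (TED, µJ)

Depths are referenced to the touchdown origin (first surface contact).
Energy per cycle is the area enclosed by the loading-unloading loop in
force-displacement space (1 N·µm = 1 µJ), evaluated by the shoelace formula
on the raw samples -- no smoothing or filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from .exceptions import (
    InsufficientCyclesError,
    NoContactError,
    ParameterError,
    SegmentationError,
)

#: default touchdown force threshold, N (1 % of the 10 N protocol peak)
TOUCHDOWN_THRESHOLD_N = 0.1

#: unloading-slope fit window as fractions of peak force (high, low)
SLOPE_FIT_WINDOW = (0.95, 0.40)

#: a sample is "at peak force" when within this relative tolerance of the
#: cycle maximum; the constant-force dwell is the contiguous run of such
#: samples
PEAK_FORCE_RTOL = 1e-3


@dataclass
class IndentationTrace:
    """Time/force/displacement series for one multi-cycle test at one site.

    Displacement is positive into the bone, in µm; force in N; time in s.
    """

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    site_id: str = ""
    animal_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if not (n == self.force.size == self.displacement.size):
            raise ParameterError("time/force/displacement lengths differ")
        if n < 100:
            raise ParameterError("trace shorter than 100 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")

    def check_peak_force(self, protocol_peak_n: float, rtol: float = 0.05):
        """Verify the trace reached the protocol peak force within ``rtol``."""
        peak = float(np.max(self.force))
        if abs(peak - protocol_peak_n) > rtol * protocol_peak_n:
            raise ParameterError(
                f"max force {peak:.3g} N outside {rtol:.0%} of protocol "
                f"peak {protocol_peak_n:.3g} N"
            )


@dataclass
class CycleMetrics:
    """Per-cycle outcome measures (depths in µm, energy in µJ, slope N/µm)."""

    cycle_index: int
    depth_at_peak: float
    indentation_distance: float
    unloading_slope: float
    energy_dissipated: float
    creep_distance: float
    dwell_missing: bool = False


@dataclass
class RPISummary:
    """The seven per-test outcome measures."""

    first_cycle_indentation_distance: float
    first_cycle_energy_dissipation: float
    first_cycle_unloading_slope: float
    first_cycle_creep_distance: float
    indentation_distance_increase: float
    total_indentation_distance: float
    total_energy_dissipation: float


def polygon_area(x: np.ndarray, y: np.ndarray) -> float:
    """Unsigned area of the closed polygon (x_i, y_i) by the shoelace formula.

    The polygon is implicitly closed from the last vertex back to the first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    )


def detect_touchdown(
    trace: IndentationTrace, force_threshold: float = TOUCHDOWN_THRESHOLD_N
) -> float:
    """Displacement origin: displacement at the first sample above threshold.

    All depths are reported relative to this origin.  Raises
    :class:`NoContactError` if the force never exceeds the threshold, and
    :class:`ParameterError` if the trace does not begin below it.
    """
    above = trace.force > force_threshold
    if not above.any():
        raise NoContactError(
            f"force never exceeded touchdown threshold {force_threshold} N"
        )
    first = int(np.argmax(above))
    if first == 0:
        raise ParameterError(
            "trace must begin below the touchdown force threshold"
        )
    return float(trace.displacement[first])


def segment_cycles(
    trace: IndentationTrace,
    expected_cycles: int,
    peak_fraction: float = 0.9,
) -> list[tuple[int, int]]:
    """Split a trace into ``expected_cycles`` contiguous half-open ranges.

    Peaks are located as contiguous runs of samples above
    ``peak_fraction * max(force)``; cycle boundaries are placed at the force
    minimum between consecutive peak runs.  Raises
    :class:`SegmentationError` when the number of detected peaks differs
    from ``expected_cycles``.
    """
    f = trace.force
    n = f.size
    high = f >= peak_fraction * float(np.max(f))
    # contiguous runs of "high" samples, one per cycle
    idx = np.flatnonzero(high)
    runs: list[tuple[int, int]] = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.r_[idx[0], idx[breaks + 1]]
        run_ends = np.r_[idx[breaks], idx[-1]]
        runs = list(zip(run_starts.tolist(), run_ends.tolist()))
    if len(runs) != expected_cycles:
        raise SegmentationError(found=len(runs), expected=expected_cycles)
    # boundary between consecutive runs: last index attaining the minimum
    # force (a full unload may hold zero force across several samples; the
    # next cycle starts at the final one)
    bounds = [0]
    for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
        seg = f[e0 + 1 : s1]
        at_min = np.flatnonzero(seg == seg.min())
        bounds.append(e0 + 1 + int(at_min[-1]))
    bounds.append(n)
    return [(bounds[i], bounds[i + 1]) for i in range(expected_cycles)]


def _dwell_run(force: np.ndarray) -> tuple[int, int] | None:
    """Longest contiguous run of samples at the cycle's peak force.

    Returns (start, end) inclusive indices, or None if no run of at least
    3 samples exists (no resolvable dwell).
    """
    fmax = float(np.max(force))
    at_peak = force >= fmax * (1.0 - PEAK_FORCE_RTOL)
    idx = np.flatnonzero(at_peak)
    if idx.size == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_ends = np.r_[idx[breaks], idx[-1]]
    lengths = run_ends - run_starts
    best = int(np.argmax(lengths))
    if run_ends[best] - run_starts[best] + 1 < 3:
        return None
    return int(run_starts[best]), int(run_ends[best])


def analyze_cycle(
    time: np.ndarray,
    force: np.ndarray,
    displacement: np.ndarray,
    origin: float,
    cycle_index: int = 1,
    slope_fit_window: tuple[float, float] = SLOPE_FIT_WINDOW,
) -> CycleMetrics:
    """Compute the per-cycle metrics from one cycle's samples.

    * ``depth_at_peak``: depth at first attainment of the cycle peak force.
    * ``indentation_distance``: maximum depth minus the origin.
    * ``creep_distance``: depth change across the constant-force dwell.
    * ``energy_dissipated``: shoelace area of the force-displacement loop.
    * ``unloading_slope``: dF/dx of the unloading branch restricted to the
      ``slope_fit_window`` force fractions.  Displacement is regressed on
      force (force is the commanded, low-noise channel) and the slope
      inverted, which avoids regression-attenuation bias from displacement
      noise.

    When the dwell run spans enough samples, its endpoints are taken from a
    least-squares line through the dwell (robust to displacement noise); the
    dwell start doubles as the depth at first attainment of peak force.  If
    no dwell is resolvable, creep falls back to the depth change over the
    top 5 % force window and the result carries ``dwell_missing=True``.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(force, dtype=float)
    x = np.asarray(displacement, dtype=float)
    if t.size < 10:
        raise ParameterError("cycle has too few samples")
    fmax = float(np.max(f))

    run = _dwell_run(f)
    dwell_missing = run is None
    if run is not None and run[1] - run[0] + 1 >= 10:
        s, e = run
        # linear trend through the dwell; evaluate at its end points
        coef = np.polyfit(t[s : e + 1], x[s : e + 1], 1)
        d_start = float(np.polyval(coef, t[s]))
        d_end = float(np.polyval(coef, t[e]))
        unload_from = e + 1
    elif run is not None:
        s, e = run
        d_start = float(x[s])
        d_end = float(x[e])
        unload_from = e + 1
    else:
        # no dwell: creep over the top-5%-force window, flagged
        top = np.flatnonzero(f >= 0.95 * fmax)
        s, e = int(top[0]), int(top[-1])
        d_start = float(x[s])
        d_end = float(x[e])
        unload_from = e + 1

    depth_at_peak = d_start - origin
    creep = d_end - d_start
    indentation_distance = d_end - origin

    energy = polygon_area(x, f)

    # unloading branch: samples after the dwell within the force window
    hi, lo = slope_fit_window
    fu = f[unload_from:]
    xu = x[unload_from:]
    sel = (fu <= hi * fmax) & (fu >= lo * fmax)
    if sel.sum() < 5:
        raise ParameterError(
            "unloading branch has too few samples in the slope fit window"
        )
    # regress displacement on force; slope is dF/dx = 1/b
    b, _a = np.polyfit(fu[sel], xu[sel], 1)
    if b == 0:
        raise ParameterError("degenerate unloading branch (zero dx/dF)")
    unloading_slope = 1.0 / float(b)

    return CycleMetrics(
        cycle_index=cycle_index,
        depth_at_peak=depth_at_peak,
        indentation_distance=indentation_distance,
        unloading_slope=unloading_slope,
        energy_dissipated=energy,
        creep_distance=creep,
        dwell_missing=dwell_missing,
    )


def summarize_test(cycles: Sequence[CycleMetrics]) -> RPISummary:
    """Collapse per-cycle metrics into the seven per-test outcome measures.

    IDI = depth_at_peak(last) - depth_at_peak(first); TID = maximum
    indentation distance over all cycles; TED = sum of per-cycle energies.
    """
    if len(cycles) < 2:
        raise InsufficientCyclesError(
            f"need at least 2 cycles, got {len(cycles)}"
        )
    first = cycles[0]
    return RPISummary(
        first_cycle_indentation_distance=first.indentation_distance,
        first_cycle_energy_dissipation=first.energy_dissipated,
        first_cycle_unloading_slope=first.unloading_slope,
        first_cycle_creep_distance=first.creep_distance,
        indentation_distance_increase=(
            cycles[-1].depth_at_peak - first.depth_at_peak
        ),
        total_indentation_distance=max(
            c.indentation_distance for c in cycles
        ),
        total_energy_dissipation=sum(c.energy_dissipated for c in cycles),
    )


def analyze_trace(
    trace: IndentationTrace,
    expected_cycles: int = 10,
    force_threshold: float = TOUCHDOWN_THRESHOLD_N,
    slope_fit_window: tuple[float, float] = SLOPE_FIT_WINDOW,
) -> RPISummary:
    """Full per-test pipeline: touchdown, segmentation, cycle metrics, summary."""
    origin = detect_touchdown(trace, force_threshold)
    ranges = segment_cycles(trace, expected_cycles)
    cycles = [
        analyze_cycle(
            trace.time[a:b],
            trace.force[a:b],
            trace.displacement[a:b],
            origin,
            cycle_index=i + 1,
            slope_fit_window=slope_fit_window,
        )
        for i, (a, b) in enumerate(ranges)
    ]
    return summarize_test(cycles)


def aggregate_animal(summaries: Sequence[RPISummary]) -> RPISummary:
    """Arithmetic mean of each outcome measure across a test sites.

    All tests from one animal are averaged to a single per-animal value.
    """
    if not summaries:
        raise ParameterError("no summaries to aggregate")
    vals = {
        f.name: float(np.mean([getattr(s, f.name) for s in summaries]))
        for f in fields(RPISummary)
    }
    return RPISummary(**vals)
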