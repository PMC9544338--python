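"""Plate-screen hit calling and dose-dependence analysis.

Per-well metrics are (i) the binding rate ``k_bind`` fitted on the trace
restricted to the screening window and (ii) ``max_uptake``, the maximal
signal rise above the first reading within the window.  Hits are called
per plate against the vehicle-control (DMSO) wells: a compound well is a
hit on a metric when its value deviates from the control mean by at least
the metric's threshold in control standard deviations (2 SD for
``k_bind``, 3 SD for ``max_uptake``), in either direction, boundary
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateFitError,
    InsufficientControlsError,
    InvalidInputError,
    ZeroVarianceError,
)
from .kinetic_models import KineticTrace
from .trace_fitting import FitOptions, FitResult, fit_k_bind

__all__ = [
    "WELL_ROLES",
    "METRICS",
    "Well",
    "ScreenPlate",
    "WellMetrics",
    "ControlStats",
    "HitCall",
    "DoseResponse",
    "compute_well_metrics",
    "compute_plate_metrics",
    "control_stats",
    "call_hits",
    "make_hit_call",
    "dose_response",
    "DEFAULT_WINDOW_S",
    "KBIND_THRESHOLD_SD",
    "UPTAKE_THRESHOLD_SD",
]

WELL_ROLES = ("dmso", "compound", "empty")
METRICS = ("k_bind", "max_uptake")

DEFAULT_WINDOW_S = 600.0
KBIND_THRESHOLD_SD = 2.0
UPTAKE_THRESHOLD_SD = 3.0
MIN_CONTROL_WELLS = 8

_GRID_RTOL = 1e-6


@dataclass
class Well:
    role: str
    compound_id: str | None = None
    concentration_uM: float | None = None
    trace: KineticTrace | None = None

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise InvalidInputError(f"unknown well role {self.role!r}")


@dataclass
class ScreenPlate:
    """Plate map plus per-well traces sharing a common time grid."""

    plate_id: str
    wells: dict[str, Well]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = None
        for well_id, well in self.wells.items():
            if well.trace is None:
                continue
            if grid is None:
                grid = well.trace.times
            elif well.trace.times.shape != grid.shape or not np.allclose(
                well.trace.times, grid, rtol=_GRID_RTOL, atol=1e-9
            ):
                raise InvalidInputError(
                    f"well {well_id}: trace time grid differs from the plate grid"
                )

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, well in self.wells.items() if well.role == role)


@dataclass
class WellMetrics:
    k_bind: float | None
    max_uptake: float | None
    flags: list[str] = field(default_factory=list)

    def get(self, metric: str) -> float | None:
        if metric not in METRICS:
            raise InvalidInputError(f"unknown metric {metric!r}")
        return getattr(self, metric)


@dataclass(frozen=True)
class ControlStats:
    mean: float
    sd: float
    n: int


@dataclass
class HitCall:
    well_id: str
    compound_id: str | None
    metric: str
    value: float | None
    control_mean: float
    control_sd: float
    z: float | None
    direction: str | None  # "up" | "down"
    is_hit: bool
    threshold_sd: float


@dataclass(frozen=True)
class DoseResponse:
    f_statistic: float
    p_value: float
    dose_means: dict[float, float]
    monotone: bool


def _window_trace(trace: KineticTrace, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    rel = trace.times - trace.times[0]
    mask = rel <= window_s * (1.0 + 1e-9)
    if mask.sum() < 8:
        raise InvalidInputError("fewer than 8 samples inside the screening window")
    return trace.times[mask], trace.signal[mask]


def compute_well_metrics(
    trace: KineticTrace,
    window_s: float = DEFAULT_WINDOW_S,
    opts: FitOptions | None = None,
) -> WellMetrics:
    """Compute the two screening metrics on the trace's screening window.

    ``max_uptake`` is the maximal signal minus the first reading inside the
    window; ``k_bind`` comes from the association fit on the windowed
    signal and is flagged missing when the fit is degenerate or fails.
    """
    times, signal = _window_trace(trace, window_s)
    max_uptake = float(np.max(signal) - signal[0])
    flags: list[str] = []
    k_bind: float | None = None
    try:
        windowed = KineticTrace(times, signal, "association", well_id=trace.well_id)
        fr = fit_k_bind(windowed, opts)
        if fr.converged:
            k_bind = float(fr.params.k_bind)
        else:
            flags.append("k_bind fit did not converge")
    except DegenerateFitError:
        flags.append("k_bind missing: flat trace")
    return WellMetrics(k_bind=k_bind, max_uptake=max_uptake, flags=flags)


def compute_plate_metrics(
    plate: ScreenPlate,
    window_s: float = DEFAULT_WINDOW_S,
    opts: FitOptions | None = None,
) -> dict[str, WellMetrics]:
    """Metrics for every non-empty well with a trace, keyed by well id."""
    out = {}
    for well_id in sorted(plate.wells):
        well = plate.wells[well_id]
        if well.role == "empty" or well.trace is None:
            continue
        out[well_id] = compute_well_metrics(well.trace, window_s, opts)
    return out


def control_stats(
    plate: ScreenPlate,
    metric: str,
    window_s: float = DEFAULT_WINDOW_S,
    metrics: dict[str, WellMetrics] | None = None,
) -> ControlStats:
    """Plain mean and sample SD of a metric over this plate's DMSO wells."""
    if metric not in METRICS:
        raise InvalidInputError(f"unknown metric {metric!r}")
    if metrics is None:
        metrics = compute_plate_metrics(plate, window_s)
    values = [
        metrics[w].get(metric)
        for w in plate.wells_with_role("dmso")
        if w in metrics and metrics[w].get(metric) is not None
    ]
    if len(values) < MIN_CONTROL_WELLS:
        raise InsufficientControlsError(
            f"{len(values)} usable dmso wells for {metric}; need >= {MIN_CONTROL_WELLS}"
        )
    arr = np.asarray(values, dtype=float)
    return ControlStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


def make_hit_call(
    well_id: str,
    compound_id: str | None,
    metric: str,
    value: float | None,
    ctrl: ControlStats,
    threshold_sd: float,
) -> HitCall:
    """Score a single value against control statistics (boundary inclusive)."""
    if value is None:
        return HitCall(well_id, compound_id, metric, None, ctrl.mean, ctrl.sd, None, None, False, threshold_sd)
    if ctrl.sd == 0.0:
        raise ZeroVarianceError(f"control SD for {metric} is zero")
    z = (value - ctrl.mean) / ctrl.sd
    return HitCall(
        well_id=well_id,
        compound_id=compound_id,
        metric=metric,
        value=float(value),
        control_mean=ctrl.mean,
        control_sd=ctrl.sd,
        z=float(z),
        direction="up" if z >= 0 else "down",
        is_hit=bool(abs(z) >= threshold_sd),
        threshold_sd=threshold_sd,
    )


def call_hits(
    plate: ScreenPlate,
    window_s: float = DEFAULT_WINDOW_S,
    kbind_sd: float = KBIND_THRESHOLD_SD,
    uptake_sd: float = UPTAKE_THRESHOLD_SD,
    opts: FitOptions | None = None,
) -> list[HitCall]:
    """One HitCall per compound well per metric, two-sided, per-plate controls.

    Wells whose ``k_bind`` fit failed are still scored on ``max_uptake``
    (the missing metric yields a non-hit call with ``value=None``).
    """
    metrics = compute_plate_metrics(plate, window_s, opts)
    thresholds = {"k_bind": kbind_sd, "max_uptake": uptake_sd}
    ctrl = {m: control_stats(plate, m, window_s, metrics) for m in METRICS}
    for m in METRICS:
        if ctrl[m].sd == 0.0:
            raise ZeroVarianceError(f"control SD for {m} is zero")
    calls: list[HitCall] = []
    for well_id in plate.wells_with_role("compound"):
        if well_id not in metrics:
            continue
        wm = metrics[well_id]
        compound_id = plate.wells[well_id].compound_id
        for m in METRICS:
            calls.append(
                make_hit_call(well_id, compound_id, m, wm.get(m), ctrl[m], thresholds[m])
            )
    return calls


def dose_response(
    doses,
    groups,
    which: str = "k_hydr",
) -> DoseResponse:
    """One-way fixed-effects ANOVA of a fitted rate across dose groups.

    Parameters
    ----------
    doses : sequence of float
        Concentration of each group, same order as ``groups``.
    groups : sequence of sequences
        Per-dose replicate values; entries may be floats or
        :class:`FitResult` objects (the rate ``which`` is extracted).
    which : {"k_hydr", "k_bind"}
        Rate extracted from FitResult entries.

    The ``monotone`` flag is True when the per-dose means, ordered by dose,
    are non-decreasing or non-increasing.
    """
    doses = [float(d) for d in doses]
    if len(doses) != len(groups):
        raise InvalidInputError("doses and groups must have the same length")
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 dose groups")
    values = []
    for g in groups:
        vals = [v.rate(which) if isinstance(v, FitResult) else float(v) for v in g]
        if len(vals) < 2:
            raise InvalidInputError("every dose group needs >= 2 replicates")
        values.append(np.asarray(vals, dtype=float))

    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in values)
    means = {d: float(v.mean()) for d, v in zip(doses, values)}
    ordered = [means[d] for d in sorted(means)]
    diffs = np.diff(ordered)
    monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))

    grand = np.concatenate(values).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    if ssw == 0.0:
        if ssb == 0.0:
            # all observations identical: conventionally no effect
            return DoseResponse(0.0, 1.0, means, monotone)
        raise ZeroVarianceError("zero within-group variance; F undefined")
    f_stat, p_val = stats.f_oneway(*values)
    return DoseResponse(float(f_stat), float(p_val), means, monotone)
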