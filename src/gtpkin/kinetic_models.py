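"""Closed-form forward models for fluorescent nucleotide assays.

Three single-well assay geometries are modelled, all driven by first-order
(observed) kinetics of a fluorescent probe on a 1:1 protein/probe mix:

``association``
    Non-hydrolyzable probe.  The signal is a single rising exponential
    ``F(t) = F_free + A * (1 - exp(-k_bind * (t - t0)))``.

``binding_hydrolysis``
    Hydrolyzable probe.  A sequential first-order scheme
    free -> bound-GTP* -> bound-GDP* gives a transient rise followed by a
    decay towards ``F_free + rho * A`` (the hydrolyzed product is dimmer by
    the factor ``rho``).

``displacement``
    A probe-loaded protein is challenged with excess unlabelled nucleotide
    at ``t_inj``; the signal drops (optionally with an instantaneous
    dilution step ``d_inj``) as a single exponential with rate ``k_diss``
    towards a residual level set by the retained fraction ``f_ret``.

Every closed form has a matching numerical-ODE route (:func:`ode_signal`)
integrated with tight tolerances; the two are kept deliberately
independent so each can check the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidInputError

__all__ = [
    "ASSAY_KINDS",
    "KineticParams",
    "KineticTrace",
    "bound_gtp_fraction",
    "hydrolyzed_fraction",
    "simulate_association",
    "simulate_binding_hydrolysis",
    "simulate_displacement",
    "ode_signal",
    "ode_species",
    "RATE_DEGENERACY_RTOL",
]

ASSAY_KINDS = ("association", "binding_hydrolysis", "displacement")

#: relative gap below which k_bind and k_hydr are treated as equal and the
#: analytic equal-rates limit is used (avoids catastrophic cancellation).
RATE_DEGENERACY_RTOL = 1e-6

_MIN_SAMPLES = 8


@dataclass(frozen=True)
class KineticParams:
    """Forward-model parameter set.

    Rates are in s^-1, fluorescence levels in arbitrary units (AU).

    Attributes
    ----------
    k_bind : float
        Observed first-order binding rate of the probe.
    k_hydr : float
        First-order hydrolysis rate of the bound probe.
    k_diss : float
        First-order dissociation rate after nucleotide challenge.
    F_free : float
        Fluorescence of the fully unbound state.
    A : float
        Full-binding amplitude (bound state minus ``F_free``).
    rho : float
        Relative brightness of the bound, hydrolyzed probe, in [0, 1).
    t0 : float
        Dead time between mixing and first usable model time, s.
    t_inj : float, optional
        Displacement-injection time (displacement assay only).
    d_inj : float
        Multiplicative dilution factor applied at ``t_inj``, in (0, 1].
        Default 0.8 (a 5 ul injection into 20 ul: 20/25).
    f_ret : float
        Residual retained fraction of bound probe after displacement.
    """

    k_bind: float = 0.0
    k_hydr: float = 0.0
    k_diss: float = 0.0
    F_free: float = 0.0
    A: float = 0.0
    rho: float = 0.2
    t0: float = 0.0
    t_inj: float | None = None
    d_inj: float = 0.8
    f_ret: float = 0.2

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_hydr", "k_diss"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.F_free) or self.F_free < 0:
            raise InvalidInputError(f"F_free must be finite and >= 0, got {self.F_free!r}")
        if not math.isfinite(self.A) or self.A < 0:
            raise InvalidInputError(f"A must be finite and >= 0, got {self.A!r}")
        if not (0.0 <= self.rho < 1.0):
            raise InvalidInputError(f"rho must lie in [0, 1), got {self.rho!r}")
        if not math.isfinite(self.t0) or self.t0 < 0:
            raise InvalidInputError(f"t0 must be finite and >= 0, got {self.t0!r}")
        if not (0.0 < self.d_inj <= 1.0):
            raise InvalidInputError(f"d_inj must lie in (0, 1], got {self.d_inj!r}")
        if not (0.0 <= self.f_ret <= 1.0):
            raise InvalidInputError(f"f_ret must lie in [0, 1], got {self.f_ret!r}")

    def with_(self, **changes) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class KineticTrace:
    """One well's fluorescence time series.

    ``injection_index`` must be present exactly when
    ``assay_kind == "displacement"``; it is the index of the first reading
    taken at or after the injection.
    """

    times: np.ndarray
    signal: np.ndarray
    assay_kind: str
    injection_index: int | None = None
    well_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.assay_kind not in ASSAY_KINDS:
            raise InvalidInputError(f"unknown assay_kind {self.assay_kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise InvalidInputError("times and signal must be 1-D arrays of equal length")
        if self.times.size < _MIN_SAMPLES:
            raise InvalidInputError(f"need >= {_MIN_SAMPLES} samples, got {self.times.size}")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.signal)):
            raise InvalidInputError("times and signal must be finite")
        if (self.assay_kind == "displacement") != (self.injection_index is not None):
            raise InvalidInputError(
                "injection_index must be set iff assay_kind == 'displacement'"
            )
        if self.injection_index is not None and not (
            0 <= int(self.injection_index) < self.times.size
        ):
            raise InvalidInputError("injection_index out of range")

    def __len__(self) -> int:
        return int(self.times.size)


def _check_time_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < _MIN_SAMPLES:
        raise InvalidInputError(f"time grid must be 1-D with >= {_MIN_SAMPLES} points")
    if not np.all(np.diff(times) > 0):
        raise InvalidInputError("time grid must be strictly increasing")
    if times[0] < 0 or not np.all(np.isfinite(times)):
        raise InvalidInputError("time grid must be finite and within [0, inf)")
    return times


def bound_gtp_fraction(
    tau: np.ndarray,
    k_bind: float,
    k_hydr: float,
    degeneracy_rtol: float = RATE_DEGENERACY_RTOL,
) -> np.ndarray:
    """Fraction of total probe in the bound, unhydrolyzed state at time tau.

    Sequential scheme free --k_bind--> bound* --k_hydr--> hydrolyzed*, with
    unit total probe and everything free at ``tau = 0``.  Uses the analytic
    equal-rates limit ``k * tau * exp(-k * tau)`` when the two rates agree
    to within ``degeneracy_rtol``.
    """
    tau = np.asarray(tau, dtype=float)
    if k_bind == 0.0:
        return np.zeros_like(tau)
    if abs(k_bind - k_hydr) < degeneracy_rtol * max(k_bind, k_hydr):
        k = 0.5 * (k_bind + k_hydr)
        return k * tau * np.exp(-k * tau)
    return (k_bind / (k_hydr - k_bind)) * (np.exp(-k_bind * tau) - np.exp(-k_hydr * tau))


def hydrolyzed_fraction(
    tau: np.ndarray,
    k_bind: float,
    k_hydr: float,
    degeneracy_rtol: float = RATE_DEGENERACY_RTOL,
) -> np.ndarray:
    """Fraction of total probe in the bound, hydrolyzed state at time tau."""
    tau = np.asarray(tau, dtype=float)
    B = bound_gtp_fraction(tau, k_bind, k_hydr, degeneracy_rtol)
    return 1.0 - np.exp(-k_bind * tau) - B


def association_signal(params: KineticParams, times: np.ndarray) -> np.ndarray:
    tau = np.clip(np.asarray(times, dtype=float) - params.t0, 0.0, None)
    return params.F_free + params.A * (1.0 - np.exp(-params.k_bind * tau))


def binding_hydrolysis_signal(params: KineticParams, times: np.ndarray) -> np.ndarray:
    tau = np.clip(np.asarray(times, dtype=float) - params.t0, 0.0, None)
    B = bound_gtp_fraction(tau, params.k_bind, params.k_hydr)
    C = hydrolyzed_fraction(tau, params.k_bind, params.k_hydr)
    return params.F_free + params.A * (B + params.rho * C)


def displacement_signal(params: KineticParams, times: np.ndarray) -> np.ndarray:
    if params.t_inj is None:
        raise InvalidInputError("displacement model requires t_inj")
    times = np.asarray(times, dtype=float)
    F_pre = params.F_free + params.A
    F_res = params.F_free + params.f_ret * params.A
    out = np.full_like(times, F_pre, dtype=float)
    post = times >= params.t_inj
    dt = times[post] - params.t_inj
    out[post] = params.d_inj * (F_res + (F_pre - F_res) * np.exp(-params.k_diss * dt))
    return out


def simulate_association(params: KineticParams, times: np.ndarray) -> KineticTrace:
    """Simulate a non-hydrolyzable-probe association trace."""
    times = _check_time_grid(times)
    return KineticTrace(times, association_signal(params, times), "association")


def simulate_binding_hydrolysis(params: KineticParams, times: np.ndarray) -> KineticTrace:
    """Simulate a hydrolyzable-probe binding-then-decay trace."""
    times = _check_time_grid(times)
    return KineticTrace(times, binding_hydrolysis_signal(params, times), "binding_hydrolysis")


def simulate_displacement(params: KineticParams, times: np.ndarray) -> KineticTrace:
    """Simulate a nucleotide-challenge displacement trace.

    ``params.t_inj`` must lie inside the time grid; the trace's
    ``injection_index`` is set to the first sample at or after ``t_inj``.
    """
    times = _check_time_grid(times)
    if params.t_inj is None or not (times[0] <= params.t_inj <= times[-1]):
        raise InvalidInputError("t_inj must lie inside the time grid")
    signal = displacement_signal(params, times)
    inj = int(np.argmax(times >= params.t_inj))
    return KineticTrace(times, signal, "displacement", injection_index=inj)


# ---------------------------------------------------------------------------
# Numerical-ODE route (the independent oracle for the closed forms)
# ---------------------------------------------------------------------------

_ODE_OPTS = dict(method="DOP853", rtol=1e-12, atol=1e-14)


def ode_species(params: KineticParams, times: np.ndarray) -> np.ndarray:
    """Integrate the three-species sequential scheme numerically.

    Returns an array of shape (3, n): free, bound-GTP*, bound-GDP*
    fractions at each (dead-time-shifted) grid time.
    """
    times = np.asarray(times, dtype=float)
    tau = np.clip(times - params.t0, 0.0, None)
    kb, kh = params.k_bind, params.k_hydr

    def rhs(_t, y):
        free, bound, _hyd = y
        return [-kb * free, kb * free - kh * bound, kh * bound]

    t_end = float(tau[-1]) if tau[-1] > 0 else 1.0
    sol = solve_ivp(rhs, (0.0, t_end), [1.0, 0.0, 0.0], t_eval=np.unique(tau), **_ODE_OPTS)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    # map back onto the (possibly clipped/duplicated) tau grid
    idx = np.searchsorted(np.unique(tau), tau)
    return sol.y[:, idx]


def ode_signal(params: KineticParams, times: np.ndarray, assay_kind: str) -> np.ndarray:
    """Numerically integrated counterpart of the closed-form signals."""
    times = np.asarray(times, dtype=float)
    if assay_kind == "association":
        tau = np.clip(times - params.t0, 0.0, None)
        kb = params.k_bind

        def rhs(_t, y):
            return [kb * (1.0 - y[0])]

        t_end = float(tau[-1]) if tau[-1] > 0 else 1.0
        sol = solve_ivp(rhs, (0.0, t_end), [0.0], t_eval=np.unique(tau), **_ODE_OPTS)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        idx = np.searchsorted(np.unique(tau), tau)
        bound = sol.y[0, idx]
        return params.F_free + params.A * bound

    if assay_kind == "binding_hydrolysis":
        free, bound, hyd = ode_species(params, times)
        return params.F_free + params.A * (bound + params.rho * hyd)

    if assay_kind == "displacement":
        if params.t_inj is None:
            raise InvalidInputError("displacement model requires t_inj")
        kd, f_ret = params.k_diss, params.f_ret
        F_pre = params.F_free + params.A
        out = np.full_like(times, F_pre, dtype=float)
        post = times >= params.t_inj
        if np.any(post):
            def rhs(_t, y):
                return [-kd * (y[0] - f_ret)]

            t_post = times[post] - params.t_inj
            t_end = float(t_post[-1]) if t_post[-1] > 0 else 1.0
            sol = solve_ivp(rhs, (0.0, t_end), [1.0], t_eval=np.unique(t_post), **_ODE_OPTS)
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            idx = np.searchsorted(np.unique(t_post), t_post)
            bfrac = sol.y[0, idx]
            out[post] = params.d_inj * (params.F_free + params.A * bfrac)
        return out

    raise InvalidInputError(f"unknown assay_kind {assay_kind!r}")
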