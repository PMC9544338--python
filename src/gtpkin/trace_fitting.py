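"""Nonlinear least-squares estimation of rate constants from single-well traces.

Each fitter follows the same recipe: a heuristic initial guess (time to
half-rise / half-decay), a small multi-start (log-spaced starting rates)
run through :func:`scipy.optimize.least_squares` with box bounds, and
standard errors taken from the local curvature of the objective at the
optimum.  Ties between starts are broken by lowest residual sum of
squares, then by lowest hydrolysis rate.

Baseline conventions for the binding+hydrolysis fit:

``endpoint``
    The long-time asymptote ``F_free + rho * A`` is anchored to the final
    reading (the convention for traces that decay back to baseline).

``initial``
    ``F_free`` is anchored to the first reading (the convention for
    hydrolysis-dead, flat-top traces where no endpoint baseline exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import (
    ComparisonUndefinedError,
    DegenerateFitError,
    DivisionUnstableError,
    InvalidInputError,
)
from .kinetic_models import (
    KineticParams,
    KineticTrace,
    association_signal,
    binding_hydrolysis_signal,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "RateComparison",
    "FoldChange",
    "fit_k_bind",
    "fit_k_hydr",
    "fit_k_diss",
    "compare_rates",
    "fold_change",
    "batch_fit",
]

RATE_BOUNDS = (1e-8, 10.0)
RHO_BOUNDS = (0.0, 0.95)


@dataclass(frozen=True)
class FitOptions:
    """Knobs shared by the fitters.

    ``n_starts`` starting points are log-spaced around the heuristic rate
    guess by successive factors of ``start_factor``.
    """

    n_starts: int = 3
    start_factor: float = 4.0
    fit_dead_time: bool = False
    fix_rho: float | None = None  # pin rho (e.g. from probe calibration)
    fix_k_bind: float | None = None  # pin k_bind (e.g. from the association assay)
    baseline_window: int = 1  # readings averaged into the baseline anchor
    rate_bounds: tuple[float, float] = RATE_BOUNDS
    rho_bounds: tuple[float, float] = RHO_BOUNDS
    alpha: float = 0.05
    d_inj: float = 1.0  # dilution correction off unless explicitly enabled
    F_free: float | None = None  # reference for the retained fraction
    max_nfev: int | None = None

    def start_factors(self) -> np.ndarray:
        n = max(int(self.n_starts), 1)
        exps = np.arange(n) - (n - 1) / 2.0
        return self.start_factor ** exps


@dataclass
class FitResult:
    """Fitted parameters plus residual diagnostics and derived metrics."""

    params: KineticParams
    param_errors: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    baseline_mode: str | None = None
    derived: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    message: str = ""

    def rate(self, which: str) -> float:
        if which not in ("k_bind", "k_hydr", "k_diss"):
            raise InvalidInputError(f"unknown rate {which!r}")
        return getattr(self.params, which)

    def rate_error(self, which: str) -> float:
        return float(self.param_errors.get(which, float("nan")))

    def to_dict(self) -> dict:
        return {
            "params": {
                k: getattr(self.params, k)
                for k in ("k_bind", "k_hydr", "k_diss", "F_free", "A", "rho", "t0", "t_inj", "d_inj", "f_ret")
            },
            "param_errors": dict(self.param_errors),
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "baseline_mode": self.baseline_mode,
            "derived": dict(self.derived),
            "flags": list(self.flags),
            "message": self.message,
        }


@dataclass(frozen=True)
class RateComparison:
    """Welch-style z comparison of a dissociation rate against a binding rate."""

    ratio: float
    z: float
    p_value: float
    exceeds: bool
    alpha: float


@dataclass(frozen=True)
class FoldChange:
    """Mutant/wild-type rate ratio with quadrature-propagated relative error."""

    ratio: float
    rel_error: float


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

_LS_OPTS = dict(method="trf", ftol=1e-13, xtol=1e-13, gtol=1e-13)


def _noise_floor(signal: np.ndarray) -> float:
    """Robust per-sample noise estimate from first differences."""
    d = np.diff(signal)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def _is_flat(signal: np.ndarray) -> bool:
    rng = float(np.ptp(signal))
    if rng == 0.0:
        return True
    nf = _noise_floor(signal)
    n = signal.size
    # expected range of n iid Gaussian draws is ~ sigma * 2 sqrt(2 ln n)
    return rng <= nf * (2.0 * math.sqrt(2.0 * math.log(max(n, 3))) + 2.0)


def _smooth(signal: np.ndarray, width: int = 5) -> np.ndarray:
    if signal.size < 2 * width:
        return signal
    kernel = np.ones(width)
    num = np.convolve(signal, kernel, mode="same")
    den = np.convolve(np.ones_like(signal), kernel, mode="same")
    return num / den


def _half_crossing_time(times: np.ndarray, signal: np.ndarray, start: float, stop: float) -> float:
    """Time after times[0] at which the (smoothed) signal crosses midway."""
    y = _smooth(signal)
    half = start + 0.5 * (stop - start)
    rising = stop >= start
    hit = y >= half if rising else y <= half
    idx = int(np.argmax(hit))
    if not hit.any() or idx == 0:
        return float(times[min(1, times.size - 1)] - times[0])
    return float(times[idx] - times[0])


def _multistart(residual, x0_list, bounds, khydr_index=None, max_nfev=None):
    """Run least_squares from each start, return the best OptimizeResult.

    Ties in rss (within 1e-6 relative) go to the lowest hydrolysis rate.
    """
    results = []
    lo, hi = bounds
    for x0 in x0_list:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(
                residual, x0, bounds=bounds, max_nfev=max_nfev, **_LS_OPTS
            )
        except Exception:  # pragma: no cover - pathological objective
            continue
        if np.all(np.isfinite(res.x)):
            results.append(res)
    if not results:
        return None
    rss = [float(np.sum(r.fun**2)) for r in results]
    best_rss = min(rss)
    tol = 1e-6 * max(best_rss, 1e-300)
    tied = [r for r, s in zip(results, rss) if s <= best_rss + tol]
    if khydr_index is not None and len(tied) > 1:
        tied.sort(key=lambda r: r.x[khydr_index])
    return tied[0]


def _standard_errors(res, n_points: int) -> np.ndarray:
    """SEs from the Gauss-Newton curvature approximation at the optimum."""
    J = res.jac
    rss = float(np.sum(res.fun**2))
    p = J.shape[1]
    dof = max(n_points - p, 1)
    cov = np.linalg.pinv(J.T @ J) * (rss / dof)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def _require_kind(trace: KineticTrace, kind: str) -> None:
    if trace.assay_kind != kind:
        raise InvalidInputError(
            f"expected assay_kind={kind!r}, got {trace.assay_kind!r}"
        )


# ---------------------------------------------------------------------------
# association: k_bind
# ---------------------------------------------------------------------------

def fit_k_bind(trace: KineticTrace, opts: FitOptions | None = None) -> FitResult:
    """Fit the rising-exponential association model for {k_bind, F_free, A}.

    ``t0`` is additionally fitted when ``opts.fit_dead_time`` is set.
    Raises :class:`DegenerateFitError` on traces whose range is below the
    noise floor.
    """
    opts = opts or FitOptions()
    _require_kind(trace, "association")
    t, y = trace.times, trace.signal
    if _is_flat(y):
        raise DegenerateFitError("signal range below noise floor; no binding phase")

    f0 = float(y[0])
    a0 = max(float(y[-1] - y[0]), 1e-12)
    t_half = _half_crossing_time(t, y, f0, f0 + a0)
    k0 = math.log(2.0) / max(t_half, 1e-9)
    lo_k, hi_k = opts.rate_bounds
    k0 = min(max(k0, lo_k * 10), hi_k / 10)

    fit_t0 = opts.fit_dead_time
    span = float(t[-1] - t[0])

    def unpack(x):
        if fit_t0:
            return x[0], x[1], x[2], x[3]
        return x[0], x[1], x[2], 0.0

    def residual(x):
        k, f_free, a, t0 = unpack(x)
        p = KineticParams(k_bind=k, F_free=max(f_free, 0.0), A=max(a, 0.0), t0=max(t0, 0.0))
        return association_signal(p, t) - y

    lo = [lo_k, 0.0, 0.0] + ([0.0] if fit_t0 else [])
    hi = [hi_k, np.inf, np.inf] + ([0.5 * span] if fit_t0 else [])
    x0s = []
    for f in opts.start_factors():
        base = [k0 * f, f0, a0] + ([0.0] if fit_t0 else [])
        x0s.append(base)

    res = _multistart(residual, x0s, (lo, hi), max_nfev=opts.max_nfev)
    if res is None:
        return FitResult(
            params=KineticParams(k_bind=k0, F_free=max(f0, 0.0), A=a0),
            param_errors={},
            rss=float("inf"),
            n_points=len(trace),
            converged=False,
            message="all starts failed",
        )
    k, f_free, a, t0 = unpack(res.x)
    se = _standard_errors(res, len(trace))
    names = ["k_bind", "F_free", "A"] + (["t0"] if fit_t0 else [])
    params = KineticParams(k_bind=k, F_free=max(f_free, 0.0), A=max(a, 0.0), t0=max(t0, 0.0))
    return FitResult(
        params=params,
        param_errors=dict(zip(names, map(float, se))),
        rss=float(np.sum(res.fun**2)),
        n_points=len(trace),
        converged=bool(res.success),
        derived={"half_time_s": math.log(2.0) / k},
    )


# ---------------------------------------------------------------------------
# binding + hydrolysis: k_bind and k_hydr
# ---------------------------------------------------------------------------

def fit_k_hydr(
    trace: KineticTrace,
    baseline_mode: str = "endpoint",
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit the sequential binding+hydrolysis model.

    Free parameters are {k_bind, k_hydr, A, rho}; ``F_free`` is eliminated
    by the baseline convention (see module docstring).  ``k_hydr`` is
    reported with its standard error even when it sits at the lower bound
    (hydrolysis-dead traces).
    """
    opts = opts or FitOptions()
    _require_kind(trace, "binding_hydrolysis")
    if baseline_mode not in ("endpoint", "initial"):
        raise InvalidInputError(f"unknown baseline_mode {baseline_mode!r}")
    t, y = trace.times, trace.signal
    if _is_flat(y):
        raise DegenerateFitError("signal range below noise floor")

    # the endpoint anchor may average a tail window (the plateau is flat);
    # the initial anchor is always the first reading (the signal rises at once)
    w = max(int(opts.baseline_window), 1)
    y_first = float(y[0])
    y_last = float(np.mean(y[-w:]))
    ys = _smooth(y)
    i_peak = int(np.argmax(ys))
    peak = float(ys[i_peak])
    tail = float(np.median(y[-5:]))
    amp0 = max(peak - y_first, 1e-12)
    rho0 = min(max((tail - y_first) / amp0, 0.02), 0.9)
    t_half = _half_crossing_time(t[: i_peak + 1], y[: i_peak + 1], y_first, peak)
    kb0 = math.log(2.0) / max(t_half, 1e-9)
    span = float(t[-1] - t[0])
    decay = peak - tail
    if baseline_mode == "endpoint" and decay <= max(0.05 * amp0, 4.0 * _noise_floor(y)):
        raise DegenerateFitError(
            "trace shows no decay: the endpoint is not a post-hydrolysis plateau; "
            "use baseline_mode='initial' for flat-top traces"
        )
    if decay > 0.05 * amp0 and i_peak < t.size - 5:
        t_halfdec = _half_crossing_time(t[i_peak:], y[i_peak:], peak, tail)
        kh0 = math.log(2.0) / max(t_halfdec, 1e-9)
    else:
        kh0 = 0.2 / max(span, 1e-9)

    lo_k, hi_k = opts.rate_bounds
    kb0 = min(max(kb0, lo_k * 10), hi_k / 10)
    kh0 = min(max(kh0, lo_k), hi_k / 10)

    fixed_rho = opts.fix_rho
    fixed_kb = opts.fix_k_bind

    def unpack(x):
        x = list(x)
        kb = fixed_kb if fixed_kb is not None else x.pop(0)
        kh, a = x.pop(0), x.pop(0)
        rho = fixed_rho if fixed_rho is not None else x.pop(0)
        return kb, kh, a, rho

    def model(x):
        kb, kh, a, rho = unpack(x)
        if baseline_mode == "initial":
            f_free = y_first
        else:
            f_free = y_last - rho * a
        p_free = max(f_free, 0.0)
        p = KineticParams(k_bind=kb, k_hydr=kh, A=max(a, 0.0), rho=rho, F_free=p_free)
        out = binding_hydrolysis_signal(p, t)
        # retain the (possibly negative) analytic baseline in the residual
        return out + (f_free - p_free)

    def residual(x):
        return model(x) - y

    se_names, lo, hi = [], [], []
    if fixed_kb is None:
        se_names.append("k_bind"); lo.append(lo_k); hi.append(hi_k)
    se_names.append("k_hydr"); lo.append(lo_k); hi.append(hi_k)
    se_names.append("A"); lo.append(0.0); hi.append(np.inf)
    if fixed_rho is None:
        se_names.append("rho"); lo.append(opts.rho_bounds[0]); hi.append(opts.rho_bounds[1])

    def start(f):
        x0 = []
        if fixed_kb is None:
            x0.append(kb0 * f)
        x0.extend([kh0 * f, amp0])
        if fixed_rho is None:
            x0.append(rho0)
        return x0

    x0s = [start(f) for f in opts.start_factors()]
    khydr_index = se_names.index("k_hydr")

    res = _multistart(residual, x0s, (lo, hi), khydr_index=khydr_index, max_nfev=opts.max_nfev)
    flags: list[str] = []
    if res is None:
        return FitResult(
            params=KineticParams(k_bind=kb0, k_hydr=kh0, A=amp0, rho=rho0, F_free=max(y_first, 0.0)),
            param_errors={},
            rss=float("inf"),
            n_points=len(trace),
            converged=False,
            baseline_mode=baseline_mode,
            message="all starts failed",
        )
    kb, kh, a, rho = unpack(res.x)
    f_free = y_first if baseline_mode == "initial" else y_last - rho * a
    if f_free < 0:
        flags.append("baseline clipped to zero")
        f_free = 0.0
    if span < 2.0 / max(kb, 1e-300):
        flags.append("binding phase unresolved")
    se = _standard_errors(res, len(trace))
    params = KineticParams(k_bind=kb, k_hydr=kh, A=max(a, 0.0), rho=rho, F_free=f_free)
    return FitResult(
        params=params,
        param_errors=dict(zip(se_names, map(float, se))),
        rss=float(np.sum(res.fun**2)),
        n_points=len(trace),
        converged=bool(res.success),
        baseline_mode=baseline_mode,
        derived={"F_free": float(f_free)},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# displacement: k_diss
# ---------------------------------------------------------------------------

def fit_k_diss(trace: KineticTrace, opts: FitOptions | None = None) -> FitResult:
    """Fit the post-injection exponential decay for {k_diss, F_pre, F_res}.

    The derived ``retained_fraction`` is ``(F_res - F_free)/(F_pre - F_free)``
    when ``opts.F_free`` is supplied and ``F_res / F_pre`` otherwise.  When
    ``opts.d_inj < 1`` the post-injection signal is divided by the dilution
    factor before fitting.
    """
    opts = opts or FitOptions()
    _require_kind(trace, "displacement")
    i = int(trace.injection_index)  # presence enforced by KineticTrace
    t = trace.times[i:]
    y = trace.signal[i:].astype(float)
    if t.size < 8:
        raise InvalidInputError(f"need >= 8 post-injection points, got {t.size}")
    if opts.d_inj != 1.0:
        y = y / opts.d_inj
    t_ref = float(t[0])

    lo_k, hi_k = opts.rate_bounds

    def finish(k, f_pre, f_res, res=None):
        se = {}
        rss = 0.0
        converged = True
        if res is not None:
            se = dict(zip(["k_diss", "F_pre", "F_res"], map(float, _standard_errors(res, t.size))))
            rss = float(np.sum(res.fun**2))
            converged = bool(res.success)
        if opts.F_free is not None and f_pre != opts.F_free:
            retained = (f_res - opts.F_free) / (f_pre - opts.F_free)
        else:
            retained = f_res / f_pre if f_pre != 0 else float("nan")
        params = KineticParams(k_diss=k, F_free=opts.F_free or 0.0, A=max(f_pre - (opts.F_free or 0.0), 0.0))
        return FitResult(
            params=params,
            param_errors=se,
            rss=rss,
            n_points=int(t.size),
            converged=converged,
            derived={
                "F_pre": float(f_pre),
                "F_res": float(f_res),
                "retained_fraction": float(retained),
                "half_time_s": math.log(2.0) / k if k > 0 else float("inf"),
            },
        )

    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.mean(y)))):
        # exactly constant after injection: no displacement observed
        level = float(np.mean(y))
        return finish(lo_k, level, level)

    f_pre0 = float(y[0])
    f_res0 = float(np.median(y[-5:]))
    t_half = _half_crossing_time(t, y, f_pre0, f_res0)
    k0 = math.log(2.0) / max(t_half, 1e-9)
    k0 = min(max(k0, lo_k * 10), hi_k / 10)

    def residual(x):
        k, f_pre, f_res = x
        return (f_res + (f_pre - f_res) * np.exp(-k * (t - t_ref))) - y

    lo = [lo_k, 0.0, 0.0]
    hi = [hi_k, np.inf, np.inf]
    x0s = [[k0 * f, f_pre0, f_res0] for f in opts.start_factors()]
    res = _multistart(residual, x0s, (lo, hi), max_nfev=opts.max_nfev)
    if res is None:
        out = finish(k0, f_pre0, f_res0)
        out.converged = False
        out.message = "all starts failed"
        return out
    k, f_pre, f_res = res.x
    return finish(float(k), float(f_pre), float(f_res), res)


# ---------------------------------------------------------------------------
# derived comparisons
# ---------------------------------------------------------------------------

def compare_rates(
    diss: FitResult, bind: FitResult, alpha: float = 0.05
) -> RateComparison:
    """Two-sided Welch-style z comparison of k_diss against k_bind.

    ``exceeds`` is True when the ratio is > 1 and the difference is
    significant at ``alpha``.
    """
    if not (diss.converged and bind.converged):
        raise InvalidInputError("both fits must have converged")
    kd, kb = diss.rate("k_diss"), bind.rate("k_bind")
    se_d, se_b = diss.rate_error("k_diss"), bind.rate_error("k_bind")
    if not (se_d > 0 or se_b > 0) or not (math.isfinite(se_d) and math.isfinite(se_b)):
        raise ComparisonUndefinedError("zero/missing standard errors")
    z = (kd - kb) / math.sqrt(se_d**2 + se_b**2)
    p = 2.0 * float(norm.sf(abs(z)))
    ratio = kd / kb if kb > 0 else float("inf")
    return RateComparison(ratio=ratio, z=z, p_value=p, exceeds=(ratio > 1.0 and p < alpha), alpha=alpha)


def fold_change(mutant: FitResult, wildtype: FitResult, which: str) -> FoldChange:
    """Mutant/wild-type ratio of the chosen rate with propagated relative error."""
    if not (mutant.converged and wildtype.converged):
        raise InvalidInputError("both fits must have converged")
    m, w = mutant.rate(which), wildtype.rate(which)
    if w <= 0 or w <= RATE_BOUNDS[0] * (1.0 + 1e-9):
        raise DivisionUnstableError("wild-type rate at/below the lower bound")
    rel_m = mutant.rate_error(which) / m if m > 0 else 0.0
    rel_w = wildtype.rate_error(which) / w
    rel_m = rel_m if math.isfinite(rel_m) else 0.0
    rel_w = rel_w if math.isfinite(rel_w) else 0.0
    return FoldChange(ratio=m / w, rel_error=math.sqrt(rel_m**2 + rel_w**2))


# ---------------------------------------------------------------------------
# batch interface
# ---------------------------------------------------------------------------

def batch_fit(
    traces: dict[str, KineticTrace],
    baseline_mode: str = "endpoint",
    opts: FitOptions | None = None,
):
    """Fit every trace with the fitter matching its assay kind.

    Returns a tidy :class:`pandas.DataFrame`, one row per well, with rates,
    standard errors, rss, baseline mode and flags.
    """
    import pandas as pd

    rows = []
    for well_id in sorted(traces):
        trace = traces[well_id]
        row: dict = {"well": well_id, "assay_kind": trace.assay_kind}
        try:
            if trace.assay_kind == "association":
                fr = fit_k_bind(trace, opts)
            elif trace.assay_kind == "binding_hydrolysis":
                fr = fit_k_hydr(trace, baseline_mode, opts)
            else:
                fr = fit_k_diss(trace, opts)
        except (DegenerateFitError, InvalidInputError) as exc:
            row.update({"converged": False, "flags": type(exc).__name__, "rss": float("nan")})
            rows.append(row)
            continue
        row.update(
            {
                "k_bind": fr.params.k_bind,
                "k_hydr": fr.params.k_hydr,
                "k_diss": fr.params.k_diss,
                "se_k_bind": fr.param_errors.get("k_bind", float("nan")),
                "se_k_hydr": fr.param_errors.get("k_hydr", float("nan")),
                "se_k_diss": fr.param_errors.get("k_diss", float("nan")),
                "rss": fr.rss,
                "n_points": fr.n_points,
                "baseline_mode": fr.baseline_mode,
                "converged": fr.converged,
                "flags": ";".join(fr.flags),
            }
        )
        for key, val in fr.derived.items():
            row[f"derived_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
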