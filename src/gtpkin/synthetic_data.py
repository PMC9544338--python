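"""Seeded generators emulating plate-reader and dual-channel BRET inputs.

Everything the analysis pipeline consumes can be produced here: single
traces for the three assay kinds, whole screening plates with vehicle
controls and spiked wells (spikes are expressed in units of the control
standard deviation of the scored metric), and BRET ratio series with an
agonist-induced exponential decay and optional antagonist recovery.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .hts_screen import METRICS, ScreenPlate, Well, compute_well_metrics
from .bret_analysis import BretSeries
from .kinetic_models import (
    KineticParams,
    KineticTrace,
    association_signal,
    binding_hydrolysis_signal,
    displacement_signal,
)

__all__ = [
    "Spike",
    "PlateLayout",
    "BretProfile",
    "SyntheticConfig",
    "generate_trace",
    "generate_plate",
    "generate_bret",
]

_ROWS = "ABCDEFGHIJKLMNOP"


def default_well_ids(n_rows: int = 16, n_cols: int = 24) -> list[str]:
    return [f"{_ROWS[r]}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)]


@dataclass(frozen=True)
class Spike:
    """A programmed effect, in control-SD units, on one metric of one well."""

    metric: str
    effect_sd: float
    well_id: str | None = None  # auto-assigned to a compound well when None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise InvalidInputError(f"unknown spike metric {self.metric!r}")


@dataclass(frozen=True)
class PlateLayout:
    n_rows: int = 16
    n_cols: int = 24
    n_dmso: int = 32
    n_compound: int = 344
    spikes: tuple[Spike, ...] = ()

    def __post_init__(self) -> None:
        if self.n_dmso + self.n_compound > self.n_rows * self.n_cols:
            raise InvalidInputError("layout counts exceed the plate size")


@dataclass(frozen=True)
class BretProfile:
    basal: float = 0.5
    decrease: float = 0.3  # programmed fractional drop of the ratio
    tau_s: float = 30.0
    n_readings: int = 120
    interval_s: float = 1.0
    injection_index: int = 20
    second_injection_index: int | None = None
    recovery_tau_s: float = 30.0
    donor_counts: float = 10000.0

    def __post_init__(self) -> None:
        if self.injection_index < 10:
            raise InvalidInputError("injection_index must be >= 10")
        if not (0.0 <= self.decrease < 1.0):
            raise InvalidInputError("decrease must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    noise_sigma_frac: float = 0.02
    sample_interval_s: float = 10.0
    duration_s: float = 600.0
    true_params: KineticParams = field(
        default_factory=lambda: KineticParams(k_bind=0.02, k_hydr=0.0, F_free=100.0, A=100.0, rho=0.2)
    )
    plate_layout: PlateLayout = field(default_factory=PlateLayout)
    bret_profile: BretProfile = field(default_factory=BretProfile)

    def __post_init__(self) -> None:
        if self.noise_sigma_frac < 0:
            raise InvalidInputError("noise_sigma_frac must be >= 0")
        if self.sample_interval_s <= 0 or self.duration_s <= 0:
            raise InvalidInputError("sampling interval and duration must be > 0")


def _time_grid(config: SyntheticConfig) -> np.ndarray:
    n = int(round(config.duration_s / config.sample_interval_s)) + 1
    return np.arange(n) * config.sample_interval_s


_SIGNALS = {
    "association": association_signal,
    "binding_hydrolysis": binding_hydrolysis_signal,
    "displacement": displacement_signal,
}


def generate_trace(
    config: SyntheticConfig,
    assay_kind: str,
    rng: np.random.Generator | None = None,
    well_id: str | None = None,
    params: KineticParams | None = None,
) -> KineticTrace:
    """Forward-model signal plus i.i.d. Gaussian read noise of SD
    ``noise_sigma_frac * A``.  Deterministic under a fixed seed."""
    if assay_kind not in _SIGNALS:
        raise InvalidInputError(f"unknown assay_kind {assay_kind!r}")
    params = params or config.true_params
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    times = _time_grid(config)
    clean = _SIGNALS[assay_kind](params, times)
    signal = clean + rng.normal(0.0, config.noise_sigma_frac * params.A, size=times.size)
    injection_index = None
    if assay_kind == "displacement":
        injection_index = int(np.argmax(times >= params.t_inj))
    return KineticTrace(
        times,
        signal,
        assay_kind,
        injection_index=injection_index,
        well_id=well_id,
        meta={"true_k_bind": params.k_bind, "true_k_hydr": params.k_hydr, "true_k_diss": params.k_diss},
    )


def _calibrate_metric_stats(
    config: SyntheticConfig,
    rng: np.random.Generator,
    window_s: float,
    n_cal: int = 48,
) -> dict[str, tuple[float, float]]:
    """Empirical mean/SD of each metric over simulated control wells.

    Used to translate spike sizes from control-SD units into forward-model
    parameter perturbations.
    """
    values: dict[str, list[float]] = {m: [] for m in METRICS}
    for _ in range(n_cal):
        trace = generate_trace(config, "binding_hydrolysis", rng=rng)
        wm = compute_well_metrics(trace, window_s)
        for m in METRICS:
            v = wm.get(m)
            if v is not None:
                values[m].append(v)
    out = {}
    for m, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 8:
            raise InvalidInputError("calibration failed: too few usable control fits")
        out[m] = (float(arr.mean()), float(arr.std(ddof=1)))
    return out


def generate_plate(
    config: SyntheticConfig,
    window_s: float = 600.0,
    plate_id: str = "synthetic-plate",
) -> ScreenPlate:
    """Generate a screening plate with DMSO controls, neutral compound wells
    and spiked wells.

    Vehicle and neutral compound wells share ``config.true_params``.  A
    spike of ``s`` control SDs on ``k_bind`` sets the well's true binding
    rate to ``mean + s * sd`` of the calibrated control distribution; a
    spike on ``max_uptake`` rescales the amplitude ``A`` by the targeted
    uptake ratio.  Ground-truth labels are stored in each trace's ``meta``
    and in ``plate.meta["ground_truth"]``.
    """
    layout = config.plate_layout
    rng = np.random.default_rng(config.seed)
    cal_rng = np.random.default_rng([config.seed, 0xCA1])

    well_ids = default_well_ids(layout.n_rows, layout.n_cols)
    n_wells = len(well_ids)
    # spread control wells evenly over the plate, compounds fill the rest
    dmso_pos = set(
        int(round(i * n_wells / layout.n_dmso)) for i in range(layout.n_dmso)
    )
    roles: dict[str, str] = {}
    compound_wells: list[str] = []
    for idx, wid in enumerate(well_ids):
        if idx in dmso_pos:
            roles[wid] = "dmso"
        elif len(compound_wells) < layout.n_compound:
            roles[wid] = "compound"
            compound_wells.append(wid)
        else:
            roles[wid] = "empty"

    spikes: dict[str, Spike] = {}
    auto = iter(compound_wells)
    for spike in layout.spikes:
        wid = spike.well_id
        if wid is None:
            wid = next(w for w in auto if w not in spikes)
        elif wid not in roles or roles[wid] != "compound":
            raise InvalidInputError(f"spike references unknown compound well {wid!r}")
        spikes[wid] = spike

    cal = None
    if spikes:
        cal = _calibrate_metric_stats(config, cal_rng, window_s)

    base = config.true_params
    wells: dict[str, Well] = {}
    ground_truth: dict[str, dict] = {}
    compound_counter = 0
    for wid in well_ids:
        role = roles[wid]
        if role == "empty":
            wells[wid] = Well(role="empty")
            continue
        params = base
        label: dict = {"role": role, "spike_metric": None, "spike_sd": 0.0}
        compound_id = None
        if role == "compound":
            compound_counter += 1
            compound_id = f"CMP{compound_counter:04d}"
            if wid in spikes:
                spike = spikes[wid]
                mean, sd = cal[spike.metric]
                if spike.metric == "k_bind":
                    target = max(mean + spike.effect_sd * sd, 1e-6)
                    params = base.with_(k_bind=target)
                else:
                    target = max(mean + spike.effect_sd * sd, 0.0)
                    scale = target / mean if mean > 0 else 1.0
                    params = base.with_(A=base.A * scale)
                label.update({"spike_metric": spike.metric, "spike_sd": spike.effect_sd})
        trace = generate_trace(config, "binding_hydrolysis", rng=rng, well_id=wid, params=params)
        trace.meta.update(label)
        wells[wid] = Well(role=role, compound_id=compound_id, concentration_uM=12.5 if role == "compound" else None, trace=trace)
        ground_truth[wid] = label

    return ScreenPlate(plate_id=plate_id, wells=wells, meta={"ground_truth": ground_truth, "seed": config.seed})


def generate_bret(config: SyntheticConfig, rng: np.random.Generator | None = None) -> BretSeries:
    """Basal ratio, exponential agonist-induced decay, optional antagonist
    recovery; multiplicative Gaussian noise on each channel."""
    prof = config.bret_profile
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = prof.n_readings
    times = np.arange(n) * prof.interval_s
    t_inj = times[prof.injection_index]
    target = np.full(n, prof.basal, dtype=float)
    post = np.arange(n) >= prof.injection_index
    dt = times[post] - t_inj
    target[post] = prof.basal * (1.0 - prof.decrease * (1.0 - np.exp(-dt / prof.tau_s)))
    if prof.second_injection_index is not None:
        j = prof.second_injection_index
        level_at_second = target[j - 1] if j > 0 else prof.basal
        post2 = np.arange(n) >= j
        dt2 = times[post2] - times[j]
        target[post2] = prof.basal + (level_at_second - prof.basal) * np.exp(-dt2 / prof.recovery_tau_s)
    sigma = config.noise_sigma_frac
    donor = prof.donor_counts * (1.0 + rng.normal(0.0, sigma, n))
    acceptor = prof.donor_counts * target * (1.0 + rng.normal(0.0, sigma, n))
    return BretSeries(
        times=times,
        donor=donor,
        acceptor=acceptor,
        injection_index=prof.injection_index,
        second_injection_index=prof.second_injection_index,
        meta={"true_basal": prof.basal, "true_decrease": prof.decrease},
    )
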