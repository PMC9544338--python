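"""Quantification of dual-channel resonance-energy-transfer time series.

The acceptor/donor ratio reports heterotrimer association.  Basal level is
the mean ratio over the 10 readings immediately preceding the agonist
injection; the plateau ratio is the mean of the final 10 stimulated
readings divided by the basal mean.  Windows are defined on reading
indices, not wall-clock times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptySeriesError, InvalidInputError

__all__ = [
    "BretSeries",
    "BretSummary",
    "compute_ratio",
    "basal_bret",
    "plateau_ratio",
    "DEFAULT_WINDOW",
    "DEFAULT_RECOVERY_TOL",
]

DEFAULT_WINDOW = 10
DEFAULT_RECOVERY_TOL = 0.05


@dataclass
class BretSeries:
    """Donor/acceptor luminescence series with injection bookkeeping."""

    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    injection_index: int
    second_injection_index: int | None = None
    ratio: np.ndarray | None = None
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.times.shape == self.donor.shape == self.acceptor.shape):
            raise InvalidInputError("times, donor and acceptor must have equal length")
        if self.times.ndim != 1 or self.times.size == 0:
            raise InvalidInputError("series must be non-empty and 1-D")
        self.injection_index = int(self.injection_index)
        if self.injection_index < DEFAULT_WINDOW:
            raise InvalidInputError(
                f"injection_index must be >= {DEFAULT_WINDOW} (pre-injection readings needed)"
            )
        if self.second_injection_index is not None:
            self.second_injection_index = int(self.second_injection_index)
            if not (self.injection_index < self.second_injection_index <= self.times.size):
                raise InvalidInputError("second_injection_index must follow injection_index")
        if self.ratio is not None:
            self.ratio = np.asarray(self.ratio, dtype=float)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BretSummary:
    basal: float
    plateau_ratio: float
    recovered: bool | None = None

    def __post_init__(self) -> None:
        if not self.plateau_ratio > 0:
            raise InvalidInputError("plateau_ratio must be > 0")


def compute_ratio(series: BretSeries) -> BretSeries:
    """Return a copy with ``ratio = acceptor / donor`` populated.

    Readings with non-positive donor are dropped (the drop count is kept
    in ``n_dropped`` and injection indices are shifted accordingly).
    """
    keep = series.donor > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptySeriesError("all readings dropped (non-positive donor)")
    inj = series.injection_index - int((~keep)[: series.injection_index].sum())
    second = series.second_injection_index
    if second is not None:
        second = second - int((~keep)[:second].sum())
    times = series.times[keep]
    donor = series.donor[keep]
    acceptor = series.acceptor[keep]
    ratio = acceptor / donor
    if not np.all(np.isfinite(ratio)):
        raise InvalidInputError("non-finite ratio values")
    return replace(
        series,
        times=times,
        donor=donor,
        acceptor=acceptor,
        ratio=ratio,
        injection_index=inj,
        second_injection_index=second,
        n_dropped=series.n_dropped + n_dropped,
    )


def _ratio_of(series: BretSeries) -> np.ndarray:
    if series.ratio is None:
        series = compute_ratio(series)
    return series.ratio  # type: ignore[return-value]


def basal_bret(series: BretSeries, window: int = DEFAULT_WINDOW) -> float:
    """Mean ratio over the ``window`` readings immediately before injection."""
    ratio = _ratio_of(series)
    i = series.injection_index
    if i < window:
        raise InvalidInputError(f"need >= {window} pre-injection readings")
    return float(np.mean(ratio[i - window : i]))


def plateau_ratio(
    series: BretSeries,
    window: int = DEFAULT_WINDOW,
    recovery_tol: float = DEFAULT_RECOVERY_TOL,
) -> BretSummary:
    """Plateau-to-basal summary of the stimulated segment.

    ``plateau_ratio`` is the mean of the last ``window`` stimulated
    readings (before any second injection) over the basal mean; values
    below 1 indicate heterotrimer dissociation.  When a second
    (antagonist) injection is present, ``recovered`` flags whether the
    mean of the final ``window`` readings of the whole series returned to
    basal within ``recovery_tol`` (relative).
    """
    ratio = _ratio_of(series)
    basal = basal_bret(series, window)
    stim_end = series.second_injection_index if series.second_injection_index is not None else len(ratio)
    if stim_end - window < series.injection_index:
        raise InvalidInputError("stimulation window overlaps the pre-injection window")
    plateau = float(np.mean(ratio[stim_end - window : stim_end]))
    recovered: bool | None = None
    if series.second_injection_index is not None:
        if len(ratio) - series.second_injection_index < window:
            raise InvalidInputError(f"need >= {window} post-antagonist readings")
        final = float(np.mean(ratio[-window:]))
        recovered = bool(abs(final / basal - 1.0) < recovery_tol)
    return BretSummary(basal=basal, plateau_ratio=plateau / basal, recovered=recovered)
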