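"""RR-interval processing and the Baevsky stress index (SI).

The stress index is a histogram statistic of the inter-beat (RR) interval
series::

    SI = AMo / (2 * Mo * MxDMn)

where, after rounding the RR intervals to a 50 ms grid for noise reduction,
``Mo`` is the mode of the binned intervals (seconds), ``AMo`` the relative
frequency of that mode (percent of all beats), and ``MxDMn`` the range
between the longest and shortest binned interval (seconds).  With these
units the index is dimensionless and takes the familiar magnitudes of tens
(relaxed, high variability) to many hundreds (sympathetic stress response,
rigid heart rhythm).

Conventions fixed here because the classical definition leaves them open:

* rounding is to the *nearest* multiple of the bin width, midpoints away
  from zero;
* ``MxDMn`` is computed on the binned series, consistent with the rounding
  step being applied to the data as a whole;
* multimodal ties resolve to the smallest RR value, which keeps the
  statistic deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateVariabilityError, EmptySeriesError, InsufficientDataError

__all__ = [
    "RRSeries",
    "BSIResult",
    "bin_rr",
    "mode_stats",
    "mxdmn",
    "baevsky_si",
    "per_task_bsi",
]

DEFAULT_BIN_MS = 50
MIN_BEATS_PER_WINDOW = 10


@dataclass(frozen=True)
class RRSeries:
    """Timestamped inter-beat intervals.

    Parameters
    ----------
    t
        UNIX epoch seconds of each beat, strictly increasing.
    rr_ms
        Inter-beat interval in milliseconds preceding each beat; all > 0.
    """

    t: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "rr_ms", rr)
        if t.ndim != 1 or rr.ndim != 1 or t.shape != rr.shape:
            raise ValueError("t and rr_ms must be 1-D arrays of equal length")
        if t.size == 0:
            raise EmptySeriesError("RR series contains no beats")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(rr)):
            raise ValueError("RR series contains non-finite values")
        if np.any(rr <= 0):
            raise ValueError("all RR intervals must be positive")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    def window(self, t_start: float, t_end: float) -> "RRSeries":
        """Beats whose timestamps fall in the half-open window [t_start, t_end)."""
        mask = (self.t >= t_start) & (self.t < t_end)
        if not mask.any():
            raise EmptySeriesError(
                f"no beats in window [{t_start}, {t_end})"
            )
        return RRSeries(self.t[mask], self.rr_ms[mask])


@dataclass(frozen=True)
class BSIResult:
    """Baevsky stress index together with its three ingredients."""

    mo_s: float        # mode of binned RR, seconds
    amo_pct: float     # relative frequency of the mode, percent
    mxdmn_s: float     # max - min of binned RR, seconds
    si: float          # stress index, dimensionless

    def to_dict(self) -> dict:
        return {
            "mo_s": self.mo_s,
            "amo_pct": self.amo_pct,
            "mxdmn_s": self.mxdmn_s,
            "si": self.si,
        }


def bin_rr(rr: RRSeries, bin_width_ms: int = DEFAULT_BIN_MS) -> RRSeries:
    """Round each RR interval to the nearest multiple of ``bin_width_ms``.

    Midpoints round away from zero (825 ms -> 850 ms on the 50 ms grid);
    timestamps are unchanged.  Idempotent.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    # floor(x/w + 0.5) rounds positive values half-up == away from zero
    binned = np.floor(rr.rr_ms / bin_width_ms + 0.5) * bin_width_ms
    return RRSeries(rr.t, binned)


def mode_stats(binned: RRSeries) -> tuple[float, float]:
    """Mode of the binned series in seconds and its amplitude in percent.

    Ties between equally frequent bins resolve to the smallest RR value.
    """
    values, counts = np.unique(binned.rr_ms, return_counts=True)
    i = int(np.argmax(counts))  # first maximum == smallest value (sorted)
    mo_s = float(values[i]) / 1000.0
    amo_pct = 100.0 * float(counts[i]) / binned.rr_ms.size
    return mo_s, amo_pct


def mxdmn(binned: RRSeries) -> float:
    """Range (max - min) of the binned RR intervals, in seconds."""
    return float(binned.rr_ms.max() - binned.rr_ms.min()) / 1000.0


def baevsky_si(rr: RRSeries, bin_width_ms: int = DEFAULT_BIN_MS) -> BSIResult:
    """Compute the stress index SI = AMo / (2 * Mo * MxDMn) on binned data.

    Raises
    ------
    DegenerateVariabilityError
        If the binned series is constant (MxDMn = 0), where the index is
        undefined (division by zero; clinically a flat heart rhythm).
    """
    binned = bin_rr(rr, bin_width_ms)
    mo_s, amo_pct = mode_stats(binned)
    mx_s = mxdmn(binned)
    if mx_s == 0.0:
        raise DegenerateVariabilityError(
            "binned RR series is constant (MxDMn = 0); stress index undefined"
        )
    si = amo_pct / (2.0 * mo_s * mx_s)
    return BSIResult(mo_s=mo_s, amo_pct=amo_pct, mxdmn_s=mx_s, si=si)


def per_task_bsi(
    rr: RRSeries,
    task_window: tuple[float, float],
    bin_width_ms: int = DEFAULT_BIN_MS,
    min_beats: int = MIN_BEATS_PER_WINDOW,
) -> BSIResult:
    """Stress index over the beats of one task window [t_start, t_end).

    Mode/range statistics are meaningless on a handful of beats, so fewer
    than ``min_beats`` beats inside the window raise
    :class:`InsufficientDataError`.
    """
    t_start, t_end = task_window
    mask = (rr.t >= t_start) & (rr.t < t_end)
    n = int(mask.sum())
    if n < min_beats:
        raise InsufficientDataError(
            f"only {n} beats in window [{t_start}, {t_end}); need >= {min_beats}"
        )
    return baevsky_si(RRSeries(rr.t[mask], rr.rr_ms[mask]), bin_width_ms)
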