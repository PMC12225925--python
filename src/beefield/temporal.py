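"""Time-resolved visitation analysis: binning and percent-of-control traces.

Landings from all trials of a treatment are pooled and placed into
10-minute bins — half-open ``[a, a+10)`` except the last, which is closed at
the trial end so a landing logged at exactly minute 120 still counts. The
per-bin percent-of-control (100 x treatment / control) summarises recovery
dynamics; bins where the control count is zero have no defined percentage
and are excluded from summaries rather than treated as 0 or infinity.

Bin ranges are 1-based and inclusive throughout (bins 1..12 for a 120-min
trial), matching how such windows are usually described ("bins 3-12" for
everything after the first twenty minutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ROLE_CONTROL, ROLE_TREATMENT, VisitEvent

__all__ = ["BinnedSeries", "PercentTrace", "bin_events", "percent_trace", "rate_of_change"]


@dataclass
class BinnedSeries:
    """Pooled landing counts per time bin for treatment and control."""

    bin_edges: np.ndarray  # minutes, length n_bins + 1
    treatment_counts: np.ndarray
    control_counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_width_min(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(
                self.control_counts > 0,
                100.0 * self.treatment_counts / self.control_counts,
                np.nan,
            )
        return pd.DataFrame(
            {
                "bin_start_min": self.bin_edges[:-1],
                "bin_end_min": self.bin_edges[1:],
                "treatment": self.treatment_counts,
                "control": self.control_counts,
                "percent": pct,
            }
        )


@dataclass
class PercentTrace:
    """Per-bin percent-of-control with summaries over the defined bins.

    ``percent_of_control`` is NaN where the control bin is empty; ``defined``
    marks usable bins. ``bin_range`` records the 1-based inclusive bin window
    the summaries cover.
    """

    percent_of_control: np.ndarray
    defined: np.ndarray
    mean_percent: float
    sd_percent: float
    bin_range: tuple[int, int]
    bin_width_min: float


def bin_events(
    events: list[VisitEvent],
    duration_min: float = 120.0,
    bin_width_min: float = 10.0,
) -> BinnedSeries:
    """Pool events over trials into per-role time-bin counts.

    Raises if the duration is not a whole number of bins or any event falls
    outside [0, duration]; the error names the offending record.
    """
    n_bins = duration_min / bin_width_min
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"duration {duration_min} min is not divisible into "
            f"{bin_width_min}-min bins"
        )
    edges = np.linspace(0.0, duration_min, int(round(n_bins)) + 1)
    times = {ROLE_TREATMENT: [], ROLE_CONTROL: []}
    for e in events:
        if not 0 <= e.time_min <= duration_min:
            raise ValueError(
                f"event outside trial duration: trial {e.trial_id}, "
                f"{e.flower_role}, t={e.time_min} min"
            )
        if e.flower_role not in times:
            raise ValueError(f"unknown flower_role {e.flower_role!r}")
        times[e.flower_role].append(e.time_min)
    # np.histogram uses half-open bins with the final bin closed, exactly
    # the [0,10) ... [110,120] convention required here
    t_counts, _ = np.histogram(times[ROLE_TREATMENT], bins=edges)
    c_counts, _ = np.histogram(times[ROLE_CONTROL], bins=edges)
    return BinnedSeries(edges, t_counts.astype(int), c_counts.astype(int))


def _resolve_range(n_bins: int, bin_range: tuple[int, int] | None) -> tuple[int, int]:
    lo, hi = bin_range if bin_range is not None else (1, n_bins)
    if not (1 <= lo <= hi <= n_bins):
        raise ValueError(f"bin_range {bin_range} invalid for {n_bins} bins (1-based inclusive)")
    return lo, hi


def percent_trace(
    binned: BinnedSeries, bin_range: tuple[int, int] | None = None
) -> PercentTrace:
    """Percent-of-control per bin, summarised over a 1-based bin window.

    The full per-bin trace is always returned; ``mean_percent``/``sd_percent``
    (sample SD) cover only the defined bins inside ``bin_range`` (default:
    the whole trial).
    """
    lo, hi = _resolve_range(binned.n_bins, bin_range)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            binned.control_counts > 0,
            100.0 * binned.treatment_counts / binned.control_counts,
            np.nan,
        )
    defined = ~np.isnan(pct)
    window = pct[lo - 1 : hi]
    window = window[~np.isnan(window)]
    if window.size == 0:
        raise ValueError("every bin in the requested range has zero control count")
    sd = float(window.std(ddof=1)) if window.size > 1 else 0.0
    return PercentTrace(pct, defined, float(window.mean()), sd, (lo, hi), binned.bin_width_min)


def rate_of_change(
    trace: PercentTrace, bin_range: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Mean and SD of the per-minute rate of change of percent-of-control.

    Rates are successive differences between consecutive defined bins,
    divided by the elapsed minutes between their bin starts (one bin width
    when no bin is skipped). When every bin in the range is defined, the
    mean telescopes to (last - first) / (width * (k - 1)).
    """
    n_bins = trace.percent_of_control.size
    lo, hi = _resolve_range(n_bins, bin_range if bin_range is not None else trace.bin_range)
    idx = np.flatnonzero(trace.defined[lo - 1 : hi]) + (lo - 1)
    if idx.size < 2:
        raise ValueError("need at least 2 defined bins to compute a rate of change")
    pct = trace.percent_of_control[idx]
    dt = np.diff(idx) * trace.bin_width_min
    rates = np.diff(pct) / dt
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), sd
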