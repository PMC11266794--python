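"""Lethargus and feeding metrics from pharyngeal-pumping rasters.

Pharyngeal pumping (rhythmic grinder movement) is the feeding proxy in
*C. elegans*; it stops during lethargus, the quiescent period before each
molt.  Scoring a larva's pumping for 10 s at fixed intervals around the
L3-to-L4 transition yields a binary raster per individual; this module
calls lethargus episodes from such rasters (entry, duration, fragmentation,
censoring), summarises them per group, computes pooled feeding fractions
and stage-transition fractions, normalizes pumping-rate counts, and runs
basic two-group comparisons.

All episode durations are interval-censored: quiescence is only observed
at grid times, so a duration is the count of quiescent observations times
the sampling interval, exact to within one interval of the (unobserved)
continuous episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PumpingRaster",
    "LethargusCall",
    "call_lethargus",
    "cohort_lethargus_stats",
    "feeding_fraction",
    "stage_transition_fractions",
    "pumping_rate",
    "compare_groups",
]


@dataclass
class PumpingRaster:
    """One individual's binary pumping observations on a fixed time grid.

    times: hours, fixed interval.  pumping: 1 = pumping observed, 0 = no
    pumping (presumed lethargus).  l4: optional flags, 1 from the first
    observation at which pumping plus an invaginated vulva identify the L4.
    """

    individual_id: str
    times: np.ndarray
    pumping: np.ndarray
    l4: np.ndarray | None = None
    group: str = "control"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pumping = np.asarray(self.pumping, dtype=np.int64)
        if self.times.shape != self.pumping.shape or self.times.ndim != 1:
            raise ValueError("times and pumping must be 1-D and equal length")
        if not np.isin(self.pumping, (0, 1)).all():
            raise ValueError("pumping values must be 0 or 1")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            # tolerance covers rounding of times written to 6 decimals
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-4):
                raise ValueError("fixed interval required")
        if self.l4 is not None:
            self.l4 = np.asarray(self.l4, dtype=np.int64)
            if self.l4.shape != self.times.shape:
                raise ValueError("l4 flags must match the time grid")

    @property
    def interval_min(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need >= 2 observations to define an interval")
        return float(np.diff(self.times)[0] * 60.0)


@dataclass
class LethargusCall:
    """A called lethargus episode for one individual.

    duration_min sums quiescent observations across all bouts before L4;
    longest_bout_min is the per-longest-bout variant (the two differ only
    for fragmented animals).  censored means no quiescent observation, or
    no L4 reached within the observation window.
    """

    individual_id: str
    group: str
    entry_h: float | None
    exit_h: float | None
    l4_onset_h: float | None
    duration_min: float
    longest_bout_min: float
    bout_durations_min: tuple[float, ...]
    n_bouts: int
    fragmented: bool
    censored: bool


def call_lethargus(raster: PumpingRaster) -> LethargusCall:
    """Call the lethargus episode from one raster row.

    Entry is the first non-pumping observation; bouts are maximal runs of
    non-pumping observations before the L4 onset (or the window end);
    duration is the total count of non-pumping observations times the
    sampling interval; the call is fragmented when pumping resumed between
    quiescent bouts before L4.  Without L4 annotation, a final pumping
    stretch reaching the window end after quiescence is treated as the
    presumed L4 resumption; otherwise the call is censored.
    """
    t, p = raster.times, raster.pumping
    interval_min = raster.interval_min
    n = len(t)

    if raster.l4 is not None and raster.l4.any():
        l4_idx = int(np.flatnonzero(raster.l4)[0])
    else:
        l4_idx = None

    limit = l4_idx if l4_idx is not None else n
    zeros = np.flatnonzero(p[:limit] == 0)

    if raster.l4 is None and len(zeros) and zeros[-1] + 1 < n and p[zeros[-1] + 1 :].all():
        l4_idx = int(zeros[-1] + 1)  # presumed resumption into L4

    if len(zeros) == 0:
        return LethargusCall(
            individual_id=raster.individual_id, group=raster.group,
            entry_h=None, exit_h=None,
            l4_onset_h=float(t[l4_idx]) if l4_idx is not None else None,
            duration_min=0.0, longest_bout_min=0.0, bout_durations_min=(),
            n_bouts=0, fragmented=False, censored=True,
        )

    # maximal runs of consecutive quiescent indices
    breaks = np.flatnonzero(np.diff(zeros) > 1)
    bouts = np.split(zeros, breaks + 1)
    bout_durs = tuple(len(b) * interval_min for b in bouts)

    censored = l4_idx is None
    return LethargusCall(
        individual_id=raster.individual_id,
        group=raster.group,
        entry_h=float(t[zeros[0]]),
        exit_h=float(t[zeros[-1]] + interval_min / 60.0),
        l4_onset_h=float(t[l4_idx]) if l4_idx is not None else None,
        duration_min=float(len(zeros) * interval_min),
        longest_bout_min=float(max(bout_durs)),
        bout_durations_min=bout_durs,
        n_bouts=len(bouts),
        fragmented=len(bouts) >= 2,
        censored=censored,
    )


def _summarise(calls: list[LethargusCall], long_threshold_min: float) -> dict:
    ok = [c for c in calls if not c.censored]
    if not ok:
        raise ValueError("all calls in a group are censored")
    entries = np.array([c.entry_h for c in ok])
    durations = np.array([c.duration_min for c in ok])
    l4 = np.array([c.l4_onset_h for c in ok], dtype=float)
    return {
        "n": len(calls),
        "n_censored": sum(c.censored for c in calls),
        "entry_mean_h": float(entries.mean()),
        "entry_median_h": float(np.median(entries)),
        "l4_onset_mean_h": float(np.nanmean(l4)),
        "l4_onset_median_h": float(np.nanmedian(l4)),
        "duration_mean_min": float(durations.mean()),
        "duration_median_min": float(np.median(durations)),
        "fragmented_fraction": float(np.mean([c.fragmented for c in ok])),
        "long_fraction": float(np.mean(durations > long_threshold_min)),
    }


def cohort_lethargus_stats(
    calls_by_group: dict[str, list[LethargusCall]], long_threshold_min: float = 100.0
) -> dict:
    """Per-group lethargus summaries plus pairwise differences.

    A long episode has total duration strictly greater than the threshold
    (default 100 min).  Differences are second group minus first, in the
    dict's iteration order.
    """
    out = {g: _summarise(calls, long_threshold_min) for g, calls in calls_by_group.items()}
    groups = list(calls_by_group)
    if len(groups) == 2:
        a, b = groups
        out["difference"] = {
            k: out[b][k] - out[a][k]
            for k in out[a]
            if isinstance(out[a][k], float)
        }
    return out


def feeding_fraction(rasters, window: tuple[float, float]) -> float:
    """Pooled fraction of pumping observations within a time window.

    Pooled across animals (episodes of feeding over all recorded episodes),
    not averaged per animal: fraction = sum of pumping observations in the
    window over all observations in the window, across every raster.
    """
    t1, t2 = window
    if t2 <= t1:
        raise ValueError("window end must follow start")
    pumping = total = 0
    for r in rasters:
        mask = (r.times >= t1 - 1e-12) & (r.times <= t2 + 1e-12)
        pumping += int(r.pumping[mask].sum())
        total += int(mask.sum())
    if total == 0:
        raise ValueError("window contains no observations")
    return pumping / total


def stage_transition_fractions(rasters, t: float) -> dict:
    """Fractions of individuals that exited L3 / entered L4 by time t.

    An individual has exited L3 by t when its first quiescent observation
    is at or before t, and entered L4 when its L4 onset is at or before t.
    Censored individuals remain in the denominators.
    """
    calls = [call_lethargus(r) for r in rasters]
    n = len(calls)
    if n == 0:
        raise ValueError("no rasters supplied")
    exited = sum(1 for c in calls if c.entry_h is not None and c.entry_h <= t + 1e-12)
    entered = sum(1 for c in calls if c.l4_onset_h is not None and c.l4_onset_h <= t + 1e-12)
    return {"t": t, "n": n, "exited_l3_fraction": exited / n, "entered_l4_fraction": entered / n}


def pumping_rate(counts: int, duration_s: float, on_lawn: bool = True) -> dict:
    """Normalize a grinder-movement count to a rate, applying exclusions.

    rate = counts / duration_s (movements per second).  Worms with zero
    observed grinder movements, or located off the bacterial lawn, are
    excluded with the reason recorded rather than given a rate.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if counts < 0:
        raise ValueError("counts must be >= 0")
    if not on_lawn:
        return {"rate_per_s": None, "excluded": True, "reason": "off_lawn"}
    if counts == 0:
        return {"rate_per_s": None, "excluded": True, "reason": "no_pumping"}
    return {"rate_per_s": counts / duration_s, "excluded": False, "reason": None}


def compare_groups(values_a, values_b, kind: str = "continuous") -> dict:
    """Two-group comparison: Welch t (continuous) or Fisher exact (binary).

    Continuous: two-sided Welch t-test; effect is the difference of means
    (b minus a).  Binary: values are 0/1 outcomes; Fisher's exact test on
    the 2x2 table; effect is the difference of proportions.  Degenerate
    inputs (zero variance in both continuous groups) are flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 values per continuous group")
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        return {
            "method": "welch_t", "p_value": p,
            "effect": float(b.mean() - a.mean()),
            "n_a": len(a), "n_b": len(b), "degenerate": bool(degenerate),
        }
    if kind == "binary":
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("binary comparison requires 0/1 values")
        table = [[int(a.sum()), int(len(a) - a.sum())], [int(b.sum()), int(len(b) - b.sum())]]
        p = float(stats.fisher_exact(table)[1])
        return {
            "method": "fisher_exact", "p_value": p,
            "effect": float(b.mean() - a.mean()),
            "n_a": len(a), "n_b": len(b), "degenerate": False,
        }
    raise ValueError(f"unknown kind {kind!r}")
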