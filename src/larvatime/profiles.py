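"""Stage-normalized activity profiles.

Larval stages differ in duration across individuals (spreads exceeding 6 h
are routine), so averaging activity on the wall-clock axis smears any
within-stage structure.  The standard remedy is to express each
individual's activity against percent of stage completion: crop the trace
to the stage, map time t in [0, D_j] to i = 100*t/D_j, resample on a common
percent grid and average across individuals.  Roaming-biased early-stage
behavior and dwelling-biased late-stage behavior then line up regardless of
how fast each worm develops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityTrace",
    "StageProfile",
    "crop_to_stage",
    "resample_percent",
    "average_profiles",
    "stage_profile",
    "naive_molt_detector",
]


@dataclass
class ActivityTrace:
    """One individual's activity curve with known stage boundaries.

    times: hours, strictly increasing.  activity: displacement over the
    previous 10 s (arbitrary length units).  stage_boundaries maps a stage
    name to (entry_h, exit_h), nested within the trace's span.
    """

    individual_id: str
    times: np.ndarray
    activity: np.ndarray
    stage_boundaries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.activity.shape:
            raise ValueError("times and activity must be 1-D and equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for stage, (entry, exit_) in self.stage_boundaries.items():
            if exit_ <= entry:
                raise ValueError(f"stage {stage!r}: exit must follow entry")

    def stage_duration(self, stage: str) -> float:
        entry, exit_ = self.stage_boundaries[stage]
        return exit_ - entry


@dataclass
class StageProfile:
    """Population profile on the percent-of-stage grid."""

    stage: str
    grid: np.ndarray  # percent completion, 0..100
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    individual: np.ndarray = field(repr=False)  # (n_individuals, n_grid)


def crop_to_stage(trace: ActivityTrace, stage: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Restrict a trace to one larval stage, re-origined to stage entry.

    Returns (t_rel, activity, D_j) with t_rel starting at 0 and D_j the
    stage duration in hours.
    """
    if stage not in trace.stage_boundaries:
        raise KeyError(f"trace {trace.individual_id!r} has no boundaries for stage {stage!r}")
    entry, exit_ = trace.stage_boundaries[stage]
    mask = (trace.times >= entry - 1e-12) & (trace.times <= exit_ + 1e-12)
    return trace.times[mask] - entry, trace.activity[mask], exit_ - entry


def resample_percent(
    t_rel: np.ndarray, activity: np.ndarray, duration_h: float, grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a cropped curve onto the percent-completion grid.

    P(i) is the curve evaluated at t = D_j * i / 100 by linear interpolation
    between neighbouring samples; beyond the first/last sample the nearest
    sample value is used.  Returns (grid, P).
    """
    t_rel = np.asarray(t_rel, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if len(t_rel) < 2:
        raise ValueError("need at least two samples within the stage to resample")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    p = np.interp(duration_h * grid / 100.0, t_rel, activity)
    return grid, p


def average_profiles(profiles: list[np.ndarray], grid: np.ndarray, stage: str = "") -> StageProfile:
    """Pointwise mean/SD/SEM of per-individual percent profiles.

    NaN entries (an individual undefined at a grid point) are excluded with
    n tracked per point.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    mat = np.vstack(profiles)
    if mat.shape[1] != len(grid):
        raise ValueError("profiles are not on the supplied grid")
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.where(n > 0, np.nanmean(mat, axis=0), np.nan)
    if mat.shape[0] > 1:
        with np.errstate(invalid="ignore"):
            sd = np.where(n > 1, np.nanstd(mat, axis=0, ddof=1), np.nan)
    else:
        sd = np.full(mat.shape[1], np.nan)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return StageProfile(stage=stage, grid=np.asarray(grid, float), mean=mean, sd=sd, sem=sem, n=n, individual=mat)


def stage_profile(traces, stage: str, grid_step: float = 1.0) -> StageProfile:
    """crop -> resample -> average, for a whole cohort."""
    grid = None
    profiles = []
    for trace in traces:
        t_rel, act, dur = crop_to_stage(trace, stage)
        grid, p = resample_percent(t_rel, act, dur, grid_step)
        profiles.append(p)
    return average_profiles(profiles, grid, stage=stage)


def naive_molt_detector(
    trace: ActivityTrace, expected_h: float, search_half_width_h: float = 1.5, smooth_n: int = 11
) -> float:
    """Locate a molt as the activity minimum near an expected time.

    A convenience only: real stage boundaries come from dedicated staging,
    and this detector is not a substitute for them.  The trace is smoothed
    with a ``smooth_n``-sample moving average and the time of the minimum
    within expected_h +/- search_half_width_h is returned.
    """
    mask = np.abs(trace.times - expected_h) <= search_half_width_h
    if mask.sum() < smooth_n:
        raise ValueError("too few samples in the search window")
    t, a = trace.times[mask], trace.activity[mask]
    kernel = np.ones(smooth_n) / smooth_n
    smoothed = np.convolve(a, kernel, mode="valid")  # no zero-padded edges
    offset = (smooth_n - 1) // 2
    return float(t[offset + np.argmin(smoothed)])
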