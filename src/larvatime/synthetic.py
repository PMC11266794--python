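"""Ground-truthed synthetic inputs for every analysis stage.

Each generator emulates one of the data modalities the pipeline consumes —
a lineage diagram rendered in the standard pixel dialect, cohorts of larval
activity traces sharing a percent-of-stage template, binary pharyngeal
pumping rasters around the L3-to-L4 transition, and length/width growth
tables — and returns the exact ground truth alongside, so every stage can
be tested end to end without external data.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import ActivityTrace
from .pumping import PumpingRaster

__all__ = [
    "LineageSpec",
    "BehaviorSimParams",
    "render_lineage_diagram",
    "random_lineage_spec",
    "simulate_activity_cohort",
    "simulate_pumping_cohort",
    "simulate_morphometry",
]


# ---------------------------------------------------------------------------
# lineage diagrams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageSpec:
    """Layout of a synthetic lineage diagram.

    divisions: list of (row_index, n_bars) — each entry places ``n_bars``
    horizontal division bars whose top edge is at ``row_index``.  Bars are
    ``bar_height`` rows tall and wider than the deletion cutoff; vertical
    cell lines are ``line_width`` px wide.  Entries whose row spans overlap
    are rejected, because bars merging vertically would be uncountable.
    """

    divisions: tuple[tuple[int, int], ...]
    image_height: int
    image_width: int
    bar_height: int = 2
    line_width: int = 2

    def __post_init__(self):
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.bar_height < 1 or self.line_width < 1:
            raise ValueError("bar_height and line_width must be positive")
        spans = []
        for row, n_bars in self.divisions:
            if n_bars < 1:
                raise ValueError("n_bars must be >= 1")
            if row < 0 or row + self.bar_height > self.image_height:
                raise ValueError(f"division at row {row} does not fit the image height")
            # each bar needs >= line_width+1 ink px and a >= 1 px white gap
            slot = self.image_width // n_bars
            if slot < self.line_width + 2:
                raise ValueError(f"{n_bars} bars do not fit width {self.image_width} without touching")
            spans.append((row, row + self.bar_height))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"divisions at rows {a0} and {b0} overlap vertically and would merge")


def _free(canvas: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> bool:
    """True if the region, dilated by 1 px, contains no ink (keeps new
    elements 8-disconnected from everything already drawn)."""
    h, w = canvas.shape
    r0, c0 = max(r0 - 1, 0), max(c0 - 1, 0)
    r1, c1 = min(r1 + 1, h), min(c1 + 1, w)
    return not canvas[r0:r1, c0:c1].any()


def render_lineage_diagram(
    spec: LineageSpec,
    rng: np.random.Generator | None = None,
    n_death_markers: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a diagram in the standard pixel dialect; return (image, truth).

    The image is binary (1 = ink).  ``truth[i]`` is the exact number of
    division bars crossing row i (each bar counts in every row it spans).
    Vertical connector lines and optional 'X' death markers — five disjoint
    dots of side <= 2 px — are drawn only where they stay 8-disconnected
    from the bars, so narrow-element deletion removes exactly them under
    either the component or the per-row-run rule.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    h, w = spec.image_height, spec.image_width
    canvas = np.zeros((h, w), dtype=np.uint8)
    truth = np.zeros(h, dtype=np.int64)
    min_bar = spec.line_width + 1  # strictly wider than the deletion cutoff

    bar_anchors = []  # (row, center_col) for connector placement
    for row, n_bars in spec.divisions:
        slot = w // n_bars
        for b in range(n_bars):
            lo = b * slot
            max_bar = slot - 1  # leave >= 1 px white gap to the next slot
            width = int(rng.integers(min_bar, max_bar + 1))
            start = lo + int(rng.integers(0, max_bar - width + 1))
            canvas[row : row + spec.bar_height, start : start + width] = 1
            bar_anchors.append((row, start + width // 2))
        truth[row : row + spec.bar_height] += n_bars

    # vertical connector lines above each bar, 1 px clear of the bar
    for row, col in bar_anchors:
        length = int(rng.integers(4, 9))
        r1 = row - 2  # exclusive-ish: line occupies rows [r1-length, r1)
        r0 = max(r1 - length, 0)
        c0 = min(col, w - spec.line_width)
        if r1 > r0 and _free(canvas, r0, r1, c0, c0 + spec.line_width):
            canvas[r0:r1, c0 : c0 + spec.line_width] = 1

    # 'X' death markers: five disjoint dots (corners + center), each <= 2 px
    offsets = [(0, 0), (-3, -3), (-3, 3), (3, -3), (3, 3)]
    for _ in range(n_death_markers):
        for _attempt in range(20):
            r = int(rng.integers(5, h - 5))
            c = int(rng.integers(5, w - 5))
            if _free(canvas, r - 4, r + 6, c - 4, c + 6):
                for dr, dc in offsets:
                    canvas[r + dr : r + dr + 2, c + dc : c + dc + 2] = 1
                break

    return canvas, truth


def random_lineage_spec(
    rng: np.random.Generator,
    image_height: int = 300,
    image_width: int = 500,
    max_divisions: int = 10,
    max_bars: int = 8,
    bar_height: int = 2,
) -> LineageSpec:
    """Draw a valid random LineageSpec (non-overlapping division rows)."""
    n_div = int(rng.integers(1, max_divisions + 1))
    # keep division rows >= bar_height + 1 apart so spans never overlap
    rows = rng.choice(np.arange(1, (image_height - bar_height) // (bar_height + 1)), size=n_div, replace=False)
    rows = np.sort(rows) * (bar_height + 1)
    divisions = tuple((int(r), int(rng.integers(1, max_bars + 1))) for r in rows)
    return LineageSpec(
        divisions=divisions,
        image_height=image_height,
        image_width=image_width,
        bar_height=bar_height,
    )


# ---------------------------------------------------------------------------
# activity traces
# ---------------------------------------------------------------------------


def simulate_activity_cohort(
    template,
    n: int,
    duration_mean: float = 8.0,
    duration_cv: float = 0.15,
    noise_sd: float = 0.1,
    seed: int = 0,
    dt_h: float = 0.01,
    stage: str = "L3",
) -> tuple[list[ActivityTrace], dict]:
    """Simulate a cohort sharing an activity template on the percent axis.

    Each individual i draws its own stage duration D_i ~ Normal(mean,
    cv*mean) (redrawn while non-positive, bounded retries) and its activity
    is ``template(100*t/D_i)`` plus iid Gaussian noise, sampled every
    ``dt_h`` hours.  Activity is displacement per 10 s, the unit used for
    larval locomotion traces.  Returns the traces and a ground-truth dict
    with the drawn durations and the template.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if duration_cv < 0 or noise_sd < 0:
        raise ValueError("duration_cv and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    traces, durations = [], []
    for i in range(n):
        d = -1.0
        for _ in range(100):
            d = rng.normal(duration_mean, duration_cv * duration_mean)
            if d > 0:
                break
        if d <= 0:
            raise RuntimeError("could not draw a positive stage duration")
        t = np.arange(0.0, d + dt_h / 2, dt_h)
        t[-1] = min(t[-1], d)
        c = np.asarray(template(100.0 * t / d), dtype=float) + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(
            ActivityTrace(
                individual_id=f"sim{i:03d}",
                times=t,
                activity=c,
                stage_boundaries={stage: (0.0, float(d))},
            )
        )
        durations.append(float(d))
    truth = {"durations": np.asarray(durations), "template": template, "noise_sd": noise_sd}
    return traces, truth


# ---------------------------------------------------------------------------
# pumping rasters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorSimParams:
    """Conditions for the pumping-raster simulator.

    Defaults follow the standard L3-to-L4 scoring design: 10 s observations
    every 20 min across a 32-39 h window; lethargus onset centred at 34 h
    (half the cohort has exited L3 by 34 h); episode durations drawn from a
    short mode (truncated normal on (0, 100] min) plus, with probability
    ``long_weight``, a long mode strictly above 100 min, so ``long_weight``
    IS the ground-truth long-episode mass.  ``fragmentation_prob`` is the
    chance an episode is interrupted by one resumption of pumping.
    """

    n_individuals: int = 50
    sampling_interval_min: float = 20.0
    observation_window_h: tuple[float, float] = (32.0, 39.0)
    onset_mean_h: float = 34.0
    onset_sd_h: float = 1.0
    duration_short_mean_min: float = 85.0
    duration_short_sd_min: float = 20.0
    duration_long_scale_min: float = 45.0
    long_weight: float = 0.20
    fragmentation_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.observation_window_h[0] >= self.observation_window_h[1]:
            raise ValueError("observation window start must precede end")
        for p in (self.long_weight, self.fragmentation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.onset_sd_h < 0 or self.duration_short_sd_min < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def _draw_duration_min(params: BehaviorSimParams, rng: np.random.Generator) -> float:
    """Mixture draw: P(duration > 100 min) == long_weight exactly."""
    if rng.random() < params.long_weight:
        return 100.0 + rng.exponential(params.duration_long_scale_min)
    for _ in range(1000):
        d = rng.normal(params.duration_short_mean_min, params.duration_short_sd_min)
        if 0.0 < d <= 100.0:
            return d
    raise RuntimeError("short-mode truncation failed")


def simulate_pumping_cohort(
    params: BehaviorSimParams, group_label: str = "control"
) -> tuple[list[PumpingRaster], pd.DataFrame]:
    """Simulate a cohort of binary pumping rasters with known lethargus.

    Each individual pumps until its drawn lethargus onset, is quiescent for
    its drawn duration, then resumes pumping as an L4 (l4 flag set from the
    first post-lethargus observation).  Onsets are left-truncated at the
    window start.  Fragmented individuals get one interior pumping
    observation inserted by extending the quiescent stretch one grid step,
    so the total count of quiescent observations still tracks the drawn
    duration.  Individuals whose onset falls after the window, or whose
    episode is not finished in-window, are marked censored, never dropped.

    Returns the rasters and a ground-truth table (one row per individual)
    with drawn and discretized onset/duration, fragmentation and censoring.
    """
    rng = np.random.default_rng(params.seed)
    start, end = params.observation_window_h
    dt = params.sampling_interval_min / 60.0
    times = start + dt * np.arange(int(np.floor((end - start) / dt + 1e-9)) + 1)
    n_obs = len(times)

    rasters, records = [], []
    for i in range(params.n_individuals):
        onset = max(rng.normal(params.onset_mean_h, params.onset_sd_h), start)
        dur_min = _draw_duration_min(params, rng)
        want_frag = rng.random() < params.fragmentation_prob

        pumping = np.ones(n_obs, dtype=np.int64)
        l4 = np.zeros(n_obs, dtype=np.int64)
        qidx = np.flatnonzero((times >= onset - 1e-12) & (times < onset + dur_min / 60.0 - 1e-12))

        fragmented = False
        if want_frag and len(qidx) >= 2 and qidx[-1] + 1 < n_obs:
            qidx = np.append(qidx, qidx[-1] + 1)  # extend one step to keep total quiescence
            interior = qidx[len(qidx) // 2]
            if interior not in (qidx[0], qidx[-1]):
                qidx = qidx[qidx != interior]
                fragmented = True

        pumping[qidx] = 0
        censored = len(qidx) == 0 or qidx[-1] + 1 >= n_obs
        if not censored:
            l4[qidx[-1] + 1 :] = 1

        records.append(
            {
                "individual_id": f"{group_label}{i:03d}",
                "group": group_label,
                "onset_drawn_h": onset,
                "duration_drawn_min": dur_min,
                "onset_obs_h": float(times[qidx[0]]) if len(qidx) else np.nan,
                "n_quiescent_obs": int(len(qidx)),
                "duration_obs_min": len(qidx) * params.sampling_interval_min,
                "l4_onset_h": float(times[qidx[-1] + 1]) if not censored else np.nan,
                "fragmented": fragmented,
                "censored": censored,
                "long_episode": dur_min > 100.0,
            }
        )
        rasters.append(
            PumpingRaster(
                individual_id=f"{group_label}{i:03d}",
                times=times.copy(),
                pumping=pumping,
                l4=l4,
                group=group_label,
            )
        )
    return rasters, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# morphometry tables
# ---------------------------------------------------------------------------


def simulate_morphometry(
    n_per_group: int = 30,
    timepoints=(30.0, 32.0, 34.0, 36.0, 38.0, 40.0),
    growth_rate: float = 0.016,
    length_at_start_um: float = 600.0,
    width_to_length_ratio: float = 0.06,
    noise_cv: float = 0.035,
    group_offset_h: float = 0.0,
    divergence_time_h: float | None = None,
    groups: tuple[str, str] = ("control", "MCP"),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate isomorphic growth tables for two groups.

    Length follows L(t) = L0 * exp(growth_rate * (t - t0)); width is
    ``width_to_length_ratio`` times length, so growth is isomorphic by
    construction.  Both dimensions get independent multiplicative Gaussian
    measurement noise of ``noise_cv``.  The second group runs the same
    trajectory advanced by ``group_offset_h`` — from the start when
    ``divergence_time_h`` is None, or only at timepoints >=
    ``divergence_time_h`` otherwise (a growth acceleration switching on at
    that age).  At the default 1.6%/h length growth a 2 h advance makes
    volume ~10% larger.
    """
    if width_to_length_ratio <= 0:
        raise ValueError("width_to_length_ratio must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    t0 = float(timepoints[0])
    rows = []
    for gi, group in enumerate(groups):
        offset = group_offset_h if gi == 1 else 0.0
        for t in timepoints:
            eff = offset if (divergence_time_h is None or t >= divergence_time_h) else 0.0
            length_true = length_at_start_um * np.exp(growth_rate * (t - t0 + eff))
            width_true = width_to_length_ratio * length_true
            for i in range(n_per_group):
                rows.append(
                    {
                        "individual_id": f"{group}_t{t:g}_{i:03d}",
                        "time_h": float(t),
                        "group": group,
                        "length_um": length_true * (1.0 + rng.normal(0.0, noise_cv)),
                        "width_um": width_true * (1.0 + rng.normal(0.0, noise_cv)),
                    }
                )
    df = pd.DataFrame.from_records(rows)
    if (df[["length_um", "width_um"]] <= 0).any().any():
        raise RuntimeError("noise produced a non-positive measurement; lower noise_cv")
    return df
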