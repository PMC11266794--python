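"""Worm morphometrics: cylindrical body volume, isomorphy, divergence onset.

Body volume is estimated from midline length and body width assuming a
cylindrical larva, V = pi * length * (width/2)**2.  Growth of two groups is
compared through (a) the width-to-length ratio over time — isomorphic
growth keeps proportions, so no timepoint should show a group difference in
the ratio — and (b) per-timepoint volume comparisons locating the earliest
sustained divergence between the groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pumping import compare_groups

__all__ = [
    "estimate_volume",
    "add_volume",
    "polyline_length",
    "isomorphy_test",
    "divergence_onset",
    "relative_size",
]


def estimate_volume(length_um, width_um):
    """Cylindrical body volume V = pi * length * (width/2)^2, in um^3.

    Vectorized; inputs must be positive and width smaller than length.
    """
    length = np.asarray(length_um, dtype=float)
    width = np.asarray(width_um, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("length and width must be positive")
    if np.any(width >= length):
        raise ValueError("width must be smaller than length")
    return np.pi * length * (width / 2.0) ** 2


def add_volume(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a morphometry table with a volume_um3 column."""
    out = records.copy()
    out["volume_um3"] = estimate_volume(out["length_um"].to_numpy(), out["width_um"].to_numpy())
    return out


def polyline_length(points) -> float:
    """Length of a segmented midline: sum of Euclidean segment lengths.

    ``points`` is an (n, 2) array of vertex coordinates, as produced by a
    segmented-line skeletonization of the worm midline.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need >= 2 two-dimensional points")
    return float(np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1)).sum())


def _holm(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _per_time_tests(records: pd.DataFrame, column: str, groups: tuple[str, str]) -> pd.DataFrame:
    ga, gb = groups
    times = sorted(set(records.loc[records.group == ga, "time_h"]) & set(records.loc[records.group == gb, "time_h"]))
    if not times:
        raise ValueError("groups share no timepoints")
    rows = []
    for t in times:
        a = records.loc[(records.group == ga) & (records.time_h == t), column].to_numpy()
        b = records.loc[(records.group == gb) & (records.time_h == t), column].to_numpy()
        res = compare_groups(a, b, kind="continuous")
        rows.append({"time_h": t, "effect": res["effect"], "p_value": res["p_value"],
                     "n_a": res["n_a"], "n_b": res["n_b"]})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = _holm(out["p_value"].to_numpy())
    return out


def isomorphy_test(records: pd.DataFrame, groups: tuple[str, str] = ("control", "MCP"), alpha: float = 0.05) -> dict:
    """Test whether two groups grow isomorphically.

    Compares the width/length ratio between groups at every shared
    timepoint (Welch t, Holm-adjusted across timepoints).  The verdict is
    isomorphic when no timepoint shows a significant ratio difference.
    """
    df = records.copy()
    df["ratio"] = df["width_um"] / df["length_um"]
    tests = _per_time_tests(df, "ratio", groups)
    return {
        "per_time": tests,
        "isomorphic": bool((tests["p_adjusted"] >= alpha).all()),
        "alpha": alpha,
    }


def divergence_onset(records: pd.DataFrame, groups: tuple[str, str] = ("control", "MCP"), alpha: float = 0.05) -> dict:
    """Earliest sustained volume divergence between two groups.

    Runs a per-timepoint Welch t-test on body volume (Holm-adjusted across
    timepoints).  The onset is the earliest timepoint at which the
    difference is significant and stays significant at every later measured
    timepoint; None when no such timepoint exists.
    """
    df = add_volume(records) if "volume_um3" not in records.columns else records
    tests = _per_time_tests(df, "volume_um3", groups)
    sig = (tests["p_adjusted"] < alpha).to_numpy()
    onset = None
    # sustained: significant from here through the last timepoint
    sustained = np.flip(np.cumprod(np.flip(sig.astype(bool)))).astype(bool)
    if sustained.any():
        onset = float(tests.loc[np.argmax(sustained), "time_h"])
    return {"per_time": tests, "onset_h": onset, "alpha": alpha}


def relative_size(records: pd.DataFrame, t: float, groups: tuple[str, str] = ("control", "MCP")) -> float:
    """Percent difference of mean volumes at time t: 100*(b - a)/a."""
    df = add_volume(records) if "volume_um3" not in records.columns else records
    ga, gb = groups
    a = df.loc[(df.group == ga) & (df.time_h == t), "volume_um3"]
    b = df.loc[(df.group == gb) & (df.time_h == t), "volume_um3"]
    if a.empty or b.empty:
        raise ValueError(f"both groups must be measured at t={t}")
    return float(100.0 * (b.mean() - a.mean()) / a.mean())
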