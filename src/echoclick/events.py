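"""Grouping of clicks into fixed-window acoustic events and event-level
feature summaries (per-parameter means, ICI by histogram mode)."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS

__all__ = ["MIN_EVENT_CLICKS", "ICI_MODE_BIN_S", "assign_events", "ici_mode", "event_feature_summary", "build_event_table"]

#: Events need at least two clicks so the ICI mode exists.
MIN_EVENT_CLICKS = 2

#: Histogram bin width (s) used to approximate the ICI mode.
ICI_MODE_BIN_S = 0.010


def assign_events(times_s: np.ndarray, window_s: float, anchor_s: float = 0.0) -> np.ndarray:
    """Index of the half-open window ``[anchor + k*w, anchor + (k+1)*w)``
    containing each click time."""
    times_s = np.asarray(times_s, dtype=float)
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    return np.floor((times_s - anchor_s) / window_s).astype(int)


def ici_mode(click_times_s: np.ndarray, bin_s: float = ICI_MODE_BIN_S) -> float:
    """Mode of successive click-time differences.

    Approximated as the centre of the most populated histogram bin; bins
    are centred on multiples of ``bin_s`` so exact grid values land on
    their own centre.  Ties break toward the smaller interval.  Fewer
    than two clicks leave the mode undefined (NaN).
    """
    t = np.sort(np.asarray(click_times_s, dtype=float))
    if t.size < 2:
        return float("nan")
    d = np.diff(t)
    # bin k covers [(k - 0.5) * bin_s, (k + 0.5) * bin_s)
    k = np.floor(d / bin_s + 0.5).astype(int)
    counts = np.bincount(k)
    return float(np.argmax(counts) * bin_s)


def event_feature_summary(click_features: pd.DataFrame, click_times_s: np.ndarray) -> pd.Series:
    """Mean of each click-level parameter, with ``ici`` replaced by the
    event-level ICI mode."""
    if len(click_features) < MIN_EVENT_CLICKS:
        raise ValueError("event below the minimum click count")
    means = click_features[list(FEATURE_COLUMNS)].mean()
    means["ici"] = ici_mode(click_times_s)
    return means


def build_event_table(click_table: pd.DataFrame, min_clicks: int = MIN_EVENT_CLICKS) -> pd.DataFrame:
    """Aggregate a click-level table into the events x parameters table.

    ``click_table`` must carry the 20 feature columns plus ``time_s``,
    ``event_id``, ``species`` and ``encounter``.  Events with fewer than
    ``min_clicks`` clicks or an undefined ICI mode are dropped.
    """
    required = {"time_s", "event_id", "species", "encounter"}
    missing = required - set(click_table.columns)
    if missing:
        raise ValueError(f"click table missing columns: {sorted(missing)}")
    rows = []
    for event_id, grp in click_table.groupby("event_id", sort=True):
        if len(grp) < min_clicks:
            continue
        summary = event_feature_summary(grp, grp["time_s"].to_numpy())
        if not np.isfinite(summary["ici"]):
            continue
        row = summary.to_dict()
        row["event_id"] = event_id
        row["species"] = grp["species"].iloc[0]
        row["encounter"] = grp["encounter"].iloc[0]
        row["n_clicks"] = len(grp)
        rows.append(row)
    cols = list(FEATURE_COLUMNS) + ["species", "encounter", "event_id", "n_clicks"]
    return pd.DataFrame(rows, columns=cols)
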