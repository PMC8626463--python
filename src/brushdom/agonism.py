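"""Agonistic replacement detection from electronic bin-visit logs.

A replacement is one cow pushing another away from a feed or water bin
and occupying the same bin.  In electronic visit data this leaves a
signature: the displaced cow's visit ends and, within a short interval,
a different cow's visit starts at the same bin.  The validated interval
is 26 s or less, boundary inclusive.  Only consecutive occupancies of a
bin are paired, so one departure can yield at most one replacement.
"""

from __future__ import annotations

import pandas as pd

from .io import REPLACEMENT_COLUMNS


def detect_replacements(visits: pd.DataFrame,
                        threshold_seconds: float = 26.0) -> pd.DataFrame:
    """Detect replacements in a validated visit log.

    For each bin independently, visits are ordered by start time and a
    replacement is emitted for every consecutive pair of visits by
    different cows whose inter-visit gap (next start minus previous end)
    lies in ``[0, threshold_seconds]``.  The incoming cow is the actor
    (winner), the departing cow the reactor (loser); the event time is
    the actor's visit start.

    Parameters
    ----------
    visits
        Validated visit frame (non-overlapping per bin).
    threshold_seconds
        Maximum gap, inclusive.  Default 26 s.

    Returns
    -------
    DataFrame with columns time, bin_id, bin_type, actor_id, reactor_id,
    gap_seconds, sorted by (time, bin_id, actor_id).
    """
    if threshold_seconds < 0:
        raise ValueError(f"threshold_seconds must be >= 0, got {threshold_seconds}")
    if visits.empty:
        return pd.DataFrame(columns=REPLACEMENT_COLUMNS)

    v = visits.sort_values(["bin_id", "start_time"], kind="mergesort")
    same_bin = v["bin_id"].eq(v["bin_id"].shift())
    prev_cow = v["cow_id"].shift()
    prev_end = v["end_time"].shift()
    gap = (v["start_time"] - prev_end).dt.total_seconds()
    hit = same_bin & (v["cow_id"] != prev_cow) & (gap >= 0) & (gap <= threshold_seconds)

    out = pd.DataFrame(
        {
            "time": v.loc[hit, "start_time"],
            "bin_id": v.loc[hit, "bin_id"],
            "bin_type": v.loc[hit, "bin_type"],
            "actor_id": v.loc[hit, "cow_id"],
            "reactor_id": prev_cow[hit],
            "gap_seconds": gap[hit],
        }
    )
    return out.sort_values(
        ["time", "bin_id", "actor_id"], kind="mergesort", ignore_index=True
    )


def replacement_counts(replacements: pd.DataFrame) -> pd.DataFrame:
    """Per-cow counts of replacements performed (actor) and received (reactor)."""
    performed = replacements["actor_id"].value_counts()
    received = replacements["reactor_id"].value_counts()
    out = pd.DataFrame({"performed": performed, "received": received})
    out = out.fillna(0).astype(int)
    out.index.name = "cow_id"
    return out.sort_index()


def replacement_ratio(replacements: pd.DataFrame, cow_id: str) -> float | None:
    """Replacements performed per replacement received for one cow.

    Returns ``None`` (an explicit undefined flag, never infinity) when the
    cow was never displaced — including cows absent from the log entirely.
    """
    performed = int((replacements["actor_id"] == cow_id).sum())
    received = int((replacements["reactor_id"] == cow_id).sum())
    if received == 0:
        return None
    return performed / received
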