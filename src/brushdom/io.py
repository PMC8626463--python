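"""CSV schemas, readers/writers and validation for the barn event logs.

The pipeline exchanges four tabular formats, all comma-separated UTF-8
with a header row and ISO-8601 timestamps at one-second resolution
(timezone-naive local barn time):

roster.csv        cow_id,entry_time,calving_time,parity,excluded,exclusion_reason
visits.csv        cow_id,bin_id,bin_type,start_time,end_time
brush.csv         event_type,cow_id,recipient_id,start_time,end_time,rotation_active
replacements.csv  time,bin_id,bin_type,actor_id,reactor_id,gap_seconds

``brush.csv`` mixes two event kinds: ``event_type=use`` rows are brushing
bouts (cow_id, start_time, end_time, rotation_active) and
``event_type=displacement`` rows are physical displacements at the brush
(cow_id holds the performer, recipient_id the displaced cow, start_time
the moment of contact).

Validation is total: every malformed row yields a :class:`ValidationError`
that names the offending CSV line numbers (header = line 1); rows are
never silently dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("brushdom")

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"

VISIT_COLUMNS = ["cow_id", "bin_id", "bin_type", "start_time", "end_time"]
ROSTER_COLUMNS = [
    "cow_id",
    "entry_time",
    "calving_time",
    "parity",
    "excluded",
    "exclusion_reason",
]
REPLACEMENT_COLUMNS = [
    "time",
    "bin_id",
    "bin_type",
    "actor_id",
    "reactor_id",
    "gap_seconds",
]
BRUSH_EVENT_COLUMNS = ["cow_id", "start_time", "end_time", "rotation_active"]
BRUSH_DISPLACEMENT_COLUMNS = ["time", "performer_id", "recipient_id"]


class ValidationError(ValueError):
    """A located data-validation failure (CSV line numbers in the message)."""


def _csv_lines(df: pd.DataFrame, mask) -> list[int]:
    """CSV line numbers (1-based, header = line 1) of rows selected by mask."""
    return [int(i) + 2 for i in df.index[mask]]


def _parse_times(df: pd.DataFrame, columns, where: str) -> None:
    for col in columns:
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"{where}: unparseable {col} at CSV lines {_csv_lines(df, bad)}"
            )
        df[col] = parsed


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------

def validate_roster(df: pd.DataFrame, where: str = "roster") -> pd.DataFrame:
    df = df.copy()
    dup = df["cow_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{where}: duplicate cow_id at CSV lines {_csv_lines(df, dup)}"
        )
    bad = ~(df["entry_time"] < df["calving_time"])
    if bad.any():
        raise ValidationError(
            f"{where}: entry_time must precede calving_time at CSV lines "
            f"{_csv_lines(df, bad)}"
        )
    bad = df["parity"] < 1
    if bad.any():
        raise ValidationError(
            f"{where}: parity must be a positive integer at CSV lines "
            f"{_csv_lines(df, bad)}"
        )
    return df.sort_values("cow_id", ignore_index=True)


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cow_id": str, "exclusion_reason": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns and c != "exclusion_reason"]
    if missing:
        raise ValidationError(f"roster {path}: missing columns {missing}")
    if "exclusion_reason" not in df.columns:
        df["exclusion_reason"] = ""
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    _parse_times(df, ["entry_time", "calving_time"], f"roster {path}")
    df["parity"] = df["parity"].astype(int)
    df["excluded"] = df["excluded"].astype(bool)
    return validate_roster(df, where=f"roster {path}")


def write_roster(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("entry_time", "calving_time"):
        out[col] = out[col].dt.strftime(TIME_FORMAT)
    out[ROSTER_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bin visits
# ---------------------------------------------------------------------------

def validate_visits(df: pd.DataFrame, roster: pd.DataFrame | None = None,
                    where: str = "visits") -> pd.DataFrame:
    """Check visit invariants; return the frame sorted by (bin_id, start_time).

    Invariants: start < end; bin_type in {feed, water}; one occupant per bin
    (no overlapping visits at one bin_id); if a roster is given, every cow_id
    is known and every visit lies within the cow's residence window.
    """
    df = df.copy()
    bad = ~(df["start_time"] < df["end_time"])
    if bad.any():
        raise ValidationError(
            f"{where}: start_time must precede end_time at CSV lines "
            f"{_csv_lines(df, bad)}"
        )
    bad = ~df["bin_type"].isin(["feed", "water"])
    if bad.any():
        raise ValidationError(
            f"{where}: bin_type must be 'feed' or 'water' at CSV lines "
            f"{_csv_lines(df, bad)}"
        )

    ordered = df.sort_values(["bin_id", "start_time"], kind="mergesort")
    same_bin = ordered["bin_id"].eq(ordered["bin_id"].shift())
    overlap = same_bin & (ordered["start_time"] < ordered["end_time"].shift())
    if overlap.any():
        pairs = []
        pos = np.flatnonzero(overlap.to_numpy())
        for p in pos[:10]:
            a = int(ordered.index[p - 1]) + 2
            b = int(ordered.index[p]) + 2
            pairs.append((a, b))
        raise ValidationError(
            f"{where}: overlapping visits at one bin; colliding CSV line pairs "
            f"{pairs}" + (" (first 10 shown)" if len(pos) > 10 else "")
        )

    if roster is not None:
        known = set(roster["cow_id"])
        bad = ~df["cow_id"].isin(known)
        if bad.any():
            names = sorted(df.loc[bad, "cow_id"].unique())
            raise ValidationError(
                f"{where}: unknown cow_id {names} at CSV lines {_csv_lines(df, bad)}"
            )
        ridx = roster.set_index("cow_id")
        entry = df["cow_id"].map(ridx["entry_time"])
        calv = df["cow_id"].map(ridx["calving_time"])
        bad = (df["start_time"] < entry) | (df["end_time"] > calv)
        if bad.any():
            raise ValidationError(
                f"{where}: visit outside the cow's residence window at CSV lines "
                f"{_csv_lines(df, bad)}"
            )
    return ordered.reset_index(drop=True)


def read_visits(path, roster: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cow_id": str, "bin_id": str, "bin_type": str})
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"visits {path}: missing columns {missing}")
    _parse_times(df, ["start_time", "end_time"], f"visits {path}")
    return validate_visits(df, roster=roster, where=f"visits {path}")


def write_visits(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("start_time", "end_time"):
        out[col] = out[col].dt.strftime(TIME_FORMAT)
    out[VISIT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# brush log (use bouts + displacements in one file)
# ---------------------------------------------------------------------------

def read_brush_log(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a mixed brush log; return (use bouts, displacements)."""
    df = pd.read_csv(
        path, dtype={"event_type": str, "cow_id": str, "recipient_id": str}
    )
    for col in ("event_type", "cow_id", "start_time"):
        if col not in df.columns:
            raise ValidationError(f"brush log {path}: missing column {col!r}")
    if "recipient_id" not in df.columns:
        df["recipient_id"] = None
    if "end_time" not in df.columns:
        df["end_time"] = None
    if "rotation_active" not in df.columns:
        df["rotation_active"] = True
    bad = ~df["event_type"].isin(["use", "displacement"])
    if bad.any():
        raise ValidationError(
            f"brush log {path}: event_type must be 'use' or 'displacement' at "
            f"CSV lines {_csv_lines(df, bad)}"
        )
    _parse_times(df, ["start_time", "end_time"], f"brush log {path}")

    use = df[df["event_type"] == "use"].copy()
    bad = ~(use["start_time"] < use["end_time"])
    if bad.any():
        raise ValidationError(
            f"brush log {path}: use bout needs start_time < end_time at CSV "
            f"lines {_csv_lines(use, bad)}"
        )
    _BOOL = {True: True, False: False, "True": True, "False": False,
             "true": True, "false": False, "1": True, "0": False, 1: True,
             0: False}
    try:
        use["rotation_active"] = [
            True if pd.isna(v) or v == "" else _BOOL[v]
            for v in use["rotation_active"]
        ]
    except KeyError as exc:
        raise ValidationError(
            f"brush log {path}: rotation_active must be boolean, got {exc}"
        ) from exc
    events = (
        use[BRUSH_EVENT_COLUMNS]
        .sort_values("start_time", kind="mergesort")
        .reset_index(drop=True)
    )

    disp = df[df["event_type"] == "displacement"].copy()
    bad = disp["recipient_id"].isna() | (disp["recipient_id"] == "")
    if bad.any():
        raise ValidationError(
            f"brush log {path}: displacement needs a recipient_id at CSV lines "
            f"{_csv_lines(disp, bad)}"
        )
    bad = disp["cow_id"] == disp["recipient_id"]
    if bad.any():
        raise ValidationError(
            f"brush log {path}: displacement performer equals recipient at CSV "
            f"lines {_csv_lines(disp, bad)}"
        )
    disp = disp.rename(columns={"cow_id": "performer_id", "start_time": "time"})
    displacements = (
        disp[BRUSH_DISPLACEMENT_COLUMNS]
        .sort_values("time", kind="mergesort")
        .reset_index(drop=True)
    )
    return events, displacements


def write_brush_log(events: pd.DataFrame, displacements: pd.DataFrame, path) -> None:
    use = events.copy()
    use.insert(0, "event_type", "use")
    use["recipient_id"] = ""
    disp = displacements.rename(
        columns={"performer_id": "cow_id", "time": "start_time"}
    ).copy()
    disp.insert(0, "event_type", "displacement")
    disp["end_time"] = pd.NaT
    disp["rotation_active"] = ""
    cols = ["event_type", "cow_id", "recipient_id", "start_time", "end_time",
            "rotation_active"]
    out = pd.concat([use[cols], disp[cols]], ignore_index=True)
    out = out.sort_values("start_time", kind="mergesort")
    for col in ("start_time", "end_time"):
        out[col] = out[col].dt.strftime(TIME_FORMAT)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# replacements
# ---------------------------------------------------------------------------

def read_replacements(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"bin_id": str, "bin_type": str, "actor_id": str,
                     "reactor_id": str}
    )
    missing = [c for c in REPLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"replacements {path}: missing columns {missing}")
    _parse_times(df, ["time"], f"replacements {path}")
    bad = df["actor_id"] == df["reactor_id"]
    if bad.any():
        raise ValidationError(
            f"replacements {path}: actor equals reactor at CSV lines "
            f"{_csv_lines(df, bad)}"
        )
    bad = df["gap_seconds"] < 0
    if bad.any():
        raise ValidationError(
            f"replacements {path}: negative gap_seconds at CSV lines "
            f"{_csv_lines(df, bad)}"
        )
    return df.sort_values(
        ["time", "bin_id", "actor_id"], kind="mergesort", ignore_index=True
    )


def write_replacements(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = out["time"].dt.strftime(TIME_FORMAT)
    out[REPLACEMENT_COLUMNS].to_csv(path, index=False)
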