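"""Sequential Elo rating of a dynamically changing cow group.

Every cow enters the group with a start rating (1000 points).  After each
replacement the winner (actor) gains and the loser (reactor) loses

    transfer = (1 - p) * k

points, where p is the winning expectation — the probability that the
actor displaces the reactor given the pre-event rating difference — and
k (default 20) caps the points exchanged per interaction.  The
expectation is the normal-CDF form used throughout the animal-dominance
Elo literature:

    p = Phi((actor_rating - reactor_rating) / scale),   scale = 200 * sqrt(2)

so equally rated opponents transfer exactly k/2 points, an expected
outcome (higher-rated actor wins) transfers less, and an upset transfers
more.  Ratings are real-valued; the integer "points gained" figures used
in reports come from :func:`transfer_band`.

Ratings are updated per event in chronological order and snapshotted per
calendar day of each cow's residence; a cow's exit freezes its
trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EloConfig

log = logging.getLogger("brushdom")

_SQRT2 = math.sqrt(2.0)


class EloError(ValueError):
    """Raised for replacements that are inconsistent with the roster."""


def expectation(actor_rating: float, reactor_rating: float,
                config: EloConfig | None = None) -> float:
    """Winning expectation p of the actor against the reactor.

    Standard-normal CDF of the rating difference divided by
    ``config.expectation_scale``.  Satisfies p = 0.5 at equal ratings,
    strict monotonicity in the difference, and p(a,b) + p(b,a) = 1.
    """
    config = config or EloConfig()
    z = (actor_rating - reactor_rating) / config.expectation_scale
    # complementary error function keeps tiny tail probabilities exact,
    # so a huge favourite's transfer stays strictly positive
    return 0.5 * math.erfc(-z / _SQRT2)


def update(actor_rating: float, reactor_rating: float,
           config: EloConfig | None = None) -> tuple[float, float, float]:
    """Apply one replacement; return (new actor, new reactor, transfer).

    transfer = (1 - p) * k; the actor gains it, the reactor loses it, so
    the rating sum is conserved.  No rounding is applied.
    """
    config = config or EloConfig()
    z = (actor_rating - reactor_rating) / config.expectation_scale
    # 1 - p computed directly in the tail (see expectation)
    transfer = 0.5 * math.erfc(z / _SQRT2) * config.k
    return actor_rating + transfer, reactor_rating - transfer, transfer


def transfer_band(transfer: float, expected_outcome: bool, k: float = 20.0) -> int:
    """Integer reporting band for a transfer.

    Expected outcomes (actor rated strictly higher) transfer less than
    k/2 and report ``floor(transfer)`` — 0..9 at k = 20; unexpected
    outcomes transfer more than k/2 and report ``ceil(transfer)`` —
    11..20.  A transfer of exactly k/2 (equal pre-event ratings) reports
    round(k/2) = 10 regardless of the flag.
    """
    if not (0.0 < transfer <= k):
        raise ValueError(f"transfer must lie in (0, {k}], got {transfer}")
    if transfer == k / 2.0:
        return int(round(k / 2.0))
    return math.floor(transfer) if expected_outcome else math.ceil(transfer)


@dataclass
class RatingTrajectory:
    """Daily rating snapshots plus the full per-event update sequence.

    ``daily`` has one row per cow per residence day (cow_id, date,
    rating); the entry-day snapshot is the rating at entry
    (= start_rating), later days are end-of-day values.  ``events``
    records, per replacement, both cows' pre/post ratings, the winning
    expectation, the transfer and its reporting band.
    """

    daily: pd.DataFrame
    events: pd.DataFrame
    start_rating: float

    def snapshots(self, cow_id: str) -> pd.Series:
        sub = self.daily[self.daily["cow_id"] == cow_id]
        return pd.Series(sub["rating"].to_numpy(), index=sub["date"].to_numpy())

    def final_ratings(self) -> pd.Series:
        """Each cow's last snapshot (frozen at exit or at the data end)."""
        last = self.daily.sort_values(["cow_id", "date"]).groupby("cow_id").tail(1)
        return pd.Series(last["rating"].to_numpy(), index=last["cow_id"].to_numpy())


def run_elo(replacements: pd.DataFrame, roster: pd.DataFrame,
            config: EloConfig | None = None,
            last_day: pd.Timestamp | None = None) -> RatingTrajectory:
    """Rate the whole replacement stream and snapshot daily.

    Events are applied in chronological order with a deterministic tie
    break on (time, bin_id, actor_id).  Snapshots cover every calendar
    day of each cow's residence from entry to calving (clipped at
    ``last_day`` when given, e.g. the last day with sensor data) and no
    day outside it.

    Raises
    ------
    EloError
        If a replacement references a cow absent from the roster or
        outside its residence window at the event time.
    """
    config = config or EloConfig()
    ridx = roster.set_index("cow_id")

    ev = replacements.sort_values(
        ["time", "bin_id", "actor_id"], kind="mergesort"
    ).reset_index(drop=True)
    for col in ("actor_id", "reactor_id"):
        unknown = set(ev[col]) - set(ridx.index)
        if unknown:
            raise EloError(f"replacement {col} not in roster: {sorted(unknown)}")
    for col in ("actor_id", "reactor_id"):
        entry = ev[col].map(ridx["entry_time"])
        calv = ev[col].map(ridx["calving_time"])
        bad = (ev["time"] < entry) | (ev["time"] > calv)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise EloError(
                f"replacement at {ev.loc[i, 'time']} references {col} "
                f"{ev.loc[i, col]!r} outside its residence window"
            )

    entry_day = ridx["entry_time"].dt.normalize()
    exit_day = ridx["calving_time"].dt.normalize()
    if last_day is not None:
        last_day = pd.Timestamp(last_day).normalize()
        exit_day = exit_day.clip(upper=last_day)

    ratings: dict[str, float] = {c: config.start_rating for c in ridx.index}
    ev_day = ev["time"].dt.normalize()
    ev_by_day = {day: grp for day, grp in ev.groupby(ev_day)}

    day0 = entry_day.min().normalize()
    day1 = exit_day.max()
    days = pd.date_range(day0, day1, freq="D")

    event_rows: list[tuple] = []
    daily_rows: list[tuple] = []
    for day in days:
        grp = ev_by_day.get(day)
        if grp is not None:
            for row in grp.itertuples(index=False):
                a, r = row.actor_id, row.reactor_id
                pre_a, pre_r = ratings[a], ratings[r]
                p = expectation(pre_a, pre_r, config)
                new_a, new_r, transfer = update(pre_a, pre_r, config)
                ratings[a], ratings[r] = new_a, new_r
                if pre_a == pre_r:
                    band = transfer_band(transfer, True, config.k)
                else:
                    band = transfer_band(transfer, pre_a > pre_r, config.k)
                event_rows.append(
                    (row.time, a, r, p, transfer, band, pre_a, new_a, pre_r, new_r)
                )
        resident = ridx.index[(entry_day <= day) & (day <= exit_day)]
        for cow in resident:
            value = config.start_rating if day == entry_day[cow] else ratings[cow]
            daily_rows.append((cow, day, value))

    daily = pd.DataFrame(daily_rows, columns=["cow_id", "date", "rating"])
    daily = daily.sort_values(["cow_id", "date"], ignore_index=True)
    events = pd.DataFrame(
        event_rows,
        columns=["time", "actor_id", "reactor_id", "p", "transfer", "band",
                 "actor_pre", "actor_post", "reactor_pre", "reactor_post"],
    )
    return RatingTrajectory(daily=daily, events=events,
                            start_rating=config.start_rating)


def mean_elo_precalving(trajectory: RatingTrajectory, cow: pd.Series,
                        window_days: int = 7) -> float | None:
    """Mean of a cow's daily snapshots over the pre-calving window.

    The window is the ``window_days`` calendar days ending the day before
    the calving day.  When only part of the window falls inside the cow's
    snapshot record, the mean is taken over the available days and a
    warning is logged; with no snapshots at all the cow is flagged
    missing (``None``) and excluded downstream.
    """
    calving_day = pd.Timestamp(cow["calving_time"]).normalize()
    lo = calving_day - pd.Timedelta(days=window_days)
    hi = calving_day - pd.Timedelta(days=1)
    snaps = trajectory.snapshots(cow["cow_id"])
    window = snaps[(snaps.index >= lo) & (snaps.index <= hi)]
    if window.empty:
        log.warning("cow %s: no rating snapshots in the pre-calving window",
                    cow["cow_id"])
        return None
    if len(window) < window_days:
        log.warning("cow %s: only %d of %d window days have snapshots",
                    cow["cow_id"], len(window), window_days)
    return float(window.mean())
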