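"""Dominance-extreme selection and the brush-use statistical battery.

Given per-cow pre-calving Elo means, this module selects the dominance
extremes (below the 0.15 / above the 0.85 empirical quantile, then the
12 lowest and 12 highest), builds the cow-by-day brush-use matrix for
the 7 pre-calving days, and runs:

* one-way random-effects ICC of daily brush use (consistency across days),
* five single-predictor OLS models on weekly totals — brush duration vs
  dominance status / performed displacements / received displacements,
  and performed / received displacements vs dominance status,
* balanced split-plot ANOVAs of the diel pattern: per-cow mean minutes in
  each 3-h period of the day, with period, dominance, their interaction,
  and cow nested within dominance as the blocking term.  With 12 cows
  per group and 8 periods the interaction is tested on (7, 154) df and
  the dominance main effect against the cow stratum on (1, 22) df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .agonism import detect_replacements, replacement_counts
from .config import AnalysisConfig
from .elo import RatingTrajectory, mean_elo_precalving, run_elo

log = logging.getLogger("brushdom")

DOMINANT = "dominant"
SUBORDINATE = "subordinate"
UNCLASSIFIED = "unclassified"


class SelectionError(ValueError):
    """Too few eligible cows in a percentile tail to fill the focal groups."""


class DesignError(ValueError):
    """The data do not form the balanced design a model requires."""


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class TermResult:
    term: str
    f: float
    df_num: int
    df_den: int
    p: float
    coef: float | None = None


@dataclass
class ModelResult:
    name: str
    terms: list[TermResult]
    residual_df: int
    degenerate: bool = False
    note: str = ""

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


@dataclass
class ICCResult:
    icc: float
    ms_between: float
    ms_within: float
    n_cows: int
    k_days: int
    undefined: bool = False


# ---------------------------------------------------------------------------
# selection of dominance extremes
# ---------------------------------------------------------------------------

def select_extremes(mean_elos: pd.Series | dict, roster: pd.DataFrame,
                    lower_q: float = 0.15, upper_q: float = 0.85,
                    n_per_group: int = 12) -> pd.DataFrame:
    """Label the dominance extremes among the scored, non-excluded cows.

    Empirical quantiles use the linear-interpolation definition
    (``numpy.quantile`` default).  Eligible cows lie strictly below the
    lower or strictly above the upper quantile; the ``n_per_group``
    lowest become subordinate and the ``n_per_group`` highest dominant
    (ties broken by cow_id); everyone else is unclassified.

    Returns a frame with one row per scored cow: cow_id, mean_elo_7d,
    category.  Raises :class:`SelectionError` when a tail is too small.
    """
    scores = pd.Series(mean_elos, dtype=float).dropna()
    scores.index.name = "cow_id"
    excluded = set(roster.loc[roster["excluded"], "cow_id"])
    eligible = scores[~scores.index.isin(excluded)]

    if len(eligible) < 2 * n_per_group:
        raise SelectionError(
            f"need at least {2 * n_per_group} non-excluded scored cows, "
            f"have {len(eligible)}"
        )
    lo = float(np.quantile(eligible.to_numpy(), lower_q))
    hi = float(np.quantile(eligible.to_numpy(), upper_q))
    low_tail = eligible[eligible < lo]
    high_tail = eligible[eligible > hi]
    if len(low_tail) < n_per_group or len(high_tail) < n_per_group:
        raise SelectionError(
            f"too few cows in the percentile tails: {len(low_tail)} strictly "
            f"below the {lower_q} quantile ({lo:.1f}), {len(high_tail)} "
            f"strictly above the {upper_q} quantile ({hi:.1f}); "
            f"{n_per_group} needed per tail"
        )

    def _take(tail: pd.Series, n: int, lowest: bool) -> list[str]:
        order = tail.reset_index()
        order.columns = ["cow_id", "score"]
        order = order.sort_values(["score", "cow_id"], ascending=[lowest, True])
        return list(order["cow_id"].head(n))

    subordinate = set(_take(low_tail, n_per_group, lowest=True))
    dominant = set(_take(high_tail, n_per_group, lowest=False))

    out = scores.reset_index()
    out.columns = ["cow_id", "mean_elo_7d"]
    out["category"] = UNCLASSIFIED
    out.loc[out["cow_id"].isin(subordinate), "category"] = SUBORDINATE
    out.loc[out["cow_id"].isin(dominant), "category"] = DOMINANT
    return out.sort_values("cow_id", ignore_index=True)


# ---------------------------------------------------------------------------
# per-day / per-period minute accounting
# ---------------------------------------------------------------------------

def _window_segments(events: pd.DataFrame, cow: pd.Series, window_days: int,
                     time_cols=("start_time", "end_time")):
    """One cow's events clipped to the pre-calving window, as integer
    seconds since the window start.  Returns (starts, ends, window_start)."""
    calving_day = pd.Timestamp(cow["calving_time"]).normalize()
    w0 = calving_day - pd.Timedelta(days=window_days)
    sub = events[events["cow_id"] == cow["cow_id"]]
    s = ((sub[time_cols[0]] - w0).dt.total_seconds()).to_numpy()
    e = ((sub[time_cols[1]] - w0).dt.total_seconds()).to_numpy()
    total = window_days * 86400
    s = np.clip(s, 0, total)
    e = np.clip(e, 0, total)
    keep = e > s
    return s[keep], e[keep], w0


def _bin_minutes(starts: np.ndarray, ends: np.ndarray, bin_seconds: int,
                 n_bins_total: int) -> np.ndarray:
    """Split [start, end) segments over a tiling of ``bin_seconds`` cells
    and return minutes per cell."""
    out = np.zeros(n_bins_total)
    for s, e in zip(starts, ends):
        k0 = int(s // bin_seconds)
        k1 = int((e - 1) // bin_seconds) if e > s else k0
        for k in range(k0, k1 + 1):
            lo = max(s, k * bin_seconds)
            hi = min(e, (k + 1) * bin_seconds)
            out[k] += (hi - lo) / 60.0
    return out


def daily_brush_minutes(brush_events: pd.DataFrame, cow: pd.Series,
                        window_days: int = 7) -> pd.Series:
    """Minutes of brush use per pre-calving day for one cow.

    The window is the ``window_days`` calendar days before the calving
    day; bouts spanning midnight are split proportionally between days,
    and bouts extending past the window edge count only their in-window
    part.  Returned Series is indexed by day offset -window_days..-1
    relative to the calving day; absent days are 0.
    """
    s, e, _ = _window_segments(brush_events, cow, window_days)
    per_day = _bin_minutes(s, e, 86400, window_days)
    return pd.Series(per_day, index=range(-window_days, 0), name=cow["cow_id"])


def build_daily_matrix(brush_events: pd.DataFrame, roster: pd.DataFrame,
                       cow_ids, window_days: int = 7) -> pd.DataFrame:
    """Cow-by-day matrix of brush minutes, columns aligned per cow's calving."""
    ridx = roster.set_index("cow_id")
    rows = []
    for c in cow_ids:
        cow = ridx.loc[c].copy()
        cow["cow_id"] = c
        rows.append(daily_brush_minutes(brush_events, cow, window_days))
    mat = pd.DataFrame(rows)
    mat.index = list(cow_ids)
    mat.index.name = "cow_id"
    return mat


def diel_period_minutes(events: pd.DataFrame, cow: pd.Series,
                        window_days: int = 7, period_hours: int = 3,
                        time_cols: tuple[str, str] = ("start_time", "end_time"),
                        ) -> pd.Series:
    """Mean daily minutes per diel period over the pre-calving window.

    Periods are ``period_hours``-wide bins of the day starting at
    midnight local time (8 bins of 3 h by default).  Events are clipped
    to the window, split at period boundaries, summed per period over
    the window, and divided by ``window_days``.
    """
    n_periods = 24 // period_hours
    s, e, _ = _window_segments(events, cow, window_days, time_cols)
    cells = _bin_minutes(s, e, period_hours * 3600, window_days * n_periods)
    totals = cells.reshape(window_days, n_periods).sum(axis=0)
    return pd.Series(totals / window_days, index=range(n_periods),
                     name=cow["cow_id"])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_consistency(matrix: pd.DataFrame) -> ICCResult:
    """One-way random-effects ICC of a cow-by-day matrix.

    ICC(1) = (MS_between - MS_within) / (MS_between + (k - 1) * MS_within)
    with k the number of days per cow; cows are the random grouping
    factor and days exchangeable repeats.  A matrix with zero total
    variance has no defined ICC and is flagged instead.
    """
    m = matrix.to_numpy(dtype=float)
    n, k = m.shape
    if n < 2 or k < 2:
        raise DesignError(f"need >= 2 cows and >= 2 days, got {n} x {k}")
    grand = m.mean()
    row_means = m.mean(axis=1)
    ss_between = k * float(((row_means - grand) ** 2).sum())
    ss_within = float(((m - row_means[:, None]) ** 2).sum())
    if ss_between + ss_within <= 1e-20 * m.size * max(1.0, grand * grand):
        return ICCResult(icc=float("nan"), ms_between=0.0, ms_within=0.0,
                         n_cows=n, k_days=k, undefined=True)
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    icc = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
    return ICCResult(icc=float(icc), ms_between=ms_between, ms_within=ms_within,
                     n_cows=n, k_days=k)


# ---------------------------------------------------------------------------
# weekly single-predictor models
# ---------------------------------------------------------------------------

def _single_predictor_ols(df: pd.DataFrame, response: str, predictor: str,
                          categorical: bool, name: str) -> ModelResult:
    constant = None
    if df[predictor].nunique() < 2:
        constant = f"constant predictor {predictor}"
    elif df[response].nunique() < 2:
        constant = f"constant response {response}"
    if constant:
        log.warning("model %s: %s, flagged degenerate", name, constant)
        return ModelResult(name=name, terms=[
            TermResult(predictor, float("nan"), 1, len(df) - 2, float("nan"))
        ], residual_df=len(df) - 2, degenerate=True, note=constant)
    rhs = f"C({predictor})" if categorical else predictor
    fit = smf.ols(f"{response} ~ {rhs}", data=df).fit()
    coef = float(fit.params.iloc[1])
    return ModelResult(
        name=name,
        terms=[TermResult(predictor, float(fit.fvalue), int(fit.df_model),
                          int(fit.df_resid), float(fit.f_pvalue), coef=coef)],
        residual_df=int(fit.df_resid),
    )


def weekly_models(weekly: pd.DataFrame) -> dict[str, ModelResult]:
    """The five weekly linear models on the focal cows.

    ``weekly`` needs one row per focal cow with columns category
    (dominant/subordinate), brush_min, performed, received.  Each model
    is an OLS with a single predictor, F reported on (1, n - 2) df:

    1. brush_min ~ category          3. brush_min ~ received
    2. brush_min ~ performed         4. performed ~ category
                                     5. received  ~ category

    For the categorical models the reported coefficient is the
    dominant-minus-subordinate difference.
    """
    w = weekly.copy()
    # patsy orders levels alphabetically (dominant < subordinate); recode so
    # the slope is dominant minus subordinate.
    w["category"] = pd.Categorical(w["category"], [SUBORDINATE, DOMINANT])
    return {
        "brush~dominance": _single_predictor_ols(
            w, "brush_min", "category", True, "brush~dominance"),
        "brush~performed": _single_predictor_ols(
            w, "brush_min", "performed", False, "brush~performed"),
        "brush~received": _single_predictor_ols(
            w, "brush_min", "received", False, "brush~received"),
        "performed~dominance": _single_predictor_ols(
            w, "performed", "category", True, "performed~dominance"),
        "received~dominance": _single_predictor_ols(
            w, "received", "category", True, "received~dominance"),
    }


# ---------------------------------------------------------------------------
# diel split-plot ANOVA
# ---------------------------------------------------------------------------

def split_plot_anova(long: pd.DataFrame, response: str, name: str) -> ModelResult:
    """Balanced split-plot ANOVA: period * dominance with cow blocking.

    ``long`` needs columns cow_id, category, period and the response, as
    a complete balanced grid: equal numbers of cows per category, every
    cow observed in every period.  Decomposition (a categories, n cows
    per category, q periods; N = a*n*q observations):

        SS_dom       df a-1        tested against MS_cow
        SS_cow(dom)  df a(n-1)     blocking stratum
        SS_period    df q-1        tested against residual
        SS_inter     df (a-1)(q-1) tested against residual
        SS_resid     df a(n-1)(q-1)

    With a=2, n=12, q=8 the interaction F carries (7, 154) df and the
    dominance F (1, 22) df.
    """
    from scipy import stats as sps

    cats = sorted(long["category"].unique())
    periods = sorted(long["period"].unique())
    a, q = len(cats), len(periods)
    counts = long.groupby(["cow_id", "period"], observed=True).size()
    if (counts != 1).any():
        raise DesignError(f"{name}: design is not one observation per cow per period")
    cows_per_cat = long.groupby("category", observed=True)["cow_id"].nunique()
    if cows_per_cat.nunique() != 1:
        raise DesignError(
            f"{name}: unequal group sizes {dict(cows_per_cat)}; the balanced "
            "split-plot decomposition requires equal numbers of cows per category"
        )
    n = int(cows_per_cat.iloc[0])
    expected = a * n * q
    if len(long) != expected:
        missing = {(c, p) for c in long["cow_id"].unique() for p in periods} - set(
            map(tuple, long[["cow_id", "period"]].itertuples(index=False)))
        raise DesignError(f"{name}: missing cells {sorted(missing)}")

    y = long[response].to_numpy(dtype=float)
    grand = y.mean()
    mean_cat = long.groupby("category", observed=True)[response].mean()
    mean_per = long.groupby("period", observed=True)[response].mean()
    mean_cp = long.groupby(["category", "period"], observed=True)[response].mean()
    mean_cow = long.groupby("cow_id", observed=True)[response].mean()
    cow_cat = long.drop_duplicates("cow_id").set_index("cow_id")["category"]

    ss_dom = n * q * float(((mean_cat - grand) ** 2).sum())
    ss_cow = q * float(
        ((mean_cow - cow_cat.map(mean_cat)) ** 2).sum())
    ss_per = a * n * float(((mean_per - grand) ** 2).sum())
    inter = mean_cp.copy()
    for (c, p), v in mean_cp.items():
        inter[(c, p)] = v - mean_cat[c] - mean_per[p] + grand
    ss_int = n * float((inter ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_dom - ss_cow - ss_per - ss_int

    df_dom, df_cow = a - 1, a * (n - 1)
    df_per, df_int = q - 1, (a - 1) * (q - 1)
    df_err = a * (n - 1) * (q - 1)
    ms = lambda ss, df: ss / df  # noqa: E731
    ms_err = ms(ss_err, df_err)
    ms_cow = ms(ss_cow, df_cow)

    def term(tname, ss, dfn, err_ms, dfd):
        if err_ms == 0.0:
            return TermResult(tname, float("nan"), dfn, dfd, float("nan"))
        f = ms(ss, dfn) / err_ms
        return TermResult(tname, float(f), dfn, dfd,
                          float(sps.f.sf(f, dfn, dfd)))

    return ModelResult(
        name=name,
        terms=[
            term("dominance", ss_dom, df_dom, ms_cow, df_cow),
            term("period", ss_per, df_per, ms_err, df_err),
            term("period:dominance", ss_int, df_int, ms_err, df_err),
        ],
        residual_df=df_err,
        note="cow nested within dominance is the blocking stratum "
             f"(df {df_cow}); dominance tested against it",
    )


def diel_models(period_long: pd.DataFrame) -> tuple[ModelResult, ModelResult]:
    """Split-plot ANOVAs of the diel pattern for brush use and feeding time.

    ``period_long`` needs columns cow_id, category, period,
    brush_min, feed_min (per-cow mean daily minutes per period).
    """
    brush = split_plot_anova(period_long, "brush_min", "diel brush use")
    feed = split_plot_anova(period_long, "feed_min", "diel feeding time")
    return brush, feed


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Bundle of every table the full pipeline produces."""

    replacements: pd.DataFrame
    trajectory: RatingTrajectory
    mean_elos: pd.Series
    assignments: pd.DataFrame
    daily_matrix: pd.DataFrame
    icc: ICCResult
    weekly: pd.DataFrame
    weekly_results: dict[str, ModelResult]
    period_long: pd.DataFrame
    diel_brush: ModelResult
    diel_feed: ModelResult
    params: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def weekly_summary(assignments: pd.DataFrame, roster: pd.DataFrame,
                   brush_events: pd.DataFrame, brush_displacements: pd.DataFrame,
                   window_days: int = 7) -> pd.DataFrame:
    """Per focal cow: weekly brush minutes and displacement counts.

    Totals cover the same pre-calving window as the Elo mean.
    """
    focal = assignments[assignments["category"] != UNCLASSIFIED]
    ridx = roster.set_index("cow_id")
    rows = []
    for row in focal.itertuples(index=False):
        cow = ridx.loc[row.cow_id].copy()
        cow["cow_id"] = row.cow_id
        calving_day = pd.Timestamp(cow["calving_time"]).normalize()
        w0 = calving_day - pd.Timedelta(days=window_days)
        brush_min = float(daily_brush_minutes(brush_events, cow, window_days).sum())
        disp = brush_displacements
        in_win = (disp["time"] >= w0) & (disp["time"] < calving_day)
        performed = int(((disp["performer_id"] == row.cow_id) & in_win).sum())
        received = int(((disp["recipient_id"] == row.cow_id) & in_win).sum())
        rows.append((row.cow_id, row.category, brush_min, performed, received))
    return pd.DataFrame(
        rows, columns=["cow_id", "category", "brush_min", "performed", "received"]
    )


def diel_summary(assignments: pd.DataFrame, roster: pd.DataFrame,
                 brush_events: pd.DataFrame, visits: pd.DataFrame,
                 window_days: int = 7, period_hours: int = 3) -> pd.DataFrame:
    """Long table of per-cow per-period mean daily minutes (brush + feeding).

    Feeding time counts feed-bin visits only; water bins are excluded.
    """
    focal = assignments[assignments["category"] != UNCLASSIFIED]
    ridx = roster.set_index("cow_id")
    feed_visits = visits[visits["bin_type"] == "feed"]
    rows = []
    for row in focal.itertuples(index=False):
        cow = ridx.loc[row.cow_id].copy()
        cow["cow_id"] = row.cow_id
        b = diel_period_minutes(brush_events, cow, window_days, period_hours)
        f = diel_period_minutes(feed_visits, cow, window_days, period_hours)
        for p in b.index:
            rows.append((row.cow_id, row.category, int(p), float(b[p]), float(f[p])))
    return pd.DataFrame(
        rows, columns=["cow_id", "category", "period", "brush_min", "feed_min"]
    )


def run_full_analysis(roster: pd.DataFrame, visits: pd.DataFrame,
                      brush_events: pd.DataFrame,
                      brush_displacements: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> AnalysisReport:
    """Execute the whole pipeline: detect, rate, select, model.

    Cows are scored (pre-calving Elo mean) only when their full
    ``window_days`` pre-calving window lies inside the observed data
    range, so partially observed cows never enter the focal groups.
    """
    config = config or AnalysisConfig()
    warnings: list[str] = []

    replacements = detect_replacements(visits, config.elo.threshold_seconds)
    last_time = visits["end_time"].max()
    if not brush_events.empty:
        last_time = max(last_time, brush_events["end_time"].max())
    first_time = visits["start_time"].min()
    last_day = pd.Timestamp(last_time).normalize()
    first_day = pd.Timestamp(first_time).normalize()

    trajectory = run_elo(replacements, roster, config.elo, last_day=last_day)

    mean_elos = {}
    for _, cow in roster.iterrows():
        calving_day = cow["calving_time"].normalize()
        if calving_day > last_day:
            continue  # censored: still resident when the data end
        if calving_day - pd.Timedelta(days=config.window_days) < first_day:
            warnings.append(
                f"cow {cow['cow_id']}: pre-calving window starts before the "
                "data range; cow not scored"
            )
            continue
        m = mean_elo_precalving(trajectory, cow, config.window_days)
        if m is not None:
            mean_elos[cow["cow_id"]] = m
    mean_elos = pd.Series(mean_elos, dtype=float)
    mean_elos.index.name = "cow_id"

    assignments = select_extremes(
        mean_elos, roster, config.lower_quantile, config.upper_quantile,
        config.n_per_group,
    )

    focal_ids = assignments.loc[
        assignments["category"] != UNCLASSIFIED, "cow_id"]
    daily = build_daily_matrix(brush_events, roster, focal_ids,
                               config.window_days)
    icc = icc_consistency(daily)
    if icc.undefined:
        warnings.append("ICC undefined: zero total variance in daily brush use")

    weekly = weekly_summary(assignments, roster, brush_events,
                            brush_displacements, config.window_days)
    weekly_results = weekly_models(weekly)
    for mr in weekly_results.values():
        if mr.degenerate:
            warnings.append(f"model {mr.name} degenerate: {mr.note}")

    period_long = diel_summary(assignments, roster, brush_events, visits,
                               config.window_days, config.period_hours)
    diel_brush, diel_feed = diel_models(period_long)

    from .config import config_as_dict

    return AnalysisReport(
        replacements=replacements, trajectory=trajectory, mean_elos=mean_elos,
        assignments=assignments, daily_matrix=daily, icc=icc, weekly=weekly,
        weekly_results=weekly_results, period_long=period_long,
        diel_brush=diel_brush, diel_feed=diel_feed,
        params=config_as_dict(config), warnings=warnings,
    )


def model_table(results) -> pd.DataFrame:
    """Flatten ModelResults into one tidy frame (one row per term)."""
    if isinstance(results, dict):
        results = list(results.values())
    elif isinstance(results, ModelResult):
        results = [results]
    rows = []
    for mr in results:
        for t in mr.terms:
            rows.append((mr.name, t.term, t.coef, t.f, t.df_num, t.df_den,
                         t.p, mr.degenerate))
    return pd.DataFrame(rows, columns=[
        "model", "term", "coef", "F", "df_num", "df_den", "p", "degenerate"])
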