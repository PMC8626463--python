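"""Selection, minute accounting, ICC, weekly and diel models, pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from brushdom import (
    AnalysisConfig,
    SelectionError,
    daily_brush_minutes,
    diel_models,
    diel_period_minutes,
    icc_consistency,
    run_full_analysis,
    select_extremes,
    split_plot_anova,
    weekly_models,
)
from brushdom.stats import DesignError, build_daily_matrix, weekly_summary

from conftest import make_roster


def _cow(cow_id="A", calving="2021-03-15"):
    cow = make_roster([cow_id], calving=calving).iloc[0]
    return cow


def _events(cow_id, spans):
    df = pd.DataFrame(spans, columns=["start_time", "end_time"])
    df["start_time"] = pd.to_datetime(df["start_time"])
    df["end_time"] = pd.to_datetime(df["end_time"])
    df.insert(0, "cow_id", cow_id)
    return df


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

class TestSelectExtremes:
    def _roster_scores(self, n, rng):
        ids = [f"C{i:03d}" for i in range(n)]
        return make_roster(ids), pd.Series(rng.normal(1000, 60, n), index=ids)

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(0)
        roster, scores = self._roster_scores(100, rng)
        out = select_extremes(scores, roster)
        lo, hi = np.quantile(scores, [0.15, 0.85])
        eligible_low = scores[scores < lo].sort_values()
        eligible_high = scores[scores > hi].sort_values()
        assert set(out.loc[out.category == "subordinate", "cow_id"]) == \
            set(eligible_low.index[:12])
        assert set(out.loc[out.category == "dominant", "cow_id"]) == \
            set(eligible_high.index[-12:])
        assert (out.category == "unclassified").sum() == 100 - 24

    def test_counts_equal_group_size(self):
        rng = np.random.default_rng(1)
        roster, scores = self._roster_scores(161, rng)
        out = select_extremes(scores, roster)
        assert (out.category == "dominant").sum() == 12
        assert (out.category == "subordinate").sum() == 12

    def test_excluded_cow_never_selected(self):
        rng = np.random.default_rng(2)
        ids = [f"C{i:03d}" for i in range(100)]
        roster = make_roster(ids, excluded={"C000"})
        scores = pd.Series(rng.normal(1000, 60, 100), index=ids)
        scores["C000"] = scores.min() - 100  # most subordinate but excluded
        out = select_extremes(scores, roster)
        assert "C000" not in set(out.loc[out.category != "unclassified", "cow_id"])

    def test_identical_scores_error(self):
        roster = make_roster([f"C{i}" for i in range(30)])
        scores = pd.Series(1000.0, index=roster.cow_id)
        with pytest.raises(SelectionError, match="tail"):
            select_extremes(scores, roster)

    def test_too_few_cows_error(self):
        roster = make_roster([f"C{i}" for i in range(10)])
        scores = pd.Series(np.arange(10.0), index=roster.cow_id)
        with pytest.raises(SelectionError, match="non-excluded"):
            select_extremes(scores, roster)


# ---------------------------------------------------------------------------
# daily / diel minutes
# ---------------------------------------------------------------------------

class TestDailyBrushMinutes:
    def test_single_bout_lands_on_its_day(self):
        cow = _cow(calving="2021-03-15")
        ev = _events("A", [("2021-03-12T10:00:00", "2021-03-12T10:30:00")])
        row = daily_brush_minutes(ev, cow)
        assert row[-3] == pytest.approx(30.0)
        assert row.drop(-3).eq(0).all()

    def test_midnight_bout_split_between_days(self):
        cow = _cow(calving="2021-03-15")
        ev = _events("A", [("2021-03-12T23:50:00", "2021-03-13T00:10:00")])
        row = daily_brush_minutes(ev, cow)
        assert row[-3] == pytest.approx(10.0)
        assert row[-2] == pytest.approx(10.0)

    def test_conservation_against_direct_sum(self):
        rng = np.random.default_rng(5)
        cow = _cow(calving="2021-03-15")
        w0 = pd.Timestamp("2021-03-08")
        spans = []
        for _ in range(40):
            s = w0 + pd.Timedelta(seconds=int(rng.integers(0, 7 * 86400 - 3600)))
            spans.append((s, s + pd.Timedelta(seconds=int(rng.integers(60, 3600)))))
        ev = _events("A", spans)
        row = daily_brush_minutes(ev, cow)
        in_window = sum(
            (min(e, pd.Timestamp("2021-03-15")) - max(s, w0)).total_seconds()
            for s, e in spans) / 60.0
        assert row.sum() == pytest.approx(in_window)


class TestDielPeriodMinutes:
    def test_single_bout_mean_over_window(self):
        cow = _cow(calving="2021-03-15")
        ev = _events("A", [("2021-03-12T01:00:00", "2021-03-12T02:00:00")])
        per = diel_period_minutes(ev, cow)
        assert per[0] == pytest.approx(60.0 / 7.0)
        assert per.drop(0).eq(0).all()

    def test_boundary_bout_split_between_periods(self):
        cow = _cow(calving="2021-03-15")
        ev = _events("A", [("2021-03-12T02:50:00", "2021-03-12T03:10:00")])
        per = diel_period_minutes(ev, cow)
        assert per[0] == pytest.approx(10.0 / 7.0)
        assert per[1] == pytest.approx(10.0 / 7.0)

    def test_period_totals_conserve_event_minutes(self):
        rng = np.random.default_rng(6)
        cow = _cow(calving="2021-03-15")
        w0 = pd.Timestamp("2021-03-08")
        spans = []
        for _ in range(30):
            s = w0 + pd.Timedelta(seconds=int(rng.integers(0, 7 * 86400 - 7200)))
            spans.append((s, s + pd.Timedelta(seconds=int(rng.integers(60, 7200)))))
        ev = _events("A", spans)
        per = diel_period_minutes(ev, cow)
        total = sum((e - s).total_seconds() for s, e in spans) / 60.0
        assert per.sum() * 7 == pytest.approx(total)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_perfect_repeatability(self):
        m = pd.DataFrame(np.repeat([[10.0], [20.0], [30.0]], 7, axis=1))
        assert icc_consistency(m).icc == pytest.approx(1.0)

    def test_shuffled_cells_near_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 7))
        icc = icc_consistency(pd.DataFrame(vals)).icc
        # i.i.d. cells: permutation distribution of ICC is centred at ~0
        perm = []
        flat = vals.ravel().copy()
        for _ in range(200):
            rng.shuffle(flat)
            perm.append(icc_consistency(
                pd.DataFrame(flat.reshape(40, 7))).icc)
        lo, hi = np.quantile(perm, [0.005, 0.995])
        assert lo <= icc <= hi

    def test_hand_matrix_matches_anova_oracle(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0],
                          [2.0, 4.0, 6.0],
                          [5.0, 5.0, 8.0],
                          [9.0, 7.0, 8.0]])
        res = icc_consistency(m)
        # direct-summation one-way ANOVA
        grand = m.to_numpy().mean()
        msb = 3 * ((m.mean(axis=1) - grand) ** 2).sum() / (4 - 1)
        msw = ((m.sub(m.mean(axis=1), axis=0)) ** 2).to_numpy().sum() / (4 * 2)
        assert res.ms_between == pytest.approx(msb)
        assert res.ms_within == pytest.approx(msw)
        assert res.icc == pytest.approx((msb - msw) / (msb + 2 * msw))

    def test_matches_pingouin_icc1(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(20, 5, size=(12, 7))
                         + rng.normal(0, 8, size=(12, 1)))
        long = m.reset_index().melt(id_vars="index",
                                    var_name="day", value_name="y")
        icc1 = pg.intraclass_corr(long, targets="index", raters="day",
                                  ratings="y").set_index("Type").loc["ICC(1,1)",
                                                                     "ICC"]
        assert icc_consistency(m).icc == pytest.approx(float(icc1), abs=1e-10)

    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(9)
        sb2, sw2 = 3.0, 1.0
        m = (rng.normal(0, np.sqrt(sb2), size=(400, 1))
             + rng.normal(0, np.sqrt(sw2), size=(400, 7)))
        assert icc_consistency(pd.DataFrame(m)).icc == pytest.approx(
            sb2 / (sb2 + sw2), abs=0.05)

    def test_zero_variance_flagged(self):
        m = pd.DataFrame(np.full((5, 7), 4.2))
        res = icc_consistency(m)
        assert res.undefined and np.isnan(res.icc)


# ---------------------------------------------------------------------------
# weekly models
# ---------------------------------------------------------------------------

def _weekly_frame(rng, n_per_group=12, effect=60.0):
    cats = ["dominant"] * n_per_group + ["subordinate"] * n_per_group
    brush = np.where(np.array(cats) == "dominant", 150.0 + effect, 150.0)
    brush = brush + rng.normal(0, 30, len(cats))
    return pd.DataFrame({
        "cow_id": [f"C{i:02d}" for i in range(2 * n_per_group)],
        "category": cats,
        "brush_min": brush,
        "performed": rng.poisson(1.5, len(cats)),
        "received": rng.poisson(1.5, len(cats)),
    })


class TestWeeklyModels:
    def test_df_structure_with_24_cows(self):
        w = _weekly_frame(np.random.default_rng(0))
        for res in weekly_models(w).values():
            t = res.terms[0]
            assert (t.df_num, t.df_den) == (1, 22)

    def test_identical_group_means_give_f_zero(self):
        w = _weekly_frame(np.random.default_rng(0), effect=0.0)
        w["brush_min"] = np.tile([100.0, 140.0], 12)  # same in both groups
        res = weekly_models(w)["brush~dominance"]
        assert res.terms[0].f == pytest.approx(0.0, abs=1e-20)

    def test_dominance_f_equals_t_squared(self):
        w = _weekly_frame(np.random.default_rng(4))
        res = weekly_models(w)["brush~dominance"].terms[0]
        d = w.loc[w.category == "dominant", "brush_min"]
        s = w.loc[w.category == "subordinate", "brush_min"]
        t = sps.ttest_ind(d, s)
        assert res.f == pytest.approx(t.statistic ** 2)
        assert res.p == pytest.approx(t.pvalue)
        assert res.coef == pytest.approx(d.mean() - s.mean())

    def test_continuous_predictor_matches_linregress(self):
        w = _weekly_frame(np.random.default_rng(5))
        res = weekly_models(w)["brush~performed"].terms[0]
        lr = sps.linregress(w["performed"], w["brush_min"])
        assert res.coef == pytest.approx(lr.slope)
        assert res.p == pytest.approx(lr.pvalue)

    def test_constant_predictor_flagged_degenerate(self):
        w = _weekly_frame(np.random.default_rng(6))
        w["performed"] = 0
        res = weekly_models(w)["brush~performed"]
        assert res.degenerate and np.isnan(res.terms[0].f)


# ---------------------------------------------------------------------------
# diel split-plot ANOVA
# ---------------------------------------------------------------------------

def _period_frame(rng, n_per_group=12, n_periods=8, interaction=0.0):
    rows = []
    for g, cat in enumerate(["dominant", "subordinate"]):
        for c in range(n_per_group):
            cow = f"{cat[0]}{c:02d}"
            cow_eff = rng.normal(0, 2)
            for p in range(n_periods):
                mu = 10 + 2 * np.sin(p) + cow_eff
                if cat == "dominant":
                    mu += interaction * (p in (2, 5))
                rows.append((cow, cat, p, mu + rng.normal(0, 1),
                             mu + rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["cow_id", "category", "period",
                                       "brush_min", "feed_min"])


def projection_anova_oracle(long, response):
    """Independent oracle: partial F via explicit least-squares projections."""
    cows = sorted(long["cow_id"].unique())
    periods = sorted(long["period"].unique())
    y = long[response].to_numpy(dtype=float)
    cow_d = pd.get_dummies(long["cow_id"]).to_numpy(dtype=float)
    per_d = pd.get_dummies(long["period"]).to_numpy(dtype=float)[:, 1:]
    dom = (long["category"] == "dominant").to_numpy(dtype=float)[:, None]
    inter = per_d * dom

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    full = np.hstack([cow_d, per_d, inter])
    reduced = np.hstack([cow_d, per_d])
    df_int = inter.shape[1]
    df_err = len(y) - np.linalg.matrix_rank(full)
    f = ((sse(reduced) - sse(full)) / df_int) / (sse(full) / df_err)
    return f, df_int, df_err


class TestDielModels:
    def test_df_structure_24_cows_8_periods(self):
        long = _period_frame(np.random.default_rng(0))
        brush, feed = diel_models(long)
        for res in (brush, feed):
            t = res.term("period:dominance")
            assert (t.df_num, t.df_den) == (7, 154)
            t = res.term("dominance")
            assert (t.df_num, t.df_den) == (1, 22)
            t = res.term("period")
            assert (t.df_num, t.df_den) == (7, 154)

    def test_interaction_f_matches_projection_oracle(self):
        long = _period_frame(np.random.default_rng(1), interaction=2.0)
        res = split_plot_anova(long, "brush_min", "oracle check")
        f, dfn, dfd = projection_anova_oracle(long, "brush_min")
        t = res.term("period:dominance")
        assert t.f == pytest.approx(f, rel=1e-9)
        assert (t.df_num, t.df_den) == (dfn, dfd)

    def test_small_design_matches_oracle(self):
        long = _period_frame(np.random.default_rng(2), n_per_group=2,
                             n_periods=2, interaction=1.0)
        res = split_plot_anova(long, "feed_min", "small design")
        f, dfn, dfd = projection_anova_oracle(long, "feed_min")
        t = res.term("period:dominance")
        assert t.f == pytest.approx(f, rel=1e-9)
        assert (t.df_num, t.df_den) == (dfn, dfd) == (1, 2)

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(3)
        fs, rejections = [], 0
        for _ in range(100):
            long = _period_frame(rng, interaction=0.0)
            t = split_plot_anova(long, "brush_min", "null").term(
                "period:dominance")
            fs.append(t.f)
            rejections += t.p < 0.05
        # F mean ~ df_den / (df_den - 2) ~ 1.01 under the null
        assert 0.75 < np.mean(fs) < 1.3
        assert rejections <= 12

    def test_missing_cell_raises(self):
        long = _period_frame(np.random.default_rng(4)).iloc[:-1]
        with pytest.raises(DesignError, match="missing cells"):
            split_plot_anova(long, "brush_min", "missing")

    def test_unequal_groups_raise(self):
        long = _period_frame(np.random.default_rng(5))
        long = long[long["cow_id"] != "d00"]
        with pytest.raises(DesignError, match="unequal group sizes"):
            split_plot_anova(long, "brush_min", "unbalanced")


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def long_sim():
    from brushdom import scenario_default, simulate_herd

    return simulate_herd(scenario_default(sim_days=112, seed=7))


class TestFullAnalysis:
    def test_end_to_end_report(self, long_sim):
        rep = run_full_analysis(long_sim.roster, long_sim.visits,
                                long_sim.brush_events,
                                long_sim.brush_displacements)
        assert (rep.assignments.category == "dominant").sum() == 12
        assert (rep.assignments.category == "subordinate").sum() == 12
        for res in rep.weekly_results.values():
            t = res.terms[0]
            assert (t.df_num, t.df_den) == (1, 22)
        t = rep.diel_brush.term("period:dominance")
        assert (t.df_num, t.df_den) == (7, 154)
        assert rep.daily_matrix.shape == (24, 7)
        assert (rep.daily_matrix.to_numpy() >= 0).all()
        assert -1 <= rep.icc.icc <= 1

    def test_selected_extremes_track_latent_dominance(self, long_sim):
        rep = run_full_analysis(long_sim.roster, long_sim.visits,
                                long_sim.brush_events,
                                long_sim.brush_displacements)
        lat = long_sim.truth.latent
        dom = lat[rep.assignments.loc[rep.assignments.category == "dominant",
                                      "cow_id"]].mean()
        sub = lat[rep.assignments.loc[rep.assignments.category == "subordinate",
                                      "cow_id"]].mean()
        assert dom - sub > 1.5

    def test_empty_brush_log_flagged_degenerate(self, small_sim):
        from brushdom import scenario_default, simulate_herd

        empty_events = small_sim.brush_events.iloc[0:0]
        empty_disp = small_sim.brush_displacements.iloc[0:0]
        cfg = AnalysisConfig(n_per_group=2, lower_quantile=0.3,
                             upper_quantile=0.7)
        rep = run_full_analysis(small_sim.roster, small_sim.visits,
                                empty_events, empty_disp, cfg)
        assert rep.icc.undefined
        assert rep.weekly_results["performed~dominance"].degenerate
        assert any("degenerate" in w for w in rep.warnings)

    def test_rerun_is_identical(self, long_sim):
        r1 = run_full_analysis(long_sim.roster, long_sim.visits,
                               long_sim.brush_events,
                               long_sim.brush_displacements)
        r2 = run_full_analysis(long_sim.roster, long_sim.visits,
                               long_sim.brush_events,
                               long_sim.brush_displacements)
        pd.testing.assert_frame_equal(r1.assignments, r2.assignments)
        pd.testing.assert_frame_equal(r1.weekly, r2.weekly)
        assert r1.diel_brush.term("period:dominance").f == \
            r2.diel_brush.term("period:dominance").f
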