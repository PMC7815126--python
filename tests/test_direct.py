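import numpy as np
import pandas as pd
import pytest

import mortsmooth as ms
from mortsmooth.ages import OLDER_SCHEME, U5_SCHEME, block_q_from_monthly
from mortsmooth.cmc import cmc
from mortsmooth.direct import (
    BandFit,
    build_period_grid,
    combine_bands_to_q,
    estimate_direct,
    expand_person_months,
    fit_band_logits,
    survey_period_overlap,
)


def child(birth, interview, died=False, aod=None, **kw):
    row = dict(
        survey_id="s1", stratum="st1", cluster="c1", woman_id="w1",
        weight=1.0, interview_cmc=interview, birth_cmc=birth,
        died=died, age_at_death_months=aod, admin1="A",
    )
    row.update(kw)
    return row


def records_of(*rows):
    df = pd.DataFrame(rows)
    df["age_at_death_months"] = pd.array(df["age_at_death_months"], dtype="Int64")
    return df


class TestPeriodGrid:
    def test_514_anchor_dec_2018(self):
        grid = build_period_grid([cmc(2018, 12)], "5to14")
        assert grid.labels == ("2007-2010", "2011-2014", "2015-2018")

    def test_u5_six_periods(self):
        grid = build_period_grid([cmc(2018, 12)], "u5")
        assert grid.T == 6
        assert grid.labels[0] == "1995-1998"
        assert grid.labels[-1] == "2015-2018"

    def test_two_surveys_share_anchor(self):
        grid1 = build_period_grid([cmc(2018, 12)], "u5")
        grid2 = build_period_grid([cmc(2018, 12), cmc(2013, 6)], "u5")
        # same anchor; extra early periods may be added for the older survey
        assert grid2.breaks[-7:] == grid1.breaks
        assert set(grid1.labels) <= set(grid2.labels)

    def test_empty_survey_list_rejected(self):
        with pytest.raises(ValueError):
            build_period_grid([], "u5")

    def test_period_of(self):
        grid = build_period_grid([cmc(2018, 12)], "5to14")
        assert grid.period_of(cmc(2015, 1)) == 2
        assert grid.period_of(cmc(2014, 12)) == 1
        assert grid.period_of(cmc(2006, 12)) == -1


class TestPersonMonths:
    def test_death_at_three_months(self):
        grid = build_period_grid([cmc(2018, 12)], "u5")
        rec = records_of(child(cmc(2017, 1), cmc(2018, 12), died=True, aod=3))
        pm = expand_person_months(rec, grid, U5_SCHEME)
        assert pm["months"].sum() == 4  # months 0..3 incl. death month
        by_band = pm.groupby("age_band")[["months", "event"]].sum()
        assert by_band.loc[0, "months"] == 1 and by_band.loc[0, "event"] == 0
        assert by_band.loc[1, "months"] == 3 and by_band.loc[1, "event"] == 1

    def test_survivor_age_60(self):
        grid = build_period_grid([cmc(2018, 12)], "u5")
        rec = records_of(child(cmc(2013, 12), cmc(2018, 12)))  # 60 completed months
        pm = expand_person_months(rec, grid, U5_SCHEME)
        assert pm["months"].sum() == 60
        assert pm["event"].sum() == 0
        assert list(pm.groupby("age_band")["months"].sum()) == [1, 11, 12, 12, 12, 12]
        pm_old = expand_person_months(rec, grid, OLDER_SCHEME)
        assert pm_old["months"].sum() == 0

    def test_survivor_age_170(self):
        grid = build_period_grid([cmc(2018, 12)], "u5")  # wide calendar support
        rec = records_of(child(cmc(2018, 12) - 170, cmc(2018, 12)))
        pm = expand_person_months(rec, grid, OLDER_SCHEME)
        assert pm["months"].sum() == 110  # ages 60..169

    def test_interview_month_excluded(self):
        grid = build_period_grid([cmc(2018, 12)], "u5")
        rec = records_of(child(cmc(2018, 10), cmc(2018, 12)))  # 2 completed months
        pm = expand_person_months(rec, grid, U5_SCHEME)
        assert pm["months"].sum() == 2

    def test_outside_calendar_support_dropped(self):
        grid = build_period_grid([cmc(2018, 12)], "5to14")  # starts Jan 2007
        rec = records_of(child(cmc(1990, 1), cmc(2018, 12)))  # aged out before 2007
        # child is older than 180 months throughout the grid
        pm = expand_person_months(rec, grid, OLDER_SCHEME)
        assert pm["months"].sum() == 0


class TestBandFit:
    def test_saturated_closed_form(self):
        pm = pd.DataFrame(
            dict(
                survey_id="s", stratum=["h1"] * 1000, cluster=[f"c{i}" for i in range(1000)],
                woman_id="w", admin1="A", weight=1.0, period=0, age_band=0,
                months=1, event=[1, 1] + [0] * 998,
            )
        )
        scheme = ms.HazardSchedule(((0, 1),))
        fit = fit_band_logits(pm, scheme)
        assert fit.beta[0] == pytest.approx(np.log(0.002 / 0.998), abs=1e-12)

    def test_zero_events_non_estimable(self):
        pm = pd.DataFrame(
            dict(
                survey_id="s", stratum="h1", cluster=[f"c{i}" for i in range(50)],
                woman_id="w", admin1="A", weight=1.0, period=0, age_band=0,
                months=2, event=0,
            )
        )
        fit = fit_band_logits(pm, ms.HazardSchedule(((0, 1),)))
        assert not fit.estimable[0]
        est = combine_bands_to_q(fit, ms.HazardSchedule(((0, 1),)))
        assert est.status == "missing"

    def test_iid_design_matches_binomial_variance(self):
        # every person-month its own cluster in one stratum: the sandwich
        # reduces to the iid binomial-logistic variance up to n/(n-1)
        n, d = 20_000, 400
        pm = pd.DataFrame(
            dict(
                survey_id="s", stratum="h1", cluster=[f"c{i}" for i in range(n)],
                woman_id="w", admin1="A", weight=1.0, period=0, age_band=0,
                months=1, event=[1] * d + [0] * (n - d),
            )
        )
        fit = fit_band_logits(pm, ms.HazardSchedule(((0, 1),)))
        p = d / n
        model_var = 1.0 / (n * p * (1 - p))
        assert fit.cov[0, 0] == pytest.approx(model_var, rel=0.02)


class TestCombine:
    def test_uniform_monthly_q(self):
        m = 0.002
        beta = np.full(6, np.log(m / (1 - m)))
        fit = BandFit(beta, np.eye(6) * 1e-4, np.ones(6, bool), 10, 1000)
        est = combine_bands_to_q(fit, U5_SCHEME)
        assert est.q == pytest.approx(1 - (1 - m) ** 60, abs=1e-12)

    def test_older_block_value(self):
        m = 0.001
        beta = np.full(10, np.log(m / (1 - m)))
        fit = BandFit(beta, np.eye(10) * 1e-4, np.ones(10, bool), 10, 1000)
        est = combine_bands_to_q(fit, OLDER_SCHEME)
        assert est.q == pytest.approx(1 - 0.999**120, abs=1e-12)
        assert est.q == pytest.approx(0.1131, abs=5e-4)

    def test_single_band_identity(self):
        scheme = ms.HazardSchedule(((0, 1),))
        beta = np.array([-3.2])
        var = 0.07
        fit = BandFit(beta, np.array([[var]]), np.ones(1, bool), 5, 100)
        est = combine_bands_to_q(fit, scheme)
        assert est.logit_q == pytest.approx(-3.2, abs=1e-12)
        assert est.var_logit_q == pytest.approx(var, abs=1e-12)

    def test_delta_vs_monte_carlo(self, rng):
        beta = np.log(np.array([0.02, 0.004, 0.002, 0.0015, 0.001, 0.001]))
        a = rng.standard_normal((6, 6)) * 0.05
        cov = a @ a.T + np.eye(6) * 1e-4
        fit = BandFit(beta, cov, np.ones(6, bool), 50, 5000)
        est = combine_bands_to_q(fit, U5_SCHEME)
        draws = rng.multivariate_normal(beta, cov, size=20_000)
        p = 1 / (1 + np.exp(-draws))
        q = 1 - np.exp((U5_SCHEME.widths * np.log1p(-p)).sum(axis=1))
        mc_var = np.var(np.log(q / (1 - q)), ddof=1)
        assert est.var_logit_q == pytest.approx(mc_var, rel=0.10)


class TestEstimateDirect:
    def test_exposure_rule(self):
        grid = build_period_grid([cmc(2018, 12)], "5to14")
        # survey B ends 10 months into the last period -> 11 months overlap
        end_b = grid.breaks[2] + 10
        assert survey_period_overlap(grid, end_b)[2] == 11
        rec = records_of(
            child(cmc(2008, 1), cmc(2018, 12)),
            child(cmc(2008, 1), end_b, survey_id="s2", cluster="c2"),
        )
        est = estimate_direct(rec, grid, "5to14")
        cells = set(zip(est["survey_id"], est["period"]))
        assert ("s1", 2) in cells
        assert ("s2", 2) not in cells  # <= 12 months of exposure
        assert ("s2", 1) in cells  # full 48-month overlap

    def test_full_overlap_produces_estimate(self, survey_world):
        grid = build_period_grid([survey_world["interview"]], "u5")
        est = estimate_direct(survey_world["records"], grid, "u5")
        last = est[est["period"] == grid.T - 1]
        assert (last["status"] == "ok").any()

    def test_zero_children_missing(self):
        grid = build_period_grid([cmc(2018, 12)], "5to14")
        rec = records_of(
            child(cmc(2008, 1), cmc(2018, 12)),
            child(cmc(2018, 1), cmc(2018, 12), admin1="B", cluster="c9"),
        )
        est = estimate_direct(rec, grid, "5to14")
        b_cells = est[est["admin1"] == "B"]
        assert (b_cells["status"] == "missing").all()

    def test_weight_rescaling_invariance(self, survey_world):
        grid = build_period_grid([survey_world["interview"]], "u5")
        est1 = estimate_direct(survey_world["records"], grid, "u5")
        scaled = survey_world["records"].copy()
        scaled["weight"] = scaled["weight"] * 7.3
        est2 = estimate_direct(scaled, grid, "u5")
        ok = est1["status"] == "ok"
        assert (est2["status"] == "ok").equals(ok)
        np.testing.assert_allclose(
            est1.loc[ok, "logit_q"], est2.loc[ok, "logit_q"], rtol=1e-9
        )
        np.testing.assert_allclose(
            est1.loc[ok, "var_logit_q"], est2.loc[ok, "var_logit_q"], rtol=1e-9
        )


class TestRecovery:
    def test_large_sample_recovers_block_q(self):
        # single flat area: q-hat within 3 design SEs of generating block q
        graph = ms.generate_adjacency(2, "grid", 0)
        q_true = 0.08
        lam = np.log(q_true / (1 - q_true))
        surf = ms.TrueSurface(
            tuple(graph.nodes), lam, np.zeros(3), np.zeros(3),
            np.zeros(2), np.zeros(2), np.zeros((2, 3)),
        )
        surf_old = ms.TrueSurface(
            tuple(graph.nodes), -6.0, np.zeros(3), np.zeros(3),
            np.zeros(2), np.zeros(2), np.zeros((2, 3)),
        )
        breaks = [cmc(2018, 12) + 1 - 48 * k for k in range(3, -1, -1)]
        design = ms.default_design(
            graph.nodes, clusters_per_stratum=30, women_per_cluster=30,
            n_clusters_frame=70, seed=1,
        )
        rec = ms.simulate_survey(
            {"u5": surf, "5to14": surf_old}, design, breaks, cmc(2018, 12),
            fertility=0.025, seed=2,
        )
        grid = build_period_grid([cmc(2018, 12)], "u5")
        est = estimate_direct(rec, grid, "u5")
        last = est[(est["period"] == 5) & (est["status"] == "ok")]
        assert len(last) == 2
        for _, row in last.iterrows():
            z = (row["logit_q"] - lam) / np.sqrt(row["var_logit_q"])
            assert abs(z) < 3.0
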