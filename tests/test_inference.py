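"""OLS fit and sequential (Type I) ANOVA against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from rootpsf import FeedbackLinearModel, HOME_AWAY_TERMS, home_away_model, live_control_model
from rootpsf.exceptions import ConfigurationError, RankDeficiencyError
from rootpsf.inference import term_name


def random_geometry(n, seed, beta=None, noise=1.0):
    """Random midpoint/distance covariates with optional linear signal."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.standard_normal((n, 4)),
        columns=["coll_mid", "cons_mid", "coll_dist", "cons_dist"],
    )
    y = rng.standard_normal(n) * noise
    if beta:
        for col, b in beta.items():
            y = y + b * data[col]
    data["psf_value"] = y
    return data


def nested_rss_anova(data, terms, response="psf_value"):
    """Brute-force Type I SS: RSS drops across nested refits via lstsq."""
    y = data[response].to_numpy()
    n = len(y)

    def rss(active_terms):
        X = np.column_stack(
            [np.ones(n)]
            + [np.prod([data[c].to_numpy() for c in t], axis=0) for t in active_terms]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    out = []
    prev = rss([])
    for i in range(len(terms)):
        cur = rss(terms[: i + 1])
        out.append(prev - cur)
        prev = cur
    return np.array(out), prev  # term SS, residual SS


class TestOLSFit:
    def test_exact_linear_response_r2_one(self):
        data = random_geometry(30, 0, noise=0.0, beta={"coll_dist": 2.0})
        res = FeedbackLinearModel(data, "psf_value", [("coll_dist",)]).fit()
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.ssr == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_response_r2_zero(self):
        data = pd.DataFrame({"x": [-1.0, 1.0, -1.0, 1.0], "psf_value": [1.0, 1.0, -1.0, -1.0]})
        res = FeedbackLinearModel(data, "psf_value", [("x",)]).fit()
        assert res.rsquared == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_match_normal_equations(self):
        data = random_geometry(25, 3, beta={"coll_dist": 1.5, "cons_mid": -0.7})
        terms = [("coll_mid",), ("cons_mid",), ("coll_dist",)]
        res = FeedbackLinearModel(data, "psf_value", terms).fit()
        X = np.column_stack([np.ones(25)] + [data[t[0]] for t in terms])
        y = data["psf_value"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_adjusted_r2_formula(self):
        data = random_geometry(40, 5, beta={"coll_dist": 1.0})
        res = home_away_model(data).fit()
        n, p = res.nobs, res.df_model
        assert res.rsquared_adj == pytest.approx(
            1 - (1 - res.rsquared) * (n - 1) / (n - p - 1), abs=1e-12
        )

    def test_rank_deficiency_names_terms(self):
        data = random_geometry(30, 1)
        data["dup"] = data["coll_dist"]
        with pytest.raises(RankDeficiencyError, match="dup"):
            FeedbackLinearModel(data, "psf_value", [("coll_dist",), ("dup",)]).fit()

    def test_duplicated_rows_degenerate_input(self):
        one = random_geometry(1, 2)
        data = pd.concat([one] * 30, ignore_index=True)
        with pytest.raises(RankDeficiencyError):
            home_away_model(data).fit()


class TestSequentialAnova:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_model_matches_nested_refits(self, seed):
        data = random_geometry(40, seed, beta={"coll_dist": 0.8, "cons_dist": 0.8})
        res = home_away_model(data).fit()
        ss, rss = nested_rss_anova(data, HOME_AWAY_TERMS)
        got = res.anova.loc[[term_name(t) for t in HOME_AWAY_TERMS], "SumSq"].to_numpy()
        np.testing.assert_allclose(got, ss, rtol=1e-8, atol=1e-10)
        assert res.ssr == pytest.approx(rss, rel=1e-8)

    def test_decomposition_identity(self):
        data = random_geometry(60, 9, beta={"coll_mid": 1.0})
        res = home_away_model(data).fit()
        total = res.anova["SumSq"].sum()
        assert total == pytest.approx(res.ss_total, rel=1e-10)

    def test_orthogonal_covariates_order_independent(self):
        # balanced +-1 design: covariates exactly orthogonal and centered
        rows = [(a, b, a * b) for a in (-1.0, 1.0) for b in (-1.0, 1.0)] * 5
        data = pd.DataFrame(rows, columns=["coll_mid", "cons_mid", "coll_dist"])
        rng = np.random.default_rng(4)
        data["psf_value"] = (
            0.5 * data.coll_mid - 0.25 * data.cons_mid + rng.standard_normal(len(data))
        )
        terms = [("coll_mid",), ("cons_mid",), ("coll_dist",)]
        a = FeedbackLinearModel(data, "psf_value", terms).fit()
        b = FeedbackLinearModel(data, "psf_value", terms[::-1]).fit()
        for t in terms:
            assert a.anova.loc[term_name(t), "SumSq"] == pytest.approx(
                b.anova.loc[term_name(t), "SumSq"], rel=1e-10
            )

    def test_term_order_changes_ss_not_model_statistics(self):
        data = random_geometry(50, 12, beta={"coll_dist": 1.0})
        data["coll_mid"] += 0.8 * data["coll_dist"]  # induce correlation
        terms = [("coll_mid",), ("coll_dist",)]
        a = FeedbackLinearModel(data, "psf_value", terms).fit()
        b = FeedbackLinearModel(data, "psf_value", terms[::-1]).fit()
        assert a.anova.loc["coll_mid", "SumSq"] != pytest.approx(
            b.anova.loc["coll_mid", "SumSq"], rel=1e-3
        )
        assert a.ssr == pytest.approx(b.ssr, rel=1e-12)
        assert a.rsquared == pytest.approx(b.rsquared, rel=1e-12)
        assert a.fvalue == pytest.approx(b.fvalue, rel=1e-12)
        assert a.anova.loc["Residuals", "SumSq"] == pytest.approx(
            b.anova.loc["Residuals", "SumSq"], rel=1e-12
        )

    def test_pvalues_monotone_in_f(self):
        from scipy import stats

        f = np.linspace(0.1, 30, 50)
        p = stats.f.sf(f, 1, 45)
        assert (np.diff(p) < 0).all()

    def test_all_zero_response(self):
        data = random_geometry(40, 7, noise=0.0)
        data["psf_value"] = 0.0
        res = home_away_model(data).fit()
        assert res.anova["SumSq"].sum() == pytest.approx(0.0, abs=1e-20)
        assert res.rsquared == 0.0


class TestModelLayouts:
    def test_live_control_term_order(self):
        data = pd.DataFrame(
            {
                "collab": np.random.default_rng(0).standard_normal(20),
                "cons": np.random.default_rng(1).standard_normal(20),
            }
        )
        data["psf_value"] = data["collab"] * data["cons"]
        res = live_control_model(data).fit()
        assert list(res.anova.index) == ["collab", "cons", "collab:cons", "Residuals"]
        assert res.df_model == 3

    def test_live_control_needs_five_records(self):
        data = random_geometry(4, 0).rename(columns={"coll_mid": "collab", "cons_mid": "cons"})
        with pytest.raises(ConfigurationError):
            live_control_model(data)

    def test_home_away_layout_at_case_study_size(self):
        """61 records give the printed 15-term / 45-residual-df structure."""
        data = random_geometry(61, 21, beta={"coll_dist": 0.5})
        res = home_away_model(data).fit()
        assert res.df_model == 15
        assert res.df_resid == 45
        assert int(res.anova.loc["Residuals", "Df"]) == 45
        assert list(res.anova.index[:4]) == ["coll_mid", "cons_mid", "coll_dist", "cons_dist"]
        assert res.anova.index[-2] == "coll_mid:cons_mid:coll_dist:cons_dist"

    def test_distance_signal_lands_on_distance_terms(self):
        data = random_geometry(200, 3, beta={"coll_dist": 1.0, "cons_dist": 1.0},
                               noise=0.1)
        res = home_away_model(data).fit()
        dist_ss = res.anova.loc[["coll_dist", "cons_dist"], "SumSq"].sum()
        mid_ss = res.anova.loc[["coll_mid", "cons_mid"], "SumSq"].sum()
        assert dist_ss > 50 * mid_ss

    def test_summary_mentions_fit_statistics(self):
        data = random_geometry(61, 2, beta={"coll_dist": 0.5})
        text = home_away_model(data).fit().summary()
        assert "F_15,45" in text and "R2_adj" in text
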