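"""Linear feedback models with sequential (Type I) ANOVA tables.

Two models link feedbacks to root economics space:

* the **live/control model** regresses PSF_live/control on the focal
  species' own coordinates, ``psf ~ collab + cons + collab:cons``, where a
  significant interaction indicates that the four strategy quadrants have
  distinct net soil effects;
* the **home/away model** regresses PSF_home/away on the full factorial of
  pair midpoints and signed distances along the two axes,
  ``{coll_mid, cons_mid, coll_dist, cons_dist}`` up to the four-way
  interaction (15 single-df terms).

Both are ordinary least-squares fits summarized by a sequential ANOVA:
term i's sum of squares is the drop in residual SS when it is added after
terms 1..i-1, in a frozen term order, with every F computed against the full
model's residual mean square. Term order matters for correlated covariates,
so it is part of the model definition and recorded in the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError, RankDeficiencyError

#: frozen term order of the live/control model
LIVE_CONTROL_TERMS: list[tuple[str, ...]] = [
    ("collab",),
    ("cons",),
    ("collab", "cons"),
]

#: frozen term order of the home/away model: 4 mains, 6 two-way, 4 three-way
#: interactions, then the four-way term
HOME_AWAY_TERMS: list[tuple[str, ...]] = [
    ("coll_mid",),
    ("cons_mid",),
    ("coll_dist",),
    ("cons_dist",),
    ("coll_mid", "cons_mid"),
    ("coll_mid", "coll_dist"),
    ("coll_mid", "cons_dist"),
    ("cons_mid", "coll_dist"),
    ("cons_mid", "cons_dist"),
    ("coll_dist", "cons_dist"),
    ("coll_mid", "cons_mid", "coll_dist"),
    ("coll_mid", "cons_mid", "cons_dist"),
    ("cons_mid", "coll_dist", "cons_dist"),
    ("coll_mid", "coll_dist", "cons_dist"),
    ("coll_mid", "cons_mid", "coll_dist", "cons_dist"),
]


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class FeedbackLinearModel:
    """OLS model over an ordered list of (interaction) terms.

    Parameters
    ----------
    data : DataFrame with the response and every covariate column.
    response : name of the response column.
    terms : ordered list of tuples of covariate names; singletons are main
        effects, larger tuples are product (interaction) columns. The order
        is authoritative for the sequential ANOVA and no hierarchy is
        enforced.
    standardize : z-score the covariate columns before building the design
        (off by default; a sensitivity option).
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 terms: list[tuple[str, ...]], standardize: bool = False):
        if response not in data.columns:
            raise ConfigurationError(f"response column {response!r} not in data")
        names = [term_name(t) for t in terms]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate model terms")
        covariates = sorted({c for t in terms for c in t})
        missing = [c for c in covariates if c not in data.columns]
        if missing:
            raise ConfigurationError(f"covariate columns missing from data: {missing}")

        self.response = response
        self.terms = list(terms)
        self.term_names = names
        self.data = data.reset_index(drop=True)
        cov = self.data[covariates].astype(float)
        if standardize:
            cov = (cov - cov.mean()) / cov.std(ddof=1)
        self._cov = cov
        self.endog = self.data[response].to_numpy(dtype=float)

        n = len(self.data)
        X = np.empty((n, len(terms) + 1))
        X[:, 0] = 1.0
        for j, term in enumerate(terms, start=1):
            X[:, j] = np.prod([cov[c].to_numpy() for c in term], axis=0)
        self.exog = X
        self.exog_names = ["Intercept"] + names

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       terms: list[tuple[str, ...]], **kwargs) -> "FeedbackLinearModel":
        return cls(data, response, terms, **kwargs)

    def _check_rank(self) -> None:
        n, p = self.exog.shape
        if n <= p:
            raise RankDeficiencyError(
                f"{n} observations cannot identify {p} parameters"
            )
        # column-normalized QR so very different interaction scales do not
        # masquerade as rank deficiency
        norms = np.linalg.norm(self.exog, axis=0)
        if np.any(norms == 0):
            bad = np.flatnonzero(norms == 0)
            cols = [self.exog_names[i] for i in bad]
            raise RankDeficiencyError(f"all-zero design columns: {cols}")
        _, Rm = np.linalg.qr(self.exog / norms)
        diag = np.abs(np.diag(Rm))
        tol = max(n, p) * np.finfo(float).eps * 100
        bad = np.flatnonzero(diag < tol)
        if bad.size:
            cols = [self.exog_names[i] for i in bad]
            raise RankDeficiencyError(f"design matrix rank deficient; collinear terms: {cols}")

    def fit(self) -> "FeedbackResults":
        """Least-squares fit with the sequential variance decomposition."""
        self._check_rank()
        y = self.endog
        X = self.exog
        n, p_total = X.shape

        ols = sm.OLS(y, X).fit()

        # Type I (sequential) SS via QR: with single-df terms in design order,
        # each term's SS is the squared projection of y on the next
        # orthogonalized column.
        Q, _ = np.linalg.qr(X)
        effects = Q.T @ y
        ss_terms = effects[1:] ** 2
        rss = float(y @ y - effects @ effects)
        df_resid = n - p_total
        ms_resid = rss / df_resid
        tss = float(np.sum((y - y.mean()) ** 2))

        if ms_resid > 0:
            f_vals = ss_terms / ms_resid
            p_vals = stats.f.sf(f_vals, 1, df_resid)
        else:  # perfect fit: F undefined
            f_vals = np.full(ss_terms.shape, np.inf)
            p_vals = np.zeros(ss_terms.shape)

        anova = pd.DataFrame(
            {
                "Df": np.ones(len(self.terms), dtype=int),
                "SumSq": ss_terms,
                "MeanSq": ss_terms,
                "F": f_vals,
                "P": p_vals,
            },
            index=pd.Index(self.term_names, name="term"),
        )
        anova.loc["Residuals"] = [df_resid, rss, ms_resid, np.nan, np.nan]
        anova["Df"] = anova["Df"].astype(int)

        p = len(self.terms)
        rsquared = 1.0 - rss / tss if tss > 0 else 0.0
        rsquared_adj = 1.0 - (1.0 - rsquared) * (n - 1) / (n - p - 1)
        model_ss = float(ss_terms.sum())
        fvalue = (model_ss / p) / ms_resid if ms_resid > 0 else np.inf
        f_pvalue = float(stats.f.sf(fvalue, p, df_resid)) if np.isfinite(fvalue) else 0.0

        return FeedbackResults(
            model=self,
            params=pd.Series(ols.params, index=self.exog_names),
            bse=pd.Series(ols.bse, index=self.exog_names),
            fittedvalues=np.asarray(ols.fittedvalues),
            resid=np.asarray(ols.resid),
            anova=anova,
            nobs=n,
            df_model=p,
            df_resid=df_resid,
            ssr=rss,
            ss_total=tss,
            rsquared=rsquared,
            rsquared_adj=rsquared_adj,
            fvalue=float(fvalue),
            f_pvalue=f_pvalue,
        )


@dataclass
class FeedbackResults:
    """Results of a fitted feedback model.

    Carries the coefficient estimates with their standard errors, the
    sequential ANOVA table (one single-df row per term plus a residual row),
    and the usual whole-model statistics.
    """

    model: FeedbackLinearModel
    params: pd.Series
    bse: pd.Series
    fittedvalues: np.ndarray
    resid: np.ndarray
    anova: pd.DataFrame
    nobs: int
    df_model: int
    df_resid: int
    ssr: float
    ss_total: float
    rsquared: float
    rsquared_adj: float
    fvalue: float
    f_pvalue: float
    meta: dict = field(default_factory=dict)

    @property
    def formula(self) -> str:
        return f"{self.model.response} ~ " + " + ".join(self.model.term_names)

    def summary(self) -> str:
        lines = [
            "Feedback linear model (sequential ANOVA)",
            f"  {self.formula}",
            f"  n = {self.nobs}   F_{self.df_model},{self.df_resid} = {self.fvalue:.2f}"
            f"   R2 = {self.rsquared:.2f}   R2_adj = {self.rsquared_adj:.2f}",
            "",
        ]
        tab = self.anova.copy()
        tab["sig"] = [
            _stars(p) if np.isfinite(p) else "" for p in tab["P"].fillna(np.nan)
        ]
        with pd.option_context("display.float_format", "{:0.3f}".format):
            lines.append(tab.to_string())
        return "\n".join(lines)


def live_control_model(data: pd.DataFrame, response: str = "psf_value",
                       **kwargs) -> FeedbackLinearModel:
    """PSF_live/control ~ collab + cons + collab:cons on focal-species scores."""
    if len(data) < 5:
        raise ConfigurationError("live/control model needs at least 5 records")
    return FeedbackLinearModel(data, response, LIVE_CONTROL_TERMS, **kwargs)


def home_away_model(geometry: pd.DataFrame, response: str = "psf_value",
                    **kwargs) -> FeedbackLinearModel:
    """PSF_home/away ~ full midpoint x distance factorial (15 terms)."""
    if len(geometry) < len(HOME_AWAY_TERMS) + 2:
        raise ConfigurationError(
            f"home/away model needs at least {len(HOME_AWAY_TERMS) + 2} records"
        )
    return FeedbackLinearModel(geometry, response, HOME_AWAY_TERMS, **kwargs)
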