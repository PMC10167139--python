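"""Plant-soil feedback (PSF) metrics from replicate-level pot biomass.

A conditioning (training) phase lets each species culture its own soil
community; the response phase then measures growth of a focal species on
soil conditioned by itself ("home", performance ``alpha``), by another
species ("away", ``beta``), or on a sterilized/unconditioned control
(``gamma``). Three standard contrasts are computed from those
cell-level performances:

* ``PSF_home/away  = alpha_A - beta_A``
* ``PSF_pairwise   = alpha_A - alpha_B - beta_A + beta_B``
* ``PSF_live/control = alpha_A - gamma_A``

Performance is, by default, the mean of the natural log of replicate
biomass, so every metric is a log response ratio and is invariant to
rescaling biomass units.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ExperimentDataError, MissingCellError

logger = logging.getLogger(__name__)

#: soil_species tokens that mark a control (unconditioned / sterilized) pot
CONTROL_TOKENS = frozenset({"STERILE", "UNCONDITIONED"})

#: token used for the conditioner of pooled-away records
POOLED_TOKEN = "POOLED"

EXPERIMENT_COLUMNS = ["focal_species", "soil_species", "treatment", "replicate", "biomass_g"]

METRICS = ("home_away", "pairwise", "live_control")


@dataclass(frozen=True)
class FeedbackThresholds:
    """Cut points for categorizing a feedback value.

    ``neutral_halfwidth`` is the half-width of the neutral band around zero
    and ``strong_cut`` the (negative) cut below which a feedback counts as
    strongly negative; both are in log-response-ratio units.
    """

    neutral_halfwidth: float = 0.1
    strong_cut: float = -0.5

    def __post_init__(self) -> None:
        if self.neutral_halfwidth < 0:
            raise ConfigurationError("neutral_halfwidth must be >= 0")
        if not self.strong_cut < -self.neutral_halfwidth:
            raise ConfigurationError(
                "strong_cut must be < -neutral_halfwidth "
                f"(got strong_cut={self.strong_cut}, neutral_halfwidth={self.neutral_halfwidth})"
            )


def validate_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a replicate-level experiment table.

    Requires columns ``focal_species, soil_species, treatment, replicate,
    biomass_g``; every biomass strictly positive; the
    (focal, soil, treatment, replicate) key unique; treatment in
    {live, sterile}.  Returns the table with key columns as strings.
    """
    missing = [c for c in EXPERIMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ExperimentDataError(f"experiment table is missing columns: {missing}")
    table = table.copy()
    for col in ("focal_species", "soil_species", "treatment"):
        table[col] = table[col].astype(str)

    bad_treat = sorted(set(table["treatment"]) - {"live", "sterile"})
    if bad_treat:
        raise ExperimentDataError(f"unknown treatment values: {bad_treat}")

    biomass = pd.to_numeric(table["biomass_g"], errors="coerce")
    bad = table.index[~(biomass > 0) | biomass.isna()]
    if len(bad):
        raise ExperimentDataError(
            f"non-positive or missing biomass in rows {list(bad[:10])}; "
            "plants with zero/negative mass must be pre-excluded"
        )
    table["biomass_g"] = biomass.astype(float)

    key = ["focal_species", "soil_species", "treatment", "replicate"]
    dup = table.duplicated(subset=key)
    if dup.any():
        raise ExperimentDataError(
            f"duplicate (focal, soil, treatment, replicate) keys in rows {list(table.index[dup][:10])}"
        )
    return table


def performance(biomass_replicates, transform: str = "log") -> float:
    """Cell-level performance: mean of (optionally log-) transformed biomass."""
    values = np.asarray(list(biomass_replicates), dtype=float)
    if values.size == 0:
        raise MissingCellError("empty replicate list: no plants in this cell")
    if transform not in ("log", "identity"):
        raise ConfigurationError(f"unknown transform {transform!r}")
    if np.any(~(values > 0)):
        idx = int(np.flatnonzero(~(values > 0))[0])
        raise ExperimentDataError(f"non-positive biomass {values[idx]} at replicate index {idx}")
    if transform == "log":
        values = np.log(values)
    return float(values.mean())


def _check_finite(**named) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ExperimentDataError(f"{name} must be finite, got {value}")


def psf_home_away(alpha_A: float, beta_A: float) -> float:
    """Home/away feedback: performance on conspecific minus heterospecific soil."""
    _check_finite(alpha_A=alpha_A, beta_A=beta_A)
    return alpha_A - beta_A


def psf_pairwise(alpha_A: float, alpha_B: float, beta_A: float, beta_B: float) -> float:
    """Pairwise (reciprocal) feedback ``alpha_A - alpha_B - beta_A + beta_B``.

    Equals ``psf_home_away(alpha_A, beta_A) + psf_home_away(beta_B, alpha_B)``;
    positive values indicate both species do relatively better at home, which
    links to stabilising coexistence in two-species feedback theory.
    """
    _check_finite(alpha_A=alpha_A, alpha_B=alpha_B, beta_A=beta_A, beta_B=beta_B)
    return alpha_A - alpha_B - beta_A + beta_B


def psf_live_control(alpha_A: float, gamma_A: float) -> float:
    """Live/control feedback: conspecific live soil vs sterile/unconditioned soil."""
    _check_finite(alpha_A=alpha_A, gamma_A=gamma_A)
    return alpha_A - gamma_A


def classify_feedback(value: float, thresholds: FeedbackThresholds | None = None) -> str:
    """Categorize a feedback value into one of four bins.

    ``strong_negative`` below ``strong_cut``; ``negative`` between
    ``strong_cut`` and the neutral band; ``neutral`` within
    ``[-neutral_halfwidth, +neutral_halfwidth]``; ``positive`` above it.
    Exactly one category applies to every real value.
    """
    t = thresholds or FeedbackThresholds()
    if value <= t.strong_cut:
        return "strong_negative"
    if value < -t.neutral_halfwidth:
        return "negative"
    if value <= t.neutral_halfwidth:
        return "neutral"
    return "positive"


@dataclass
class PSFTable:
    """Feedback records plus run metadata (thresholds, transform, skips)."""

    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.records)


def _cell_means(table: pd.DataFrame, transform: str) -> pd.DataFrame:
    """Per (focal, soil, treatment) performance and replicate count."""
    grouped = table.groupby(["focal_species", "soil_species", "treatment"])["biomass_g"]
    out = grouped.agg(
        performance=lambda v: performance(v, transform=transform),
        n="size",
    ).reset_index()
    return out


class _Cells:
    """Lookup helper over cell-level performances."""

    def __init__(self, cells: pd.DataFrame):
        self._map = {
            (r.focal_species, r.soil_species, r.treatment): (r.performance, int(r.n))
            for r in cells.itertuples()
        }
        self.cells = cells

    def get(self, focal: str, soil: str, treatment: str = "live"):
        return self._map.get((focal, soil, treatment))

    def control(self, focal: str):
        """Control cell: sterile treatment or a control soil token, pooled."""
        rows = self.cells[
            (self.cells.focal_species == focal)
            & (
                (self.cells.treatment == "sterile")
                | (self.cells.soil_species.isin(CONTROL_TOKENS))
            )
        ]
        if rows.empty:
            return None
        perf = float(np.average(rows.performance, weights=rows.n))
        return perf, int(rows.n.sum())

    def live_conditioners(self, focal: str):
        rows = self.cells[
            (self.cells.focal_species == focal)
            & (self.cells.treatment == "live")
            & (~self.cells.soil_species.isin(CONTROL_TOKENS))
        ]
        return list(rows.soil_species)


def compute_psf_table(
    table: pd.DataFrame,
    metric: str,
    pool_away: bool = False,
    transform: str = "log",
    thresholds: FeedbackThresholds | None = None,
) -> PSFTable:
    """Compute feedback records of one metric from a replicate-level table.

    For ``home_away`` one record is produced per focal x conditioning species
    (or one per focal with performances averaged across away soils when
    ``pool_away``); for ``live_control`` one per focal against its pooled
    control cells; for ``pairwise`` one per unordered species pair with
    reciprocal cells.  Combinations with a missing required cell are skipped
    with a logged warning; skip counts appear in the returned metadata.
    """
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    thresholds = thresholds or FeedbackThresholds()
    table = validate_experiment(table)
    cells = _Cells(_cell_means(table, transform))

    focals = sorted(table["focal_species"].unique())
    records: list[dict] = []
    skipped: list[str] = []

    def add(focal, conditioner, value, n):
        records.append(
            {
                "focal": focal,
                "conditioner": conditioner,
                "metric": metric,
                "value": value,
                "category": classify_feedback(value, thresholds),
                "n_replicates": n,
            }
        )

    if metric == "home_away":
        for focal in focals:
            home = cells.get(focal, focal)
            aways = [c for c in cells.live_conditioners(focal) if c != focal]
            if home is None or not aways:
                skipped.append(f"{focal}: missing home or away live cell")
                continue
            if pool_away:
                perfs = [cells.get(focal, a) for a in aways]
                beta = float(np.mean([p for p, _ in perfs]))
                n = home[1] + sum(n for _, n in perfs)
                add(focal, POOLED_TOKEN, psf_home_away(home[0], beta), n)
            else:
                for away in aways:
                    beta, n_b = cells.get(focal, away)
                    add(focal, away, psf_home_away(home[0], beta), home[1] + n_b)
    elif metric == "live_control":
        for focal in focals:
            home = cells.get(focal, focal)
            ctrl = cells.control(focal)
            if home is None or ctrl is None:
                skipped.append(f"{focal}: missing home live or control cell")
                continue
            add(focal, "CONTROL", psf_live_control(home[0], ctrl[0]), home[1] + ctrl[1])
    else:  # pairwise
        for a, b in itertools.combinations(focals, 2):
            quad = [cells.get(a, a), cells.get(b, b), cells.get(a, b), cells.get(b, a)]
            if any(q is None for q in quad):
                skipped.append(f"({a},{b}): missing reciprocal cell")
                continue
            (aa, n1), (ab, n2), (ba, n3), (bb, n4) = quad
            value = psf_pairwise(aa, ab, ba, bb)
            records.append(
                {
                    "focal": a,
                    "conditioner": b,
                    "metric": metric,
                    "value": value,
                    "category": classify_feedback(value, thresholds),
                    "n_replicates": n1 + n2 + n3 + n4,
                }
            )

    for msg in skipped:
        logger.warning("skipping %s record: %s", metric, msg)

    columns = ["focal", "conditioner", "metric", "value", "category", "n_replicates"]
    meta = {
        "metric": metric,
        "transform": transform,
        "pool_away": pool_away,
        "neutral_halfwidth": thresholds.neutral_halfwidth,
        "strong_cut": thresholds.strong_cut,
        "n_records": len(records),
        "n_skipped": len(skipped),
        "skipped": skipped,
    }
    return PSFTable(pd.DataFrame(records, columns=columns), meta)
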