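"""Generative soil-effect model linking root economics space to feedbacks.

The framework posits that where a species sits in root economics space
determines the soil community it cultures: species toward the outsourcer
pole (negative collab) accumulate mycorrhizal mutualists in their home soil,
and species toward the fast pole (positive cons) accumulate pathogens.
Growth of a focal plant on a conditioned soil then reflects the balance of
mutualist benefit and pathogen cost:

    soil_effect(focal, conditioner) =
        m * (1 + receptivity_slope * (-focal.collab))_+ * mutualist_load(conditioner)
      - p * (1 + susceptibility_slope * focal.cons)_+ * pathogen_load(conditioner)

with linear loads ``mutualist_load = -kappa * conditioner.collab`` and
``pathogen_load = lambda_ * conditioner.cons`` and the modifier factors
floored at zero. The symmetric generalist baseline
(m = p = kappa = lambda_ = 1, both slopes 0) makes mutualist and pathogen
effects balance, so the home/away feedback depends only on the signed
away-minus-home distances:

    PSF_home/away = m*kappa*(away.collab - home.collab)
                  + p*lambda*(away.cons  - home.cons)

Nonzero receptivity/susceptibility slopes break this symmetry — e.g. DIY
species that cannot benefit from mycorrhizae, or fast species more tolerant
of pathogen attack — and introduce dependence on where the pair sits
(midpoints), not just how far apart it is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from .exceptions import ConfigurationError


class Position(NamedTuple):
    """Location in oriented root economics space.

    collab: positive = DIY pole; cons: positive = fast pole.
    """

    collab: float
    cons: float


#: unit-corner anchor positions of the four belowground strategies
STRATEGY_CORNERS = {
    "OS": Position(-1.0, -1.0),  # outsourcer-slow
    "OF": Position(-1.0, +1.0),  # outsourcer-fast
    "DS": Position(+1.0, -1.0),  # DIY-slow
    "DF": Position(+1.0, +1.0),  # DIY-fast
}


@dataclass(frozen=True)
class FrameworkParams:
    """Coefficients of the generative soil-effect model.

    m, p : mutualist benefit / pathogen cost per unit load (>= 0).
    kappa, lambda_ : load accumulation slopes along the collaboration /
        conservation axis of the conditioning species (>= 0).
    receptivity_slope : how much less a DIY focal benefits from mutualists
        (0 = fully generalist mutualists).
    susceptibility_slope : how much more a fast focal suffers from pathogens
        (0 = fully generalist pathogens).
    neutral_eps : half-width for categorizing predictions as neutral.
    """

    m: float = 1.0
    p: float = 1.0
    kappa: float = 1.0
    lambda_: float = 1.0
    receptivity_slope: float = 0.0
    susceptibility_slope: float = 0.0
    neutral_eps: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("m", "p", "kappa", "lambda_", "receptivity_slope",
                     "susceptibility_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.neutral_eps <= 0:
            raise ConfigurationError("neutral_eps must be > 0")


BASELINE = FrameworkParams()


class Prediction(NamedTuple):
    value: float
    category: str


def _categorize(value: float, eps: float) -> str:
    if value > eps:
        return "positive"
    if value < -eps:
        return "negative"
    return "neutral"


def mutualist_load(conditioner: Position, params: FrameworkParams = BASELINE) -> float:
    """Mutualist abundance cultured in the conditioner's home soil.

    Increases linearly toward the outsourcer (negative collab) pole.
    """
    return -params.kappa * conditioner.collab


def pathogen_load(conditioner: Position, params: FrameworkParams = BASELINE) -> float:
    """Pathogen abundance cultured in the conditioner's home soil.

    Increases linearly toward the fast (positive cons) pole.
    """
    return params.lambda_ * conditioner.cons


def soil_effect(focal: Position, conditioner: Position,
                params: FrameworkParams = BASELINE) -> float:
    """Net effect of a conditioned soil community on the focal's log growth."""
    receptivity = max(0.0, 1.0 + params.receptivity_slope * (-focal.collab))
    susceptibility = max(0.0, 1.0 + params.susceptibility_slope * focal.cons)
    return (params.m * receptivity * mutualist_load(conditioner, params)
            - params.p * susceptibility * pathogen_load(conditioner, params))


def predict_live_control(pos: Position, params: FrameworkParams = BASELINE) -> Prediction:
    """Expected PSF_live/control for a species conditioning its own soil."""
    value = soil_effect(pos, pos, params)
    return Prediction(value, _categorize(value, params.neutral_eps))


def predict_home_away(home: Position, away: Position,
                      params: FrameworkParams = BASELINE) -> Prediction:
    """Expected PSF_home/away of the home species against one away soil.

    Under the generalist baseline this reduces to
    ``m*kappa*(away.collab - home.collab) + p*lambda*(away.cons - home.cons)``:
    positive signed distances (away higher up either axis) give more positive
    feedback — the plant loses mutualists or gains pathogens in the away soil
    and therefore does relatively better at home.
    """
    value = soil_effect(home, home, params) - soil_effect(home, away, params)
    return Prediction(value, _categorize(value, params.neutral_eps))


def predict_pairwise(A: Position, B: Position,
                     params: FrameworkParams = BASELINE) -> Prediction:
    """Expected PSF_pairwise; the sum of the two reciprocal home/away feedbacks.

    Symmetric in its arguments. Under the fully generalist baseline the
    reciprocal terms cancel exactly, so every pairwise prediction is neutral —
    a model-implied property of the symmetry assumption, broken as soon as
    receptivity/susceptibility asymmetries are switched on.
    """
    value = predict_home_away(A, B, params).value + predict_home_away(B, A, params).value
    return Prediction(value, _categorize(value, params.neutral_eps))


def enumerate_strategy_feedbacks(params: FrameworkParams = BASELINE) -> pd.DataFrame:
    """Predictions for the four strategies at their unit corners.

    Returns a 22-row table: 4 live/control predictions (one per strategy),
    12 ordered home/away comparisons and 6 unordered pairwise comparisons,
    with columns ``comparison, metric, value, category``.
    """
    rows = []
    names = list(STRATEGY_CORNERS)
    for s in names:
        pred = predict_live_control(STRATEGY_CORNERS[s], params)
        rows.append({"comparison": s, "metric": "live_control", **pred._asdict()})
    for home, away in itertools.permutations(names, 2):
        pred = predict_home_away(STRATEGY_CORNERS[home], STRATEGY_CORNERS[away], params)
        rows.append({"comparison": f"{home}->{away}", "metric": "home_away",
                     **pred._asdict()})
    for a, b in itertools.combinations(names, 2):
        pred = predict_pairwise(STRATEGY_CORNERS[a], STRATEGY_CORNERS[b], params)
        rows.append({"comparison": f"{a}-{b}", "metric": "pairwise", **pred._asdict()})
    return pd.DataFrame(rows, columns=["comparison", "metric", "value", "category"])
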