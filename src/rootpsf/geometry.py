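"""Signed trait distances and midpoints for species pairs.

For each home/away feedback record the comparison is located in root
economics space by the signed distance ``away - home`` and the pair midpoint
``(home + away) / 2`` along each axis. Signed (not absolute) distances are
used because the direction of the comparison carries the prediction: moving
up an axis from home to away soil means losing mutualists (collaboration) or
gaining pathogens (conservation). Midpoints rather than home positions
capture where in the space the pair sits, since the home position is
algebraically confounded with the distance (home = midpoint - distance/2).
"""

from __future__ import annotations

import logging

import pandas as pd

from .exceptions import ConfigurationError, ExperimentDataError
from .metrics import POOLED_TOKEN, PSFTable
from .trait_space import RootEconomicsSpace

logger = logging.getLogger(__name__)

GEOMETRY_COLUMNS = ["focal", "conditioner", "psf_value",
                    "coll_dist", "cons_dist", "coll_mid", "cons_mid", "source"]


def signed_distance(space: RootEconomicsSpace, home: str, away: str, axis: str) -> float:
    """Away-minus-home coordinate difference along one oriented axis."""
    return space.score(away, axis) - space.score(home, axis)


def midpoint(space: RootEconomicsSpace, home: str, away: str, axis: str) -> float:
    """Mean coordinate of the pair along one oriented axis (symmetric)."""
    return 0.5 * (space.score(home, axis) + space.score(away, axis))


def build_analysis_table(psf, space: RootEconomicsSpace,
                         source: str = "") -> pd.DataFrame:
    """Join home/away feedback records to their pair geometry.

    One output row per record with both signed distances, both midpoints and
    the feedback value. Records whose focal or conditioner lacks a score are
    dropped with a logged warning; the drop count is stored in
    ``result.attrs["n_dropped"]``. Pooled-away records have no single away
    position and are rejected.
    """
    records = psf.records if isinstance(psf, PSFTable) else psf
    if "metric" in records.columns:
        non_ha = records[records["metric"] != "home_away"]
        if len(non_ha):
            raise ConfigurationError(
                "geometry table requires home_away records; got metrics "
                f"{sorted(non_ha['metric'].unique())}"
            )
    if (records["conditioner"] == POOLED_TOKEN).any():
        raise ConfigurationError(
            "pooled-away records have no single away position in trait space; "
            "recompute the PSF table with pool_away=False"
        )

    scored = set(space.scores.index)
    rows, dropped = [], 0
    for rec in records.itertuples():
        if rec.focal not in scored or rec.conditioner not in scored:
            dropped += 1
            continue
        rows.append({
            "focal": rec.focal,
            "conditioner": rec.conditioner,
            "psf_value": rec.value,
            "coll_dist": signed_distance(space, rec.focal, rec.conditioner, "collab"),
            "cons_dist": signed_distance(space, rec.focal, rec.conditioner, "cons"),
            "coll_mid": midpoint(space, rec.focal, rec.conditioner, "collab"),
            "cons_mid": midpoint(space, rec.focal, rec.conditioner, "cons"),
            "source": getattr(rec, "source", source),
        })
    if dropped:
        logger.warning("dropped %d feedback records lacking trait-space scores", dropped)
    if not rows:
        raise ExperimentDataError("empty geometry table: no record joined to a scored pair")
    table = pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)
    table.attrs["n_dropped"] = dropped
    return table


def build_live_control_table(psf, space: RootEconomicsSpace) -> pd.DataFrame:
    """Join live/control feedback records to the focal species' own scores."""
    records = psf.records if isinstance(psf, PSFTable) else psf
    scored = set(space.scores.index)
    rows, dropped = [], 0
    for rec in records.itertuples():
        if rec.focal not in scored:
            dropped += 1
            continue
        rows.append({
            "focal": rec.focal,
            "psf_value": rec.value,
            "collab": space.score(rec.focal, "collab"),
            "cons": space.score(rec.focal, "cons"),
        })
    if dropped:
        logger.warning("dropped %d live/control records lacking trait-space scores", dropped)
    if not rows:
        raise ExperimentDataError("empty live/control table after join")
    table = pd.DataFrame(rows, columns=["focal", "psf_value", "collab", "cons"])
    table.attrs["n_dropped"] = dropped
    return table
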