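"""File interfaces and the pipeline driver.

CSV for tables, Newick for trees, TOML for run configuration and JSON for
run metadata. Every pipeline output directory embeds the configuration and
seed that produced it, so a rerun regenerates byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, ExperimentDataError
from .framework import FrameworkParams, enumerate_strategy_feedbacks
from .geometry import build_analysis_table, build_live_control_table
from .inference import home_away_model, live_control_model
from .metrics import FeedbackThresholds, compute_psf_table, validate_experiment
from .phylo import normalize_label, read_newick, write_newick
from .trait_space import PhyloPCA

logger = logging.getLogger(__name__)

TRAIT_CSV_COLUMNS = {
    "species": "species",
    "SRL_m_per_g": "SRL",
    "D_mm": "D",
    "RTD_g_per_cm3": "RTD",
    "N_mg_per_g": "N",
}


def read_traits(path) -> pd.DataFrame:
    """Read a species x root-trait CSV.

    Expected header: ``species,SRL_m_per_g,D_mm,RTD_g_per_cm3,N_mg_per_g``.
    Missing, non-numeric or non-positive entries are errors naming the
    offending rows; duplicate species are errors.
    """
    raw = pd.read_csv(path)
    missing = [c for c in TRAIT_CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ExperimentDataError(f"{path}: missing columns {missing}")
    raw = raw.rename(columns=TRAIT_CSV_COLUMNS)
    raw["species"] = raw["species"].map(normalize_label)
    dup = raw["species"].duplicated()
    if dup.any():
        raise ExperimentDataError(
            f"{path}: duplicate species at rows {list(raw.index[dup] + 2)}"
        )
    values = raw[["SRL", "D", "RTD", "N"]].apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | (values <= 0)
    if bad.any().any():
        rows = list(raw.index[bad.any(axis=1)] + 2)  # 1-based incl. header
        raise ExperimentDataError(
            f"{path}: missing/non-positive trait values at rows {rows}"
        )
    values.index = pd.Index(raw["species"], name="species")
    return values.astype(float)


def read_experiment(path) -> pd.DataFrame:
    """Read and validate a replicate-level pot-biomass CSV."""
    return validate_experiment(pd.read_csv(path))


def write_space(space, out_dir: Path) -> None:
    scores = space.scores[["collab", "cons"]].copy()
    scores["strategy"] = space.strategies["strategy"]
    scores.to_csv(out_dir / "scores.csv", float_format="%.10g")
    space.loadings.to_csv(out_dir / "loadings.csv", float_format="%.10g")


def write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    traits: str
    tree: str | None
    experiment: str
    out_dir: str
    metric: str = "home_away"
    pool_away: bool = False
    transform: str = "log"
    neutral_halfwidth: float = 0.1
    strong_cut: float = -0.5
    mode: str = "correlation"
    star_fallback: bool = False
    standardize: bool = False
    seed: int = 0
    source: str = ""

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"invalid config: {exc}") from exc

    def validate(self) -> None:
        for name in ("traits", "experiment"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p!r}")
        if self.tree and not Path(self.tree).exists():
            raise ConfigurationError(f"tree path does not exist: {self.tree!r}")


def setup_logging(out_dir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def run_pipeline(config: RunConfig) -> Path:
    """Run trait space -> PSF -> geometry -> model fits and write artifacts.

    Writes scores/loadings, the per-metric feedback tables, the geometry
    table, both ANOVA tables (where the data allow), the strategy-level
    framework predictions and a JSON metadata file embedding the
    configuration, seed and package version.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir)
    meta: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stages": {},
    }
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %s", name)
        meta["stages"][name] = round(time.perf_counter() - t0, 3)

    try:
        stage("space")
        tree = read_newick(config.tree) if config.tree else None
        traits = read_traits(config.traits)
        space = PhyloPCA(traits, tree, mode=config.mode,
                         star_fallback=config.star_fallback).fit()
        write_space(space, out_dir)
        meta["variance_explained"] = space.variance_explained.round(6).to_dict()
        meta["reflections"] = space.reflections

        stage("psf")
        experiment = read_experiment(config.experiment)
        thresholds = FeedbackThresholds(config.neutral_halfwidth, config.strong_cut)
        tables = {}
        for metric in ("home_away", "live_control"):
            tab = compute_psf_table(experiment, metric=metric,
                                    pool_away=config.pool_away and metric == "home_away",
                                    transform=config.transform, thresholds=thresholds)
            tab.records.to_csv(out_dir / f"psf_{metric}.csv", index=False,
                               float_format="%.10g")
            meta[f"psf_{metric}"] = {k: v for k, v in tab.meta.items() if k != "skipped"}
            tables[metric] = tab

        stage("geometry")
        geometry = build_analysis_table(tables["home_away"], space, source=config.source)
        geometry.to_csv(out_dir / "geometry.csv", index=False, float_format="%.10g")
        meta["geometry"] = {"n_records": len(geometry),
                            "n_dropped": geometry.attrs["n_dropped"]}

        stage("fit")
        try:
            ha_fit = home_away_model(geometry, standardize=config.standardize).fit()
            ha_fit.anova.to_csv(out_dir / "anova_home_away.csv", float_format="%.10g")
            meta["home_away_model"] = {
                "formula": ha_fit.formula, "n": ha_fit.nobs,
                "rsquared": ha_fit.rsquared, "rsquared_adj": ha_fit.rsquared_adj,
                "F": ha_fit.fvalue, "df": [ha_fit.df_model, ha_fit.df_resid],
            }
        except ConfigurationError as exc:
            logger.warning("home/away model not fitted: %s", exc)
            meta["home_away_model"] = {"skipped": str(exc)}
        try:
            lc_table = build_live_control_table(tables["live_control"], space)
            lc_fit = live_control_model(lc_table, standardize=config.standardize).fit()
            lc_fit.anova.to_csv(out_dir / "anova_live_control.csv", float_format="%.10g")
            meta["live_control_model"] = {
                "formula": lc_fit.formula, "n": lc_fit.nobs,
                "rsquared": lc_fit.rsquared, "rsquared_adj": lc_fit.rsquared_adj,
                "F": lc_fit.fvalue, "df": [lc_fit.df_model, lc_fit.df_resid],
            }
        except (ConfigurationError, ExperimentDataError) as exc:
            logger.warning("live/control model not fitted: %s", exc)
            meta["live_control_model"] = {"skipped": str(exc)}

        stage("predict")
        enumerate_strategy_feedbacks().to_csv(out_dir / "predictions.csv", index=False,
                                              float_format="%.10g")
    except Exception as exc:
        failed = [s for s in meta["stages"]][-1] if meta["stages"] else "setup"
        raise type(exc)(f"[stage {failed}] {exc}") from exc

    write_json(meta, out_dir / "metadata.json")
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return out_dir


def write_simulation(config, out_dir) -> Path:
    """Simulate a full study and write traits, tree, experiment and truth."""
    from .simulate import simulate_experiment, simulate_traits, simulate_tree
    import numpy as np

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, rng)
    traits, latents = simulate_traits(tree, config, rng)
    experiment = simulate_experiment(latents, config, rng)

    inv = {v: k for k, v in TRAIT_CSV_COLUMNS.items() if v != "species"}
    traits.rename(columns=inv).to_csv(out_dir / "traits.csv", float_format="%.10g")
    write_newick(tree, out_dir / "tree.nwk")
    experiment.to_csv(out_dir / "experiment.csv", index=False, float_format="%.10g")
    write_json(
        {
            "config": dataclasses.asdict(config),
            "latents": latents.round(10).to_dict(orient="index"),
        },
        out_dir / "truth.json",
    )
    return out_dir
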