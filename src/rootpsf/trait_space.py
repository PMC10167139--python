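"""Root economics space via phylogenetically informed PCA.

The four core fine-root traits — specific root length (SRL, m g^-1), mean
root diameter (D, mm), root tissue density (RTD, g cm^-3) and root nitrogen
concentration (N, mg g^-1) — span two largely independent gradients:

* a **collaboration** gradient from "outsourcing" species with thick,
  mycorrhiza-reliant roots (high D) to "do-it-yourself" (DIY) species that
  forage with long thin roots (high SRL), and
* a **conservation** gradient from "fast" nutrient-acquisitive roots
  (high N) to "slow" well-defended roots (high RTD).

The PCA is computed under a Brownian-motion model of trait evolution: the
species mean is a generalized-least-squares (GLS) mean weighted by the
inverse phylogenetic covariance C, and the evolutionary (co)variance of the
ln-traits is ``R = (X - 1a)' C^-1 (X - 1a) / (n - 1)``, standardized to a
correlation matrix by default. Eigendecomposition of R gives the axes;
scores are projections of the (standardized) centered traits.

Axes are oriented to a fixed convention: positive PC1 ("collab") points to
the DIY pole (SRL loads positively) and positive PC2 ("cons") to the fast
pole (N loads positively). Each species then falls in one of four strategy
quadrants: outsourcer-slow (OS), outsourcer-fast (OF), DIY-slow (DS),
DIY-fast (DF).

Example
-------
>>> space = PhyloPCA(traits, tree).fit()
>>> space.scores.head()
>>> space.variance_explained
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .exceptions import (
    ConfigurationError,
    ExperimentDataError,
    OrientationError,
    SingularCovarianceError,
    TreeMismatchError,
)
from .phylo import normalize_label, phylo_vcv, prune_tree, tip_labels

TRAIT_COLUMNS = ["SRL", "D", "RTD", "N"]

#: (trait, axis) anchors defining the sign convention of the oriented space
ORIENTATION_ANCHORS = {"collab": "SRL", "cons": "N"}

STRATEGIES = ("OS", "OF", "DS", "DF")


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Check a species x trait table: four complete, strictly positive traits."""
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ExperimentDataError(f"trait table is missing columns: {missing}")
    traits = traits[TRAIT_COLUMNS].copy()
    traits.index = [normalize_label(s) for s in traits.index]
    if traits.index.duplicated().any():
        dups = sorted(set(traits.index[traits.index.duplicated()]))
        raise ExperimentDataError(f"duplicate species in trait table: {dups}")
    values = traits.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | (values <= 0)
    if bad.any().any():
        rows = sorted(set(values.index[bad.any(axis=1)]))
        raise ExperimentDataError(
            f"traits must be strictly positive and complete; offending species: {rows}"
        )
    return values.astype(float)


def assign_strategy(collab: float, cons: float) -> tuple[str, bool]:
    """Strategy quadrant of an oriented score pair.

    Positive collab = DIY pole, positive cons = fast pole. Scores lying
    exactly on an axis are assigned to the slow/outsourcer side and flagged
    as boundary ties.
    """
    boundary = collab == 0 or cons == 0
    if collab > 0:
        strategy = "DF" if cons > 0 else "DS"
    else:
        strategy = "OF" if cons > 0 else "OS"
    return strategy, boundary


@dataclass
class RootEconomicsSpace:
    """Oriented two-axis root economics space (phylo-PCA results).

    Attributes
    ----------
    scores : DataFrame
        Species x axis coordinates; the first two axes are named ``collab``
        and ``cons``, the remainder ``PC3``...
    loadings : DataFrame
        Trait x axis eigenvector entries (unit-norm columns).
    eigenvalues : ndarray
    variance_explained : Series
        Percent of total (co)variance per axis; sums to 100.
    reflections : dict
        Which axes were sign-flipped by orientation.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: pd.Series
    mode: str
    reflections: dict = field(default_factory=dict)
    model: "PhyloPCA | None" = None

    @property
    def axes(self) -> list[str]:
        return list(self.scores.columns)

    def score(self, species: str, axis: str) -> float:
        species = normalize_label(species)
        if species not in self.scores.index:
            raise ExperimentDataError(f"no root-economics score for species {species!r}")
        return float(self.scores.loc[species, axis])

    @property
    def strategies(self) -> pd.DataFrame:
        """Per-species strategy quadrant with boundary-tie flag."""
        rows = [
            assign_strategy(r.collab, r.cons)
            for r in self.scores.itertuples()
        ]
        return pd.DataFrame(rows, columns=["strategy", "boundary"], index=self.scores.index)

    def summary(self) -> str:
        lines = ["Root economics space (phylogenetically informed PCA)"]
        lines.append(f"  species: {len(self.scores)}   mode: {self.mode}")
        ve = "  ".join(
            f"{ax}: {v:.1f}%" for ax, v in self.variance_explained.items()
        )
        lines.append(f"  variance explained: {ve}")
        if any(self.reflections.values()):
            flipped = [ax for ax, f in self.reflections.items() if f]
            lines.append(f"  axes reflected during orientation: {flipped}")
        lines.append("")
        lines.append("Loadings:")
        lines.append(self.loadings.round(3).to_string())
        counts = self.strategies["strategy"].value_counts().to_dict()
        lines.append("")
        lines.append(f"Strategy counts: {counts}")
        return "\n".join(lines)


def orient_axes(space: RootEconomicsSpace) -> RootEconomicsSpace:
    """Reflect axes so SRL loads positively on collab and N on cons.

    Scores and loadings are flipped together, so all downstream distances and
    midpoints are unchanged up to the coherent sign. Idempotent.
    """
    scores = space.scores.copy()
    loadings = space.loadings.copy()
    reflections = dict(space.reflections)
    for axis, anchor in ORIENTATION_ANCHORS.items():
        if axis not in loadings.columns:
            continue
        val = loadings.loc[anchor, axis]
        if val == 0:
            raise OrientationError(
                f"loading of anchor trait {anchor!r} on axis {axis!r} is zero; "
                "orientation is ambiguous"
            )
        if val < 0:
            scores[axis] = -scores[axis]
            loadings[axis] = -loadings[axis]
            reflections[axis] = not reflections.get(axis, False)
        else:
            reflections.setdefault(axis, False)
    return RootEconomicsSpace(
        scores=scores,
        loadings=loadings,
        eigenvalues=space.eigenvalues,
        variance_explained=space.variance_explained,
        mode=space.mode,
        reflections=reflections,
        model=space.model,
    )


class PhyloPCA:
    """Phylogenetically informed PCA of ln-transformed root traits.

    Parameters
    ----------
    traits : DataFrame
        Species x {SRL, D, RTD, N}, strictly positive, indexed by species.
    tree : dendropy.Tree, optional
        Rooted phylogeny with branch lengths covering all species. When
        omitted (or with ``star_fallback`` for species coverage problems)
        the phylogenetic covariance is the identity and the analysis reduces
        to an ordinary PCA of the ln-traits.
    mode : {"correlation", "covariance"}
        Whether to standardize traits by their evolutionary standard
        deviations before eigendecomposition (default: correlation).
    star_fallback : bool
        Replace C by the identity matrix instead of erroring when the tree
        is missing species from the trait table.
    jitter : float
        Optional diagonal jitter for near-singular C.
    """

    def __init__(self, traits: pd.DataFrame, tree: dendropy.Tree | None = None,
                 mode: str = "correlation", star_fallback: bool = False,
                 jitter: float = 0.0):
        if mode not in ("correlation", "covariance"):
            raise ConfigurationError(f"unknown PCA mode {mode!r}")
        self.traits = validate_traits(traits)
        if len(self.traits) < 3:
            raise ExperimentDataError("need at least 3 species for PCA")
        self.tree = tree
        self.mode = mode
        self.star_fallback = star_fallback
        self.jitter = jitter
        # populated by fit()
        self.C: np.ndarray | None = None
        self.gls_mean: np.ndarray | None = None
        self.R: np.ndarray | None = None
        self.eigenvectors: np.ndarray | None = None
        self.eigenvalues: np.ndarray | None = None

    @classmethod
    def from_files(cls, traits_csv, tree_path=None, **kwargs) -> "PhyloPCA":
        from .io import read_traits
        from .phylo import read_newick

        tree = read_newick(tree_path) if tree_path else None
        return cls(read_traits(traits_csv), tree, **kwargs)

    def _covariance(self, species: list[str]) -> np.ndarray:
        if self.tree is None:
            return np.eye(len(species))
        in_tree = set(tip_labels(self.tree))
        absent = sorted(set(species) - in_tree)
        if absent:
            if self.star_fallback:
                import logging

                logging.getLogger(__name__).warning(
                    "star fallback: %d species missing from tree (%s...); using C = I",
                    len(absent), absent[:3],
                )
                return np.eye(len(species))
            raise TreeMismatchError(f"species not found in tree: {absent}")
        pruned = prune_tree(self.tree, species)
        C, _ = phylo_vcv(pruned, order=species, jitter=self.jitter)
        return C

    def fit(self) -> RootEconomicsSpace:
        """Run the phylo-PCA and return the oriented root economics space."""
        species = list(self.traits.index)
        X = np.log(self.traits.to_numpy())
        n, k = X.shape
        C = self._covariance(species)

        try:
            chol = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise SingularCovarianceError(f"singular phylogenetic covariance: {exc}") from exc
        ones = np.ones((n, 1))
        Cinv_one = cho_solve(chol, ones)
        Cinv_X = cho_solve(chol, X)
        # GLS (ancestral-state) mean: a = (1'C^-1 1)^-1 1'C^-1 X
        a = (ones.T @ Cinv_X) / float((ones.T @ Cinv_one)[0, 0])
        Xc = X - ones @ a
        R_cov = Xc.T @ cho_solve(chol, Xc) / (n - 1)

        if self.mode == "correlation":
            d = np.sqrt(np.diag(R_cov))
            tiny = d <= 1e-12 * max(1.0, float(np.abs(X).max()))
            if tiny.any():
                bad = [TRAIT_COLUMNS[i] for i in np.flatnonzero(tiny)]
                raise ExperimentDataError(
                    f"constant trait column(s) under correlation mode: {bad}"
                )
            R = R_cov / np.outer(d, d)
            X_for_scores = Xc / d
        else:
            R = R_cov
            X_for_scores = Xc

        eigvals, eigvecs = np.linalg.eigh(R)
        order = np.argsort(eigvals)[::-1]
        eigvals = eigvals[order]
        eigvecs = eigvecs[:, order]
        # deterministic sign: largest-magnitude entry of each eigenvector positive
        for j in range(k):
            i = int(np.argmax(np.abs(eigvecs[:, j])))
            if eigvecs[i, j] < 0:
                eigvecs[:, j] = -eigvecs[:, j]

        scores = X_for_scores @ eigvecs
        total = eigvals.sum()
        var_pct = 100.0 * eigvals / total

        axis_names = ["collab", "cons"] + [f"PC{i}" for i in range(3, k + 1)]
        self.C, self.gls_mean, self.R = C, a.ravel(), R
        self.eigenvectors, self.eigenvalues = eigvecs, eigvals

        space = RootEconomicsSpace(
            scores=pd.DataFrame(scores, index=pd.Index(species, name="species"),
                                columns=axis_names),
            loadings=pd.DataFrame(eigvecs, index=TRAIT_COLUMNS, columns=axis_names),
            eigenvalues=eigvals,
            variance_explained=pd.Series(var_pct, index=axis_names, name="variance_pct"),
            mode=self.mode,
            model=self,
        )
        return orient_axes(space)


def phylo_pca(traits: pd.DataFrame, tree: dendropy.Tree | None = None,
              mode: str = "correlation", **kwargs) -> RootEconomicsSpace:
    """Functional shorthand for ``PhyloPCA(traits, tree, mode=mode).fit()``."""
    return PhyloPCA(traits, tree, mode=mode, **kwargs).fit()
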