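"""Exception hierarchy shared across the package."""


class RootPSFError(Exception):
    """Base class for all package-specific errors."""


class ExperimentDataError(RootPSFError, ValueError):
    """Invalid replicate-level biomass data (non-positive mass, duplicates...)."""


class MissingCellError(RootPSFError, ValueError):
    """A required (focal, soil, treatment) cell has no replicates."""


class ConfigurationError(RootPSFError, ValueError):
    """Invalid thresholds, parameters or run configuration."""


class TreeMismatchError(RootPSFError, ValueError):
    """Species requested from a phylogeny that does not contain them."""


class SingularCovarianceError(RootPSFError, ValueError):
    """Phylogenetic covariance matrix is numerically singular."""


class OrientationError(RootPSFError, ValueError):
    """Axis orientation is ambiguous (anchor trait has zero loading)."""


class RankDeficiencyError(RootPSFError, ValueError):
    """Design matrix is rank deficient (collinear model terms)."""
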