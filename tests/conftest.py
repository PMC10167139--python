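import numpy as np
import pandas as pd
import pytest

from rootpsf.phylo import read_newick


@pytest.fixture
def balanced_tree():
    """4-tip balanced ultrametric tree."""
    return read_newick("((A:1,B:1):1,(Cc:1,Dd:1):1);")


@pytest.fixture
def star_traits():
    """8 species with independent two-gradient trait structure, no tree."""
    rng = np.random.default_rng(11)
    c = rng.standard_normal(8)
    f = rng.standard_normal(8)
    eps = rng.normal(0, 0.05, size=(8, 4))
    species = [f"sp{i}" for i in range(8)]
    return pd.DataFrame(
        {
            "SRL": np.exp(c + eps[:, 0]),
            "D": np.exp(-c + eps[:, 1]),
            "RTD": np.exp(-f + eps[:, 2]),
            "N": np.exp(f + eps[:, 3]),
        },
        index=pd.Index(species, name="species"),
    )


def make_experiment(performances, n_replicates=2, noise_sd=0.0, seed=0):
    """Build a replicate table from exact cell log-performances.

    ``performances`` maps (focal, soil, treatment) -> mean ln biomass.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (focal, soil, treatment), mu in performances.items():
        for rep in range(1, n_replicates + 1):
            ln = mu + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "focal_species": focal,
                    "soil_species": soil,
                    "treatment": treatment,
                    "replicate": rep,
                    "biomass_g": float(np.exp(ln)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def two_species_experiment():
    """Reciprocal 2-species design with sterile controls, zero noise."""
    cells = {
        ("A", "A", "live"): 0.8,
        ("A", "B", "live"): 0.3,
        ("B", "B", "live"): 0.5,
        ("B", "A", "live"): 0.9,
        ("A", "STERILE", "sterile"): 0.2,
        ("B", "STERILE", "sterile"): 0.6,
    }
    return make_experiment(cells)
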