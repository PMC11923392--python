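"""Inbreeding, diversity and adaptive-divergence genomics for isolated
populations.

The pipeline takes diploid biallelic SNP genotypes (VCF) through
quality control, nonnative-ancestry masking, heterozygosity and
runs-of-homozygosity inbreeding coefficients (F_ROH), pairwise
Weir-Cockerham F_ST, and a covariance-aware genome scan (XtX + deciban
Bayes factors) for loci associated with population-level life-history
traits.  A forward-simulation module generates panels with exact
identity-by-descent truth so every stage is verifiable end to end.
"""

from importlib.resources import files

import pandas as pd

from .config import RunConfig
from .core import MISSING, GenotypeMatrix, from_calls, population_allele_counts
from .roh import ROHParams, ROHSegment, detect_roh, f_roh, inbreeding_table
from .sim import DemographyScenario, PRESETS, SimTruth, simulate_populations

__version__ = "0.1.0"

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "RunConfig",
    "ROHParams",
    "ROHSegment",
    "DemographyScenario",
    "SimTruth",
    "PRESETS",
    "detect_roh",
    "f_roh",
    "from_calls",
    "inbreeding_table",
    "population_allele_counts",
    "simulate_populations",
    "load_example_traits",
]


def load_example_traits() -> pd.DataFrame:
    """Packaged life-history trait table for ten isolated study
    populations (maximum observed length, mean age-1 length, and mean
    age-1 to age-2 growth, all in mm), indexed by population."""
    path = files("rohscan.data").joinpath("isolated_population_traits.tsv")
    return pd.read_csv(path, sep="\t").set_index("population")
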