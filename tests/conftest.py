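import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hexafib.aaindex import STANDARD_RESIDUES, AminoAcidIndex
from hexafib.synthetic_data import generate_indices


@pytest.fixture(scope="session")
def synthetic_indices():
    """A dict of 60 reproducible synthetic amino-acid indices."""
    return {ix.accession: ix for ix in generate_indices(60, seed=42)}


@pytest.fixture(scope="session")
def linear_index():
    """Index assigning 0..19 to the residues in alphabetical order."""
    return AminoAcidIndex(
        "LINEAR", "alphabetical ramp",
        {r: float(i) for i, r in enumerate(STANDARD_RESIDUES)},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


AAINDEX_TWO_RECORDS = """\
H TESTIDX1
D Hydrophobicity toy scale
R PMID:0000000
A Nobody, N.
T A toy record
J Nowhere 1 (2020)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.62   -2.53   -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40    1.38
     1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26    1.08
//
H TESTIDX2
D Volume toy scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     88.6   173.4   114.1   111.1   108.5   143.8   138.4    60.1   153.2   166.7
    166.7   168.6   162.9   189.9   112.7    89.0   116.1   227.8   193.6   140.0
//
"""

AAINDEX_WITH_NA = """\
H PARTIAL1
D Record with missing data
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.62   NA      -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40    1.38
     1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26    1.08
//
"""

AAINDEX_SHORT = """\
H SHORT1
D Only nineteen values
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.62   -2.53   -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40    1.38
     1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26
//
"""
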