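import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from rinstab.datasets import make_fixture_structure
from rinstab.structure_io import assign_secondary_structure, compute_rsa


@pytest.fixture(scope="session")
def helix():
    s, pdb_text = make_fixture_structure("helix", 15)
    return s, pdb_text


@pytest.fixture(scope="session")
def annotated_helix():
    s, _ = make_fixture_structure("helix", 15, sequence="ACDEFGHIKLMNQRS",
                                  pdb_id="helix15")
    assign_secondary_structure(s)
    compute_rsa(s)
    return s


@pytest.fixture(scope="session")
def hairpin():
    s, pdb_text = make_fixture_structure("hairpin", 16)
    return s, pdb_text


def backbones_of(s):
    """Extract N/CA/C/O coordinate dicts for the secondary-structure oracle."""
    out = []
    for r in s.residues:
        bb = {}
        for name in ("N", "CA", "C", "O"):
            a = r.atom(name)
            if a is None:
                bb = None
                break
            bb[name] = a.coord
        out.append(bb)
    return out


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.984   2.840   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.496   2.693   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.585   0.000  1.00  0.00           O
ATOM     10  N   ALA A   3       6.207   3.810   0.000  1.00  0.00           N
ATOM     11  CA  ALA A   3       7.663   3.789   0.000  1.00  0.00           C
ATOM     12  C   ALA A   3       8.220   5.202   0.000  1.00  0.00           C
ATOM     13  O   ALA A   3       7.459   6.170   0.000  1.00  0.00           O
ATOM     14  CB  ALA A   3       8.186   3.010   1.203  1.00  0.00           C
TER
END
"""
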