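import numpy as np
import pytest

from conflock.io import Topology


def make_ca_topology(n_residues: int, start_resid: int = 1) -> Topology:
    """Calpha-only protein topology with ``n_residues`` residues."""
    n = n_residues
    flags = {
        "alpha_carbon": np.ones(n, dtype=bool),
        "backbone": np.ones(n, dtype=bool),
    }
    return Topology(
        names=np.asarray(["CA"] * n, dtype=object),
        elements=np.asarray(["C"] * n, dtype=object),
        resids=np.arange(start_resid, start_resid + n),
        resnames=np.asarray(["ALA"] * n, dtype=object),
        chains=np.asarray(["A"] * n, dtype=object),
        masses=np.full(n, 12.011),
        flags=flags,
    )


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.800   5.132  -4.288  1.00  0.00           C
ATOM      4  O   ALA A   1       9.582   5.090  -4.439  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.640   7.455  -4.513  1.00  0.00           C
ATOM      6  N   GLY A   2      11.435   4.386  -3.380  1.00  0.00           N
ATOM      7  CA  GLY A   2      10.747   3.448  -2.509  1.00  0.00           C
ATOM      8  C   GLY A   2      11.273   3.521  -1.084  1.00  0.00           C
ATOM      9  O   GLY A   2      12.453   3.786  -0.857  1.00  0.00           O
ATOM     10  N   SER A   3      10.410   3.273  -0.101  1.00  0.00           N
ATOM     11  CA  SER A   3      10.796   3.323   1.303  1.00  0.00           C
ATOM     12  C   SER A   3      11.857   2.271   1.627  1.00  0.00           C
ATOM     13  O   SER A   3      11.586   1.081   1.477  1.00  0.00           O
ATOM     14  OG  SER A   3       9.648   3.111   2.113  1.00  0.00           O
HETATM   15  N   LEU L 501       5.000   5.000   5.000  1.00  0.00           N
HETATM   16  CA  LEU L 501       6.200   5.700   5.300  1.00  0.00           C
HETATM   17  O1  LEU L 501       7.400   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three_residue.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def ca480_topology():
    return make_ca_topology(480)
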