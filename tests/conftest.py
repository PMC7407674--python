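"""Shared fixtures: toy dimers and minimal hand-built PDB files."""

import numpy as np
import pytest

from cgassoc.synthetic_fixtures import ToyDimerSpec, make_toy_dimer


@pytest.fixture(scope="session")
def dimer6():
    """An 11-residue-per-chain toy complex with exactly 6 native contacts at 4 A."""
    return make_toy_dimer(ToyDimerSpec(n_residues=11, n_contacts=6, seed=1))


@pytest.fixture(scope="session")
def funnel_dimer():
    """A charge-complementary toy complex used for association studies.

    Receptor interface residues are positively charged (ARG), ligand
    interface residues negatively (GLU); the remaining positions alternate
    hydrophobic types, so electrostatic steering, the hydrophobic term and
    the native-topology term all act.
    """
    n = 9
    spec = ToyDimerSpec(
        n_residues=n,
        n_contacts=5,
        seed=2,
        receptor_types=tuple("ARG" if i % 2 == 0 else "LEU" for i in range(n)),
        ligand_types=tuple("GLU" if i % 2 == 0 else "ILE" for i in range(n)),
    )
    return make_toy_dimer(spec)


def write_two_residue_pdb(path, second_resname="ASP", separation=10.0):
    """A 2-residue PDB: ALA at the origin, a second residue ``separation`` A away.

    Each residue gets CA plus two side-chain atoms so the SC centroid differs
    from any single atom.
    """
    from cgassoc.synthetic_fixtures import write_pdb

    ala_ca = np.zeros(3)
    ala_sc = np.array([1.5, 0.0, 0.0])
    res2_ca = np.array([separation, 0.0, 0.0])
    res2_sc = np.array([separation + 1.5, 0.0, 0.0])
    return write_pdb(
        {"A": [("ALA", ala_ca, ala_sc), (second_resname, res2_ca, res2_sc)]},
        path,
    )
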