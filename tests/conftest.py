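import numpy as np
import pytest

from labelsim.structure import LabelSite, SiteClass
from labelsim.synthetic import HelixSpec, make_helix_scaffold
from labelsim.templates import CANONICAL_ANCHOR, load_template


@pytest.fixture(scope="session")
def r1_template():
    return load_template("R1")


@pytest.fixture(scope="session")
def a350_template():
    return load_template("A350")


@pytest.fixture(scope="session")
def canonical_anchor():
    return CANONICAL_ANCHOR


@pytest.fixture(scope="session")
def helix_pair():
    """Two-helix scaffold, 20 residues each, 30 A apart, sites at residue 10."""
    structure, sites = make_helix_scaffold(
        HelixSpec(n_residues=20, n_helices=2, separation=30.0, site_positions=(10,))
    )
    return structure, sites


@pytest.fixture(scope="session")
def single_helix():
    structure, sites = make_helix_scaffold(
        HelixSpec(n_residues=20, n_helices=1, site_positions=(10,))
    )
    return structure, sites[0]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_library(r1_template):
    """Small rotamer library (fast); enough rotamers to populate all
    X1/X2 classes."""
    from labelsim.rotamers import generate_library

    return generate_library(r1_template, n_rotamers=40, n_samples=4000, seed=7)


def make_pdb_text(atoms):
    """atoms: list of (serial, name, resname, chain, resnum, x, y, z, occ, altloc)"""
    lines = []
    for serial, name, resname, chain, resnum, x, y, z, occ, altloc in atoms:
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:<3s} {chain}{resnum:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           {name[0]}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_atom_pdb(tmp_path):
    path = tmp_path / "two.pdb"
    path.write_text(
        make_pdb_text(
            [
                (1, "CA", "ALA", "A", 1, 1.234, 2.345, 3.456, 1.0, " "),
                (2, "CA", "ALA", "A", 2, 4.321, 5.432, 6.543, 1.0, " "),
            ]
        )
    )
    return path
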