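"""Label-protein interaction energies.

Pairwise Lennard-Jones scoring of a label conformer against its (rigid)
protein environment, with an optional screened Coulomb term and the
"forgive factor" softening used by rotamer library analysis: scaling the
pair equilibrium distance by f in (0, 1] shifts the LJ minimum inward and
weakens clash penalties, a rudimentary stand-in for side-chain and
backbone flexibility in a fixed-structure calculation.

Energies are in internal kT(298 K) units; the per-element parameter table
ships as package data (see ``data/lj_params.json``) and uses
Lorentz-Berthelot combination rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from .constants import kcal_to_kt_units

__all__ = ["ForceFieldParams", "lj_pair", "label_environment_energy", "CLASH_ENERGY"]

#: Finite energy (kT units) assigned to overlapping atom pairs (r < 0.1 A);
#: large enough to signal a hard clash, finite so sums stay well-defined.
CLASH_ENERGY = 1.0e6

_MIN_PAIR_DISTANCE = 0.1


def _load_element_table() -> dict:
    raw = json.loads(
        resources.files("labelsim.data").joinpath("lj_params.json").read_text()
    )
    return {
        el: (kcal_to_kt_units(v["epsilon"]), v["rmin_half"])
        for el, v in raw["elements"].items()
    }


@dataclass
class ForceFieldParams:
    """Per-element LJ table plus global knobs.

    Parameters
    ----------
    dielectric_constant : relative permittivity of the implicit continuum
        (80 emulates water screening).
    forgive_factor : LJ equilibrium-distance scaling in (0, 1]; 1 = plain LJ.
    cutoff : pair-distance cutoff in Angstrom.
    use_coulomb : include q_i q_j / (eps_r r) when partial charges are given.
    """

    dielectric_constant: float = 80.0
    forgive_factor: float = 1.0
    cutoff: float = 10.0
    use_coulomb: bool = False
    element_table: dict = field(default_factory=_load_element_table)

    def __post_init__(self):
        if not (0.0 < self.forgive_factor <= 1.0):
            raise ValueError(
                f"forgive_factor must be in (0, 1], got {self.forgive_factor}"
            )
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def lookup(self, element: str) -> tuple[float, float]:
        """(epsilon kT, rmin/2 A) for an element; unknown elements score as C."""
        return self.element_table.get(
            element.upper(), self.element_table["C"]
        )


def lj_pair(r: float, epsilon: float, r_min: float, forgive: float = 1.0):
    """12-6 Lennard-Jones energy with forgive-factor softening.

    E = epsilon * [(f*r_min/r)^12 - 2*(f*r_min/r)^6]; the minimum -epsilon
    sits at r = f*r_min. Vectorized over `r`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    s6 = (forgive * r_min / r) ** 6
    return epsilon * (s6 * s6 - 2.0 * s6)


def label_environment_energy(
    conformer,
    structure,
    params: ForceFieldParams | None = None,
    exclude=None,
    label_charges=None,
    protein_charges=None,
) -> float:
    """Total interaction energy of a label conformer with a protein.

    Sums `lj_pair` over all (label atom, protein atom) pairs within the
    cutoff. `exclude` is a predicate on :class:`AtomRecord` marking protein
    atoms to omit — typically the labeled residue's own backbone (anything
    within two covalent bonds of the anchor). Overlapping pairs
    (r < 0.1 A) contribute a clamped finite clash energy.

    When ``params.use_coulomb`` and both charge arrays are given, a
    screened Coulomb term q_i q_j / (eps_r * r) (Coulomb constant 332.06
    kcal/mol A e^-2, converted to kT) is added over the same pairs.
    """
    if params is None:
        params = ForceFieldParams()
    env_atoms = [
        a for a in structure.atoms if exclude is None or not exclude(a)
    ]
    if not env_atoms or len(conformer.coordinates) == 0:
        return 0.0
    env_xyz = np.array([a.position for a in env_atoms])
    d = cdist(conformer.coordinates, env_xyz)

    lab_eps, lab_rh = zip(*(params.lookup(e) for e in conformer.elements))
    env_eps, env_rh = zip(*(params.lookup(a.element) for a in env_atoms))
    eps = np.sqrt(np.outer(lab_eps, env_eps))
    rmin = np.add.outer(np.array(lab_rh), np.array(env_rh))

    within = d <= params.cutoff
    clash = d < _MIN_PAIR_DISTANCE
    ok = within & ~clash

    total = float(np.count_nonzero(clash)) * CLASH_ENERGY
    if np.any(ok):
        total += float(np.sum(lj_pair(d[ok], eps[ok], rmin[ok], params.forgive_factor)))

    if params.use_coulomb and label_charges is not None and protein_charges is not None:
        qq = np.outer(np.asarray(label_charges, float), np.asarray(protein_charges, float))
        coulomb_kcal = 332.0636 * qq[ok] / (params.dielectric_constant * d[ok])
        total += float(np.sum(kcal_to_kt_units(coulomb_kcal)))
    return total


def site_exclusion(site, structure=None):
    """Predicate excluding the labeled residue itself (its backbone and CB
    lie within two covalent bonds of the label anchor) plus the peptide
    atoms of the adjacent residues bonded to it."""

    def _excluded(atom) -> bool:
        if atom.chain_id != site.chain_id:
            return False
        if atom.residue_number == site.residue_number:
            return True
        if atom.residue_number == site.residue_number - 1 and atom.name in ("C", "O"):
            return True
        if atom.residue_number == site.residue_number + 1 and atom.name == "N":
            return True
        return False

    return _excluded
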