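"""Label side-chain templates in internal coordinates.

A template describes one label (the R1 nitroxide, or a simplified
fluorophore conjugate) as a chain of atoms anchored on the backbone
N/CA/CB triad. Each atom carries (bond length, bond angle, dihedral,
reference triplet); a subset of the dihedrals are the rotatable degrees of
freedom (5 for the spin label, 11 for fluorophores). Cartesian conformers
are built by forward kinematics, so covalent geometry is exact for every
dihedral vector, and each conformer exposes a reporter point: the N-O bond
midpoint for the nitroxide, the chromophore centroid for dyes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import ideal_cb_position, place_atom, wrap_deg

__all__ = [
    "LabelTemplate",
    "LabelConformer",
    "load_template",
    "build_conformer",
    "reporter_position",
    "classify_angle",
    "classify_x1x2",
    "CANONICAL_ANCHOR",
]

EXPECTED_DIHEDRALS = {"spin": 5, "fluorophore": 11}

#: Idealized backbone frame used when a template is built free of a protein
#: (rotamer library generation, template self-tests). N/CA/C at standard
#: geometry, CB at ideal tetrahedral position.
CANONICAL_ANCHOR = {
    "N": np.array([-0.527, 1.359, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.525, 0.0, 0.0]),
}
CANONICAL_ANCHOR["CB"] = ideal_cb_position(
    CANONICAL_ANCHOR["N"], CANONICAL_ANCHOR["CA"], CANONICAL_ANCHOR["C"]
)


@dataclass
class LabelConformer:
    """A single Cartesian realization of a label template."""

    dihedrals: np.ndarray
    coordinates: np.ndarray  # (n_atoms, 3), Angstrom
    atom_names: list[str]
    elements: list[str]
    reporter: np.ndarray
    energy: float = np.nan

    def __post_init__(self):
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.reporter = np.asarray(self.reporter, dtype=float)


@dataclass
class LabelTemplate:
    name: str
    kind: str
    residue_name: str
    atom_specs: list[dict]
    rotatable: list[str]
    reporter_rule: dict
    comment: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        expected = EXPECTED_DIHEDRALS.get(self.kind)
        if expected is not None and len(self.rotatable) != expected:
            raise ValueError(
                f"{self.kind} template {self.name} must have {expected} "
                f"rotatable dihedrals, found {len(self.rotatable)}"
            )
        self._index = {key: i for i, key in enumerate(self.rotatable)}

    @property
    def n_dihedrals(self) -> int:
        return len(self.rotatable)

    @property
    def atom_names(self) -> list[str]:
        return [a["name"] for a in self.atom_specs]

    @property
    def elements(self) -> list[str]:
        return [a["element"] for a in self.atom_specs]

    @property
    def reference_dihedrals(self) -> np.ndarray:
        """A sterically open all-trans starting vector."""
        return np.full(self.n_dihedrals, 180.0)

    def build_conformer(self, dihedrals, anchor) -> LabelConformer:
        """Place all template atoms by forward kinematics.

        `anchor` maps the names N, CA, CB (and optionally C) to 3-vectors.
        Only dihedral changes alter the output; bond lengths and angles are
        template constants by construction.
        """
        dihedrals = wrap_deg(np.asarray(dihedrals, dtype=float))
        if dihedrals.shape != (self.n_dihedrals,):
            raise ValueError(
                f"expected {self.n_dihedrals} dihedrals, got {dihedrals.shape}"
            )
        positions = {k: np.asarray(v, dtype=float) for k, v in anchor.items()}
        coords = np.empty((len(self.atom_specs), 3))
        for i, spec in enumerate(self.atom_specs):
            try:
                a, b, c = (positions[r] for r in spec["refs"])
            except KeyError as exc:
                raise ValueError(
                    f"template {self.name}: reference atom {exc} not placed "
                    f"before {spec['name']}"
                ) from exc
            dih = spec["dihedral"]
            if isinstance(dih, str):
                dih = dihedrals[self._index[dih]]
            pos = place_atom(a, b, c, spec["bond"], spec["angle"], dih)
            positions[spec["name"]] = pos
            coords[i] = pos
        conformer = LabelConformer(
            dihedrals=dihedrals,
            coordinates=coords,
            atom_names=self.atom_names,
            elements=self.elements,
            reporter=np.zeros(3),
        )
        conformer.reporter = reporter_position(conformer, self.reporter_rule)
        return conformer


def load_template(name: str) -> LabelTemplate:
    """Load one of the shipped templates: ``R1``, ``A350`` or ``A488``."""
    fname = name.lower() + ".json"
    ref = resources.files("labelsim.data").joinpath(fname)
    try:
        raw = json.loads(ref.read_text())
    except FileNotFoundError as exc:
        raise KeyError(f"no shipped label template named {name!r}") from exc
    return LabelTemplate(
        name=raw["name"],
        kind=raw["kind"],
        residue_name=raw["residue_name"],
        atom_specs=raw["atoms"],
        rotatable=raw["rotatable"],
        reporter_rule=raw["reporter"],
        comment=raw.get("comment", ""),
    )


def build_conformer(template: LabelTemplate, dihedrals, anchor) -> LabelConformer:
    """Functional alias for :meth:`LabelTemplate.build_conformer`."""
    return template.build_conformer(dihedrals, anchor)


def reporter_position(conformer: LabelConformer, rule: dict) -> np.ndarray:
    """Evaluate a reporter rule on a conformer.

    ``NO_midpoint`` averages the two named nitroxide atoms; the chromophore
    centroid is the unweighted mean of the listed ring atoms.
    """
    names = rule["atoms"]
    index = {n: i for i, n in enumerate(conformer.atom_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise KeyError(f"reporter atoms {missing} not present in conformer")
    pts = conformer.coordinates[[index[n] for n in names]]
    if rule["mode"] == "NO_midpoint" and len(names) != 2:
        raise ValueError("NO_midpoint rule requires exactly two atoms")
    return pts.mean(axis=0)


def classify_angle(chi: float) -> str:
    """Map a dihedral to its rotamer class: m (gauche-), p (gauche+), t (trans).

    Boundaries at 0 and +-120 degrees; input wrapped, so the classification
    is invariant under +-360 degree shifts.
    """
    chi = float(wrap_deg(chi))
    if -120.0 <= chi < 0.0:
        return "m"
    if 0.0 <= chi < 120.0:
        return "p"
    return "t"


def classify_x1x2(conformer_or_dihedrals) -> tuple[str, str]:
    """Classify the first two dihedrals (X1, X2) of a conformer."""
    dihedrals = getattr(
        conformer_or_dihedrals, "dihedrals", conformer_or_dihedrals
    )
    dihedrals = np.asarray(dihedrals, dtype=float)
    if dihedrals.shape[-1] < 2:
        raise ValueError("X1/X2 classification needs at least two dihedrals")
    return classify_angle(dihedrals[0]), classify_angle(dihedrals[1])
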