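"""Protein structures: PDB reading/writing, labeling sites, backbone
reference distances and in-silico label attachment.

Reading is done with Biopython's PDB parser; only the first model is kept
and alternate locations are resolved to the highest-occupancy conformer
(ties broken alphabetically by altloc id) so that parsing is deterministic.
Coordinates are in Angstrom; residue numbering follows the author (PDB)
numbering throughout.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .geometry import ideal_cb_position

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "LabelSite",
    "SiteClass",
    "PDBFormatError",
    "SiteResolutionError",
    "StericClashError",
    "read_pdb",
    "write_pdb",
    "ca_distance",
    "attach_label",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "HA2", "HA3"}


class PDBFormatError(ValueError):
    """Raised when a PDB file is missing, empty or malformed."""


class SiteResolutionError(KeyError):
    """Raised when a labeling site does not resolve to a usable residue."""


class StericClashError(RuntimeError):
    """Raised when an initial label conformer overlaps the protein."""


class SiteClass(str, Enum):
    HELICAL = "helical"
    LOOP = "loop"
    OTHER = "other"


@dataclass
class AtomRecord:
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    insertion_code: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class ProteinStructure:
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def atom(self, chain_id: str, residue_number: int, name: str) -> AtomRecord:
        for a in self.residue_atoms(chain_id, residue_number):
            if a.name == name:
                return a
        raise SiteResolutionError(
            f"atom {name} not found in {chain_id}:{residue_number}"
        )

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            [
                AtomRecord(
                    a.name,
                    a.element,
                    a.residue_number,
                    a.residue_name,
                    a.chain_id,
                    a.position.copy(),
                    a.occupancy,
                    a.b_factor,
                    a.is_hetero,
                    a.insertion_code,
                )
                for a in self.atoms
            ]
        )


@dataclass(frozen=True)
class LabelSite:
    chain_id: str
    residue_number: int
    site_class: SiteClass = SiteClass.OTHER


def read_pdb(path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only the first model is loaded; alternate locations are resolved to the
    highest-occupancy altloc (alphabetical tie-break); water and other
    heteroatom records are retained but flagged ``is_hetero``.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    try:
        with open(path) as fh:
            text = fh.read()
    except FileNotFoundError as exc:
        raise PDBFormatError(f"PDB file not found: {path}") from exc

    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure("s", io.StringIO(text))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBFormatError(f"malformed PDB file {path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise PDBFormatError(f"no ATOM records found in {path}")
    model = models[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            het_flag, resseq, icode = residue.id
            is_het = het_flag.strip() != ""
            for atom in residue:
                if atom.is_disordered():
                    # highest occupancy; alphabetical altloc as tie-break
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    atom = children[0]
                atoms.append(
                    AtomRecord(
                        name=atom.get_name(),
                        element=(atom.element or "").strip() or atom.get_name()[0],
                        residue_number=resseq,
                        residue_name=residue.get_resname(),
                        chain_id=chain.id,
                        position=np.array(atom.get_coord(), dtype=float),
                        occupancy=atom.get_occupancy() or 1.0,
                        b_factor=atom.get_bfactor() or 0.0,
                        is_hetero=is_het,
                        insertion_code=icode.strip(),
                    )
                )
    if not atoms:
        raise PDBFormatError(f"no ATOM records found in {path}")
    return ProteinStructure(atoms)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: element right-justified in cols 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write a structure using fixed-column ATOM/HETATM records."""
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            record = "HETATM" if a.is_hetero else "ATOM  "
            x, y, z = a.position
            fh.write(
                f"{record}{i % 100000:5d} {_format_atom_name(a.name, a.element)}"
                f" {a.residue_name:<3s} {a.chain_id[:1]}{a.residue_number:4d}"
                f"{(a.insertion_code or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


def fetch_pdb(pdb_id: str, cache_dir=None):
    """Return a local path to `pdb_id`, downloading from RCSB if needed.

    Looks in `cache_dir` (default ``~/.cache/labelsim``) first; raises
    :class:`PDBFormatError` with instructions when the file is absent and
    no network is available.
    """
    import urllib.error
    import urllib.request
    from pathlib import Path

    pdb_id = pdb_id.lower()
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "labelsim"
    path = cache / f"{pdb_id}.pdb"
    if path.exists():
        return path
    cache.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            path.write_bytes(resp.read())
    except (urllib.error.URLError, OSError) as exc:
        raise PDBFormatError(
            f"structure {pdb_id} not cached at {path} and download from "
            f"{url} failed ({exc}); place the PDB file there manually to "
            "run crystal-structure comparisons"
        ) from exc
    return path


def resolve_site(structure: ProteinStructure, site: LabelSite) -> dict:
    """Return the backbone anchor atoms (N, CA, C and CB, built for glycine)
    of a labeling site, raising :class:`SiteResolutionError` otherwise."""
    residue = structure.residue_atoms(site.chain_id, site.residue_number)
    if not residue:
        raise SiteResolutionError(
            f"site {site.chain_id}:{site.residue_number} not found in structure"
        )
    by_name = {a.name: a for a in residue}
    missing = [n for n in ("N", "CA", "C") if n not in by_name]
    if missing:
        raise SiteResolutionError(
            f"site {site.chain_id}:{site.residue_number} lacks backbone atoms "
            f"{missing}"
        )
    anchors = {n: by_name[n].position for n in ("N", "CA", "C")}
    if "CB" in by_name:
        anchors["CB"] = by_name["CB"].position
    else:
        anchors["CB"] = ideal_cb_position(anchors["N"], anchors["CA"], anchors["C"])
    return anchors


def ca_distance(structure: ProteinStructure, a: LabelSite, b: LabelSite) -> float:
    """Euclidean C-alpha/C-alpha distance between two sites, Angstrom."""
    ca_a = structure.atom(a.chain_id, a.residue_number, "CA").position
    ca_b = structure.atom(b.chain_id, b.residue_number, "CA").position
    return float(np.linalg.norm(ca_a - ca_b))


def attach_label(
    structure: ProteinStructure,
    site: LabelSite,
    template,
    initial_dihedrals: Sequence[float],
    clash_cutoff: float | None = 0.8,
):
    """Replace the native side chain at `site` with a label side chain.

    Native atoms beyond C-beta are removed, the label template is placed by
    forward kinematics anchored on N-CA-CB, and the backbone is left
    bit-identical. Returns ``(labeled_structure, conformer)``.

    If any label atom lies within `clash_cutoff` Angstrom of a retained
    protein atom outside the labeled residue, a :class:`StericClashError`
    is raised (pass ``clash_cutoff=None`` to disable the check).
    """
    anchors = resolve_site(structure, site)
    conformer = template.build_conformer(np.asarray(initial_dihedrals, float), anchors)

    new_atoms: list[AtomRecord] = []
    inserted = False
    for a in structure.atoms:
        at_site = (
            a.chain_id == site.chain_id and a.residue_number == site.residue_number
        )
        if at_site and a.name not in BACKBONE_NAMES and a.name != "CB":
            continue  # native side chain beyond CB dropped
        if at_site:
            a = AtomRecord(
                a.name,
                a.element,
                a.residue_number,
                template.residue_name,
                a.chain_id,
                a.position,
                a.occupancy,
                a.b_factor,
                a.is_hetero,
                a.insertion_code,
            )
        new_atoms.append(a)
        if at_site and a.name == "CB" and not inserted:
            inserted = True
            for name, element, pos in zip(
                template.atom_names, template.elements, conformer.coordinates
            ):
                new_atoms.append(
                    AtomRecord(
                        name=name,
                        element=element,
                        residue_number=site.residue_number,
                        residue_name=template.residue_name,
                        chain_id=site.chain_id,
                        position=pos.copy(),
                    )
                )
    if not inserted:
        # glycine: CB was constructed, append it plus the label atoms
        out: list[AtomRecord] = []
        for a in new_atoms:
            out.append(a)
            if (
                a.chain_id == site.chain_id
                and a.residue_number == site.residue_number
                and a.name == "CA"
            ):
                out.append(
                    AtomRecord(
                        "CB",
                        "C",
                        site.residue_number,
                        template.residue_name,
                        site.chain_id,
                        anchors["CB"].copy(),
                    )
                )
                for name, element, pos in zip(
                    template.atom_names, template.elements, conformer.coordinates
                ):
                    out.append(
                        AtomRecord(
                            name,
                            element,
                            site.residue_number,
                            template.residue_name,
                            site.chain_id,
                            pos.copy(),
                        )
                    )
        new_atoms = out

    labeled = ProteinStructure(new_atoms)
    if clash_cutoff is not None:
        env = np.array(
            [
                a.position
                for a in structure.atoms
                if not (
                    a.chain_id == site.chain_id
                    and a.residue_number == site.residue_number
                )
            ]
        )
        if len(env) and len(conformer.coordinates):
            from scipy.spatial.distance import cdist

            dmin = cdist(conformer.coordinates, env).min()
            if dmin < clash_cutoff:
                raise StericClashError(
                    f"initial label conformer clashes with the protein "
                    f"(closest approach {dmin:.2f} A < {clash_cutoff} A); "
                    "choose different starting dihedrals"
                )
    return labeled, conformer
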