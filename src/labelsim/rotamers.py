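"""Rotamer library analysis (RLA) for spin labels.

The label's conformational ensemble is modeled as a discrete set of
rotamers with intrinsic populations. At a site, each rotamer is rigidly
superposed onto the local backbone (N/CA/C), scored against the protein
with the Lennard-Jones energy, and Boltzmann-reweighted:

    p_i = p0_i * exp(-E_i / kT) / Z,   Z = sum_j p0_j * exp(-E_j / kT)

Between two reweighted placements, the distance distribution is the
histogram of all pairwise reporter-reporter distances weighted by the
product p_i * p_j. At alpha-helical sites an optional crystallographic
selection keeps only the {m,m} and {t,p} X1/X2 rotamer classes, which are
the dominantly populated states of the R1 side chain on helices.

The shipped workflow GENERATES its library by flat-landscape Monte Carlo
on the free label followed by clustering in wrapped-dihedral space (a
functional substitute for published precalculated libraries, which are
not redistributable here; default size 210 rotamers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diststats import DistanceDistribution, default_grid
from .energy import CLASH_ENERGY, ForceFieldParams, label_environment_energy, site_exclusion
from .geometry import kabsch_transform
from .templates import CANONICAL_ANCHOR, LabelTemplate, classify_x1x2

__all__ = [
    "RotamerLibrary",
    "RotamerPlacement",
    "UnlabelableSiteError",
    "generate_library",
    "superpose_rotamer",
    "rla_probabilities",
    "x1x2_select",
    "pair_distance_distribution",
]

ANCHOR_NAMES = ("N", "CA", "C")
DEFAULT_ALLOWED_CLASSES = frozenset({("m", "m"), ("t", "p")})


class UnlabelableSiteError(RuntimeError):
    """All rotamers clash at the site: the partition function underflows."""


@dataclass
class RotamerLibrary:
    """Discrete rotamer set in a canonical backbone frame.

    ``coords`` holds, per rotamer, the anchor atoms N/CA/C/CB followed by
    the label side-chain atoms; ``populations`` are the intrinsic (free
    label) probabilities and sum to 1.
    """

    template: LabelTemplate
    dihedrals: np.ndarray  # (K, n_dih)
    coords: np.ndarray  # (K, 4 + n_atoms, 3)
    populations: np.ndarray  # (K,)
    atom_names: list[str]
    generation_temperature: float = 298.0

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("intrinsic populations must sum to 1")
        if np.any(self.populations < 0):
            raise ValueError("intrinsic populations must be non-negative")

    def __len__(self) -> int:
        return len(self.populations)

    @property
    def anchor_coords(self) -> np.ndarray:
        return self.coords[:, : len(ANCHOR_NAMES), :]

    @property
    def reporter_index(self) -> np.ndarray:
        rule = self.template.reporter_rule
        offset = 4  # N, CA, C, CB
        names = self.atom_names[offset:]
        return offset + np.array([names.index(n) for n in rule["atoms"]])


@dataclass
class RotamerPlacement:
    """A library placed and Boltzmann-reweighted at one site."""

    site: object
    library: RotamerLibrary
    energies: np.ndarray  # (K,), kT units
    probabilities: np.ndarray  # (K,), sum 1; exactly 0 for filtered rotamers
    partition_function: float
    reporter_positions: np.ndarray  # (K, 3)

    def __post_init__(self):
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("placement probabilities must sum to 1")


def generate_library(
    template: LabelTemplate,
    n_rotamers: int = 210,
    n_samples: int = 20_000,
    seed: int = 2012,
    generation_temperature: float = 298.0,
) -> RotamerLibrary:
    """Build a rotamer library for a label template.

    Flat-landscape MC on the free label (whose stationary law is uniform
    over the dihedral torus) supplies conformer samples; k-means on the
    (cos, sin) torus embedding partitions them and the medoid of each
    cluster — the member sample nearest the centroid — becomes a library
    rotamer, with intrinsic population equal to the cluster weight.
    Deterministic for fixed inputs.
    """
    from sklearn.cluster import KMeans

    from .mc import DihedralSystem, MCConfig, run_mc

    system = DihedralSystem(template.n_dihedrals, lambda x: 0.0)
    config = MCConfig(
        n_steps=n_samples, temperature=generation_temperature,
        min_jump_rmsd=20.0, seed=seed,
    )
    traj = run_mc(system, config)
    samples = traj.dihedrals

    rad = np.radians(samples)
    embed = np.hstack([np.cos(rad), np.sin(rad)])
    km = KMeans(n_clusters=n_rotamers, n_init=4, random_state=seed).fit(embed)
    labels = km.labels_

    dihedrals = np.empty((n_rotamers, template.n_dihedrals))
    populations = np.empty(n_rotamers)
    for k in range(n_rotamers):
        members = np.flatnonzero(labels == k)
        if len(members) == 0:  # degenerate cluster: reuse centroid angles
            ang = np.degrees(
                np.arctan2(km.cluster_centers_[k, template.n_dihedrals:],
                           km.cluster_centers_[k, : template.n_dihedrals])
            )
            dihedrals[k] = ang
            populations[k] = 0.0
            continue
        dist = np.linalg.norm(embed[members] - km.cluster_centers_[k], axis=1)
        dihedrals[k] = samples[members[np.argmin(dist)]]
        populations[k] = len(members)
    populations = populations / populations.sum()

    anchor = CANONICAL_ANCHOR
    anchor_block = np.array([anchor["N"], anchor["CA"], anchor["C"], anchor["CB"]])
    coords = np.empty((n_rotamers, 4 + len(template.atom_specs), 3))
    for k in range(n_rotamers):
        conf = template.build_conformer(dihedrals[k], anchor)
        coords[k, :4] = anchor_block
        coords[k, 4:] = conf.coordinates
    atom_names = ["N", "CA", "C", "CB"] + template.atom_names
    return RotamerLibrary(
        template=template,
        dihedrals=dihedrals,
        coords=coords,
        populations=populations,
        atom_names=atom_names,
        generation_temperature=generation_temperature,
    )


def superpose_rotamer(rotamer_coords, rotamer_anchor, site_anchor):
    """Rigidly map rotamer coordinates into the site frame.

    The least-squares (Kabsch) transform aligning the rotamer anchor atoms
    (N, CA, C) onto the site backbone is applied to all rotamer atoms.
    Returns ``(placed_coords, anchor_rmsd)``.
    """
    rotamer_coords = np.asarray(rotamer_coords, dtype=float)
    rotamer_anchor = np.asarray(rotamer_anchor, dtype=float)
    site_anchor = np.asarray(site_anchor, dtype=float)
    if rotamer_anchor.shape[0] < 3 or site_anchor.shape[0] < 3:
        raise ValueError("need at least 3 anchor atoms for superposition")
    spans = rotamer_anchor - rotamer_anchor.mean(axis=0)
    if np.linalg.matrix_rank(spans, tol=1e-8) < 2:
        raise ValueError("collinear anchor atoms")
    rot, t, rmsd = kabsch_transform(rotamer_anchor, site_anchor)
    return rotamer_coords @ rot.T + t, rmsd


def rla_probabilities(
    library: RotamerLibrary,
    site,
    structure,
    params: ForceFieldParams | None = None,
    temperature: float = 298.0,
) -> RotamerPlacement:
    """Place a library at a site and Boltzmann-reweight its populations.

    Raises :class:`UnlabelableSiteError` when every rotamer clashes so the
    partition function underflows.
    """
    from .structure import resolve_site
    from .templates import LabelConformer

    if params is None:
        params = ForceFieldParams()
    anchors = resolve_site(structure, site)
    site_anchor = np.array([anchors[n] for n in ANCHOR_NAMES])
    exclude = site_exclusion(site)

    k_rot = len(library)
    energies = np.empty(k_rot)
    reporters = np.empty((k_rot, 3))
    rep_idx = library.reporter_index
    beta = 298.0 / temperature  # energies are in kT(298) units
    for i in range(k_rot):
        placed, _ = superpose_rotamer(
            library.coords[i], library.anchor_coords[i], site_anchor
        )
        side = placed[4:]  # drop anchor copies N/CA/C/CB
        conf = LabelConformer(
            dihedrals=library.dihedrals[i],
            coordinates=side,
            atom_names=library.atom_names[4:],
            elements=library.template.elements,
            reporter=placed[rep_idx].mean(axis=0),
        )
        energies[i] = label_environment_energy(conf, structure, params, exclude=exclude)
        reporters[i] = conf.reporter

    e_shift = energies.min()
    if e_shift >= CLASH_ENERGY:
        raise UnlabelableSiteError(
            f"site {site.chain_id}:{site.residue_number}: every rotamer "
            "clashes with the protein (partition function underflow)"
        )
    weights = library.populations * np.exp(-(energies - e_shift) * beta)
    z = weights.sum()
    if z <= 0 or not np.isfinite(z):
        raise UnlabelableSiteError(
            f"site {site.chain_id}:{site.residue_number}: partition function "
            "underflow"
        )
    return RotamerPlacement(
        site=site,
        library=library,
        energies=energies,
        probabilities=weights / z,
        partition_function=float(z * np.exp(-e_shift * beta)),
        reporter_positions=reporters,
    )


def x1x2_select(
    placement: RotamerPlacement,
    allowed=DEFAULT_ALLOWED_CLASSES,
) -> RotamerPlacement:
    """Keep only rotamers whose (X1, X2) classes are in `allowed`.

    Filtered rotamers get probability exactly 0; survivors are
    renormalized. Raises if nothing survives.
    """
    allowed = {tuple(a) for a in allowed}
    classes = [classify_x1x2(d) for d in placement.library.dihedrals]
    mask = np.array([c in allowed for c in classes])
    p = np.where(mask, placement.probabilities, 0.0)
    total = p.sum()
    if total <= 0:
        raise UnlabelableSiteError(
            "no rotamer survives the X1/X2 class selection at "
            f"{placement.site}"
        )
    return RotamerPlacement(
        site=placement.site,
        library=placement.library,
        energies=placement.energies,
        probabilities=p / total,
        partition_function=placement.partition_function,
        reporter_positions=placement.reporter_positions,
    )


def pair_distance_distribution(
    a: RotamerPlacement, b: RotamerPlacement, grid=None
) -> DistanceDistribution:
    """Probability-weighted histogram of all pairwise reporter distances.

    Each rotamer pair (i, j) contributes weight p_i * p_j at the distance
    between its reporter points; the result is normalized and symmetric in
    its arguments.
    """
    from scipy.spatial.distance import cdist

    if len(a.probabilities) == 0 or len(b.probabilities) == 0:
        raise ValueError("empty placement")
    grid = default_grid() if grid is None else np.asarray(grid, float)
    d = cdist(a.reporter_positions, b.reporter_positions).ravel()
    w = np.outer(a.probabilities, b.probabilities).ravel()
    return DistanceDistribution.from_samples(d, weights=w, grid=grid)
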