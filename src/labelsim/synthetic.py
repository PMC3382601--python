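"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's inputs at desk scale: ideal
poly-alanine alpha-helix scaffolds with designated (helical) labeling
sites, fluorescence intensity pairs drawn from a known transfer
efficiency and labeling efficiency, and noisy DEER traces from a known
Gaussian-mixture distance distribution. Every generator is fully
determined by its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deer import DipolarTrace, simulate_trace
from .diststats import DistanceDistribution, default_grid
from .fret import FRETMeasurement
from .geometry import ideal_cb_position, place_atom
from .structure import AtomRecord, LabelSite, ProteinStructure, SiteClass

__all__ = [
    "HelixSpec",
    "make_helix_scaffold",
    "gen_fret_intensities",
    "gen_deer_trace",
]

# canonical alpha-helix backbone geometry
PHI, PSI, OMEGA = -57.0, -47.0, 180.0
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7


@dataclass
class HelixSpec:
    n_residues: int = 20
    n_helices: int = 1
    separation: float = 30.0  # inter-helix axis separation, Angstrom
    site_positions: tuple = ()  # residue numbers to flag as labeling sites

    def __post_init__(self):
        if self.n_residues < 6:
            raise ValueError("need at least 6 residues for a helix")
        if self.n_helices not in (1, 2):
            raise ValueError("scaffolds support 1 or 2 helices")


def _helix_backbone(n_residues: int) -> list[dict]:
    """Ideal alpha-helix N/CA/C positions built by forward kinematics."""
    residues = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, PSI)
        ca = place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, PHI)
        residues.append({"N": n, "CA": ca, "C": c})
    return residues


def _helix_axis(residues) -> np.ndarray:
    ca = np.array([r["CA"] for r in residues])
    axis = ca[-1] - ca[0]
    return axis / np.linalg.norm(axis)


def make_helix_scaffold(spec: HelixSpec | None = None):
    """Build a poly-alanine helix scaffold and its labeling sites.

    Returns ``(structure, sites)``; chains are A (and B for a two-helix
    scaffold, rigidly offset perpendicular to the helix axis by the
    stated separation). Sites are flagged helical. Deterministic: the
    geometry is ideal, there is no randomness to seed.
    """
    if spec is None:
        spec = HelixSpec()
    residues = _helix_backbone(spec.n_residues)
    axis = _helix_axis(residues)
    # perpendicular offset direction for the second helix
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)

    atoms: list[AtomRecord] = []
    chains = ["A", "B"][: spec.n_helices]
    for ci, chain in enumerate(chains):
        offset = perp * spec.separation * ci
        for i, res in enumerate(residues, start=1):
            n, ca, c = res["N"] + offset, res["CA"] + offset, res["C"] + offset
            cb = ideal_cb_position(n, ca, c)
            for name, element, pos in (
                ("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("CB", "C", cb),
            ):
                atoms.append(
                    AtomRecord(name, element, i, "ALA", chain, pos)
                )
    structure = ProteinStructure(atoms)
    site_positions = spec.site_positions or (spec.n_residues // 2,)
    sites = [
        LabelSite(chain, pos, SiteClass.HELICAL)
        for chain in chains
        for pos in site_positions
    ]
    return structure, sites


def gen_fret_intensities(
    e_true: float,
    f_a: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n: int = 1,
) -> list[FRETMeasurement]:
    """Donor intensity pairs from a known transfer efficiency.

    I_D = 1 and I_DA = 1 - f_A * E_true + Gaussian noise, so the
    labeling-corrected efficiency estimator recovers E_true exactly at
    zero noise.
    """
    if not (0.0 < e_true < 1.0):
        raise ValueError("E_true must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        i_da = 1.0 - f_a * e_true
        if noise_sd > 0:
            i_da += rng.normal(0.0, noise_sd)
        out.append(FRETMeasurement(i_da=float(np.clip(i_da, 0.0, 1.0)), i_d=1.0, f_a=f_a))
    return out


@dataclass
class DeerTruth:
    means: tuple = (40.0,)  # Angstrom
    sds: tuple = (3.0,)  # Angstrom
    weights: tuple = (1.0,)
    modulation_depth: float = 0.3
    background_rate: float = 0.05  # 1/us
    noise_sd: float = 0.005
    t_max: float = 2.0  # us
    dt: float = 0.008  # us
    seed: int = 0
    grid: np.ndarray = field(default_factory=default_grid)


def gen_deer_trace(truth: DeerTruth | None = None):
    """Noisy DEER trace plus its ground-truth distance distribution.

    The truth is a Gaussian mixture materialized on the analysis grid
    (defaults emulate well-defined unimodal distributions in the 25-59 A
    range with 6-11 A widths, i.e. the regime where DEER distance
    analysis is routine). Returns ``(trace, distribution)``.
    """
    if truth is None:
        truth = DeerTruth()
    w = np.asarray(truth.weights, dtype=float)
    w = w / w.sum()
    r = np.asarray(truth.grid, dtype=float)
    p = np.zeros_like(r)
    for mean, sd, wk in zip(truth.means, truth.sds, w):
        p += wk * np.exp(-0.5 * ((r - mean) / sd) ** 2) / sd
    dist = DistanceDistribution(r, p / p.sum())
    t = np.arange(0.0, truth.t_max + truth.dt / 2, truth.dt)
    trace = simulate_trace(
        dist,
        truth.modulation_depth,
        truth.background_rate,
        t,
        noise_sd=truth.noise_sd,
        seed=truth.seed,
    )
    return trace, dist
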