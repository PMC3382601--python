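"""Metropolis Monte Carlo search over label dihedrals.

The chain state is the vector of rotatable dihedrals. Proposals are
uniform per-dihedral perturbations, redrawn until the wrapped angular RMSD
from the current state exceeds a minimum jump size (20 deg for spin
labels, 50 deg for fluorophores, mirroring the study protocol), which
forces genuine conformational jumps rather than local jitter. Acceptance
follows the Metropolis criterion at the configured temperature; an
optional greedy dihedral relaxation of each proposal emulates the local
energy minimization of the original protocol at desk scale (the protein
stays rigid). With ``minimize_steps = 0`` the chain is plain Metropolis
and samples the Boltzmann distribution of the label's dihedral energy
landscape exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import beta_factor
from .energy import ForceFieldParams, label_environment_energy, site_exclusion
from .geometry import angular_rmsd, wrap_deg

__all__ = [
    "MCConfig",
    "MCTrajectory",
    "DihedralSystem",
    "LabeledSystem",
    "propose_jump",
    "metropolis_accept",
    "run_mc",
    "accessed_volume",
]


@dataclass
class MCConfig:
    n_steps: int = 50_000
    temperature: float = 300.0
    min_jump_rmsd: float = 20.0  # deg; 50 for fluorophores
    minimize_steps: int = 0
    seed: int = 0
    record_every: int = 1
    proposal_window: float = 60.0  # deg, half-width of per-dihedral draw

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.min_jump_rmsd < 0:
            raise ValueError("min_jump_rmsd must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class MCTrajectory:
    dihedrals: np.ndarray  # (n_frames, n_dih)
    energies: np.ndarray  # (n_frames,), internal kT(298) units
    reporters: np.ndarray  # (n_frames, 3)
    acceptance_count: int
    config: MCConfig
    atom_positions: np.ndarray | None = None  # (n_frames, n_atoms, 3)

    @property
    def n_frames(self) -> int:
        return len(self.energies)

    @property
    def acceptance_rate(self) -> float:
        return self.acceptance_count / self.config.n_steps

    def to_frame(self):
        """Columnar export: frame, dihedrals, energy, reporter x/y/z."""
        import pandas as pd

        data = {"frame": np.arange(self.n_frames)}
        for j in range(self.dihedrals.shape[1]):
            data[f"chi{j + 1}"] = self.dihedrals[:, j]
        data["energy"] = self.energies
        for k, ax in enumerate("xyz"):
            data[f"reporter_{ax}"] = self.reporters[:, k]
        return pd.DataFrame(data)


class DihedralSystem:
    """Minimal system interface: an energy over a dihedral vector.

    Used directly for analytic toy landscapes; :class:`LabeledSystem`
    adapts a labeled protein structure to the same interface.
    """

    def __init__(self, n_dihedrals: int, energy_fn: Callable, start=None):
        self.n_dihedrals = n_dihedrals
        self._energy_fn = energy_fn
        self.start = (
            np.zeros(n_dihedrals) if start is None else np.asarray(start, float)
        )

    def energy(self, dihedrals) -> float:
        return float(self._energy_fn(np.asarray(dihedrals, float)))

    def observables(self, dihedrals):
        """(reporter position, atom positions or None) for recording."""
        return np.zeros(3), None


class LabeledSystem(DihedralSystem):
    """A label template attached at a site of a protein structure."""

    def __init__(self, structure, site, template, params: ForceFieldParams | None = None,
                 start=None):
        from .structure import resolve_site

        self.structure = structure
        self.site = site
        self.template = template
        self.params = params if params is not None else ForceFieldParams()
        self.anchors = resolve_site(structure, site)
        self._exclude = site_exclusion(site)
        super().__init__(
            template.n_dihedrals,
            None,
            start=template.reference_dihedrals if start is None else start,
        )

    def build(self, dihedrals):
        return self.template.build_conformer(dihedrals, self.anchors)

    def energy(self, dihedrals) -> float:
        conformer = self.build(dihedrals)
        return label_environment_energy(
            conformer, self.structure, self.params, exclude=self._exclude
        )

    def observables(self, dihedrals):
        conformer = self.build(dihedrals)
        return conformer.reporter, conformer.coordinates


def propose_jump(current, min_rmsd: float, rng, window: float = 60.0,
                 max_redraw: int = 100) -> np.ndarray:
    """Propose a dihedral vector at wrapped angular RMSD >= `min_rmsd`.

    Per-dihedral perturbations are drawn from a symmetric uniform window;
    if `max_redraw` draws fail to clear the threshold the window is scaled
    up and drawing continues, so the call always terminates.
    """
    current = np.asarray(current, dtype=float)
    w = float(window)
    while True:
        for _ in range(max_redraw):
            proposal = wrap_deg(
                current + rng.uniform(-w, w, size=current.shape)
            )
            if angular_rmsd(proposal, current) >= min_rmsd and not np.array_equal(
                proposal, current
            ):
                return proposal
        w = min(w * 1.5, 180.0)


def metropolis_accept(delta_e: float, temperature: float, rng) -> bool:
    """Metropolis criterion: accept if delta_E <= 0, else with probability
    exp(-delta_E / kT). `delta_e` is in internal kT(298) units."""
    if delta_e <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_e * beta_factor(temperature)))


def _greedy_minimize(system, dihedrals, energy, steps: int, rng,
                     step_deg: float = 5.0):
    """Cheap gradient-free relaxation: random small dihedral tweaks kept
    only when they lower the energy. Deterministic for a given rng state."""
    x, e = dihedrals, energy
    for _ in range(steps):
        trial = wrap_deg(x + rng.uniform(-step_deg, step_deg, size=x.shape))
        et = system.energy(trial)
        if et < e:
            x, e = trial, et
    return x, e


def run_mc(system, config: MCConfig) -> MCTrajectory:
    """Run a Metropolis chain over a system's dihedrals.

    Reproducible bit-exactly for a fixed ``config.seed``. Recorded frames
    (every ``record_every`` accepted-or-not steps) carry dihedrals, energy
    and reporter position; atom positions are recorded when the system
    provides them.
    """
    rng = np.random.default_rng(config.seed)
    x = wrap_deg(np.asarray(system.start, dtype=float))
    e = system.energy(x)
    if not np.isfinite(e):
        raise ValueError(f"non-finite starting energy {e}")

    n_rec = config.n_steps // config.record_every
    dihedrals = np.empty((n_rec, system.n_dihedrals))
    energies = np.empty(n_rec)
    reporters = np.empty((n_rec, 3))
    atom_positions = None
    accepted = 0
    rec = 0
    for step in range(1, config.n_steps + 1):
        proposal = propose_jump(
            x, config.min_jump_rmsd, rng, window=config.proposal_window
        )
        e_prop = system.energy(proposal)
        if config.minimize_steps > 0:
            proposal, e_prop = _greedy_minimize(
                system, proposal, e_prop, config.minimize_steps, rng
            )
        if metropolis_accept(e_prop - e, config.temperature, rng):
            x, e = proposal, e_prop
            accepted += 1
        if step % config.record_every == 0:
            reporter, atoms = system.observables(x)
            if atoms is not None and atom_positions is None:
                atom_positions = np.empty((n_rec, len(atoms), 3))
            dihedrals[rec] = x
            energies[rec] = e
            reporters[rec] = reporter
            if atoms is not None:
                atom_positions[rec] = atoms
            rec += 1
    return MCTrajectory(
        dihedrals=dihedrals,
        energies=energies,
        reporters=reporters,
        acceptance_count=accepted,
        config=config,
        atom_positions=atom_positions,
    )


def accessed_volume(traj_or_positions, grid: float = 1.0) -> np.ndarray:
    """Cumulative volume (A^3) of distinct voxels touched frame by frame.

    Accepts an :class:`MCTrajectory` (label atom positions if recorded,
    else reporter positions) or a raw (n_frames, n_points, 3) /
    (n_frames, 3) array. The series is monotone non-decreasing; its final
    value does not depend on frame order.
    """
    if grid <= 0:
        raise ValueError("grid spacing must be positive")
    if isinstance(traj_or_positions, MCTrajectory):
        pos = (
            traj_or_positions.atom_positions
            if traj_or_positions.atom_positions is not None
            else traj_or_positions.reporters
        )
    else:
        pos = np.asarray(traj_or_positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    seen: set = set()
    series = np.empty(len(pos))
    for i, frame in enumerate(pos):
        vox = np.floor(frame / grid).astype(np.int64)
        seen.update(map(tuple, vox))
        series[i] = len(seen) * grid**3
    return series
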