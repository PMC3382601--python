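"""3-D occupancy densities and probability-isocontour envelopes.

Conformer ensembles (MC trajectory positions or weighted rotamer reporter
points) are deposited on a regular voxel grid; an envelope at mass m is
the smallest set of voxels whose summed probability reaches m (greedy by
descending probability, ties broken by flat voxel index), the standard
way of drawing "label clouds" that envelope a stated fraction of the
total probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DensityGrid", "density_from_ensemble", "probability_envelope"]


@dataclass
class DensityGrid:
    origin: np.ndarray  # corner of voxel (0,0,0), Angstrom
    spacing: float
    probabilities: np.ndarray  # 3-D, sums to 1

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def voxel_centers(self, indices) -> np.ndarray:
        return self.origin + (np.asarray(indices, float) + 0.5) * self.spacing

    def write(self, path) -> None:
        """Plain-voxel text format: header then `i j k p` per occupied voxel."""
        occ = np.argwhere(self.probabilities > 0)
        with open(path, "w") as fh:
            fh.write(
                f"# origin {self.origin[0]:.3f} {self.origin[1]:.3f} "
                f"{self.origin[2]:.3f} spacing {self.spacing:.3f} "
                f"shape {' '.join(map(str, self.probabilities.shape))}\n"
            )
            for i, j, k in occ:
                fh.write(f"{i} {j} {k} {self.probabilities[i, j, k]:.8e}\n")


def density_from_ensemble(positions, spacing: float = 1.0, weights=None
                          ) -> DensityGrid:
    """Deposit a weighted point set on a voxel grid (nearest voxel).

    `positions` is (n, 3); weights default to uniform. The grid is sized
    to the bounding box of the points and the result is normalized.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise ValueError("empty point set")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if weights is None:
        weights = np.ones(len(positions))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight")

    idx = np.floor(positions / spacing).astype(np.int64)
    lo = idx.min(axis=0)
    idx = idx - lo
    shape = tuple(idx.max(axis=0) + 1)
    grid = np.zeros(shape)
    np.add.at(grid, tuple(idx.T), weights)
    return DensityGrid(origin=lo * spacing, spacing=spacing,
                       probabilities=grid / total)


def probability_envelope(grid: DensityGrid, mass: float) -> np.ndarray:
    """Smallest voxel set holding at least `mass` of the probability.

    Returns the (n, 3) integer indices of the selected voxels, ordered by
    descending probability (ties by flat index). Envelopes nest: the set
    at a smaller mass is a subset of the set at a larger mass.
    """
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    p = grid.probabilities.ravel()
    occupied = np.flatnonzero(p > 0)
    order = occupied[np.lexsort((occupied, -p[occupied]))]
    csum = np.cumsum(p[order])
    n_keep = int(np.searchsorted(csum, mass - 1e-12) + 1)
    n_keep = min(n_keep, len(order))
    return np.array(np.unravel_index(order[:n_keep], grid.probabilities.shape)).T
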