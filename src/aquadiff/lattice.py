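"""Periodic face-centered-cubic lattice of spherical cells.

Models a centrifuged cell pellet as a dense FCC packing of spheres with
normally distributed radii inside a periodic box.  Each cell carries a
categorical permeability label (e.g. aquaporin-expressing vs. control) so
that mixed populations can be represented.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Label for cells with the control (low) membrane water permeability.
LOW_PERM = "LOW_PERM"
#: Label for cells with enhanced (e.g. aquaporin-mediated) permeability.
HIGH_PERM = "HIGH_PERM"
#: Compartment id returned by :meth:`CellLattice.locate` outside every cell.
EXTRACELLULAR = -1

# FCC basis sites in units of the cubic lattice constant.
_FCC_BASIS = np.array(
    [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
)


@dataclass
class CellLattice:
    """Periodic packing of spherical cells.

    Attributes
    ----------
    centers : (n, 3) array, um
        Sphere centers inside the periodic box.
    radii : (n,) array, um
        Sphere radii; spheres never overlap under periodic images.
    labels : (n,) array of str
        Per-cell permeability class (``LOW_PERM`` / ``HIGH_PERM`` by default).
    box_lengths : (3,) array, um
        Edge lengths of the periodic box.
    lattice_constant : float, um
        Edge of the cubic FCC unit cell.
    seed : int or None
        Seed used to sample radii (recorded for replay).
    """

    centers: np.ndarray
    radii: np.ndarray
    labels: np.ndarray
    box_lengths: np.ndarray
    lattice_constant: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U16")
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if np.any(self.radii <= 0):
            raise ConfigurationError("all cell radii must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_lengths))

    @property
    def intracellular_fraction(self) -> float:
        """Volume fraction occupied by cells (spheres are disjoint)."""
        return float(np.sum(4.0 / 3.0 * np.pi * self.radii**3) / self.box_volume)

    # -- geometry queries -------------------------------------------------

    def minimum_image(self, vec: np.ndarray) -> np.ndarray:
        """Map displacement vectors to their periodic minimum image."""
        return vec - self.box_lengths * np.round(vec / self.box_lengths)

    def locate(self, point: np.ndarray) -> int | np.ndarray:
        """Return the cell index containing ``point``, else ``EXTRACELLULAR``.

        A point exactly on a membrane (distance == radius) counts as
        intracellular.  Accepts a single 3-vector or an (m, 3) array.
        """
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        diff = pts[:, None, :] - self.centers[None, :, :]
        diff = diff - self.box_lengths * np.round(diff / self.box_lengths)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        inside = d2 <= self.radii[None, :] ** 2
        out = np.full(len(pts), EXTRACELLULAR, dtype=np.int64)
        hit_any = inside.any(axis=1)
        out[hit_any] = np.argmax(inside[hit_any], axis=1)
        if np.asarray(point).ndim == 1:
            return int(out[0])
        return out

    def pair_separations(self) -> np.ndarray:
        """Pairwise surface gaps r_ij = |c_i - c_j|_min-image - (r_i + r_j)."""
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        diff = diff - self.box_lengths * np.round(diff / self.box_lengths)
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        gaps = d - (self.radii[:, None] + self.radii[None, :])
        np.fill_diagonal(gaps, np.inf)
        return gaps

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "centers": self.centers.tolist(),
            "radii": self.radii.tolist(),
            "labels": self.labels.tolist(),
            "box_lengths": self.box_lengths.tolist(),
            "lattice_constant": self.lattice_constant,
            "seed": self.seed,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CellLattice":
        doc = json.loads(text)
        return cls(
            centers=np.array(doc["centers"]),
            radii=np.array(doc["radii"]),
            labels=np.array(doc["labels"]),
            box_lengths=np.array(doc["box_lengths"]),
            lattice_constant=doc["lattice_constant"],
            seed=doc["seed"],
        )

    def to_records(self):
        """Per-cell records (index, x, y, z, radius, label) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "x_um": self.centers[:, 0],
                "y_um": self.centers[:, 1],
                "z_um": self.centers[:, 2],
                "radius_um": self.radii,
                "label": self.labels,
            }
        )


def default_lattice_constant(mean_radius: float) -> float:
    """FCC lattice constant for which mean-radius spheres just touch.

    The FCC nearest-neighbour distance is a/sqrt(2); touching spheres of
    radius r require a = 2*sqrt(2)*r (~19.23 um for r = 6.8 um).
    """
    return 2.0 * np.sqrt(2.0) * mean_radius


def build_fcc_lattice(
    n_supercells_per_axis: int = 3,
    mean_radius: float = 6.8,
    sd_radius: float = 1.2,
    lattice_constant: float | None = None,
    seed: int = 0,
    min_redraw_radius: float = 0.5,
) -> CellLattice:
    """Build a periodic FCC supercell of spherical cells.

    Radii are drawn from Normal(mean_radius, sd_radius); draws at or below
    ``min_redraw_radius`` are redrawn.  Any pair of spheres that would
    overlap under periodic images is then shrunk symmetrically (each loses
    half the excess) until the packing is overlap-free, which preserves the
    radius distribution approximately while guaranteeing valid geometry.

    The default 3x3x3 supercell with 4 FCC sites per cubic cell yields 108
    cells.  The default lattice constant makes mean-radius spheres touch.
    """
    if mean_radius <= 0:
        raise ConfigurationError("mean_radius must be positive")
    if sd_radius < 0:
        raise ConfigurationError("sd_radius must be non-negative")
    if lattice_constant is None:
        lattice_constant = default_lattice_constant(mean_radius)
    if lattice_constant <= 0:
        raise ConfigurationError("lattice_constant must be positive")
    nn_dist = lattice_constant / np.sqrt(2.0)
    if nn_dist < mean_radius:
        raise ConfigurationError(
            f"lattice_constant={lattice_constant:.3g} um places nearest "
            f"neighbours {nn_dist:.3g} um apart, which cannot admit spheres "
            f"of mean radius {mean_radius:.3g} um without severe overlap"
        )

    n = n_supercells_per_axis
    cells = np.stack(
        np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = (cells[:, None, :] + _FCC_BASIS[None, :, :]).reshape(-1, 3)
    centers = centers * lattice_constant
    box = np.full(3, n * lattice_constant)

    rng = np.random.default_rng(seed)
    n_cells = len(centers)
    radii = rng.normal(mean_radius, sd_radius, size=n_cells)
    if sd_radius > 0:
        for _ in range(1000):
            bad = radii <= min_redraw_radius
            if not bad.any():
                break
            radii[bad] = rng.normal(mean_radius, sd_radius, size=bad.sum())

    # symmetric shrink until overlap-free (converges: excess only decreases)
    diff = centers[:, None, :] - centers[None, :, :]
    diff = diff - box * np.round(diff / box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(dist, np.inf)
    margin = 1e-9
    for _ in range(200):
        excess = radii[:, None] + radii[None, :] - dist + margin
        np.fill_diagonal(excess, -np.inf)
        worst = excess.max(axis=1)
        if np.all(worst <= 0):
            break
        shrink = np.maximum(worst, 0.0) / 2.0
        radii = radii - shrink
    if np.any(radii <= 0):
        raise ConfigurationError(
            "overlap removal drove a radius to zero; lattice_constant too small "
            "for the requested radius distribution"
        )

    labels = np.full(n_cells, LOW_PERM, dtype="U16")
    return CellLattice(
        centers=centers,
        radii=radii,
        labels=labels,
        box_lengths=box,
        lattice_constant=float(lattice_constant),
        seed=seed,
    )


def assign_labels(
    lattice: CellLattice, high_fraction: float, seed: int = 0
) -> CellLattice:
    """Label a random subset of cells ``HIGH_PERM``.

    Exactly ``round(high_fraction * n_cells)`` cells (round half away from
    zero) are chosen uniformly at random; the rest are ``LOW_PERM``.
    Returns a new lattice sharing geometry arrays.
    """
    if not 0.0 <= high_fraction <= 1.0:
        raise ConfigurationError("high_fraction must lie in [0, 1]")
    n = lattice.n_cells
    n_high = int(np.floor(high_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_high, replace=False)
    labels = np.full(n, LOW_PERM, dtype="U16")
    labels[chosen] = HIGH_PERM
    return dataclasses.replace(lattice, labels=labels)
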