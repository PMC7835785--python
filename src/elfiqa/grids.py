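"""Uniform Cartesian field grids and Gaussian cube output."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FieldGrid", "bounding_box", "write_cube"]


@dataclass
class FieldGrid:
    """A scalar field sampled on a uniform 3D Cartesian grid (atomic units)."""
    origin: np.ndarray          # (3,) bohr
    spacing: np.ndarray         # (3,) bohr
    values: np.ndarray          # (nx, ny, nz)
    field_name: str = "field"   # rho | tau | chi | elf | labels | ...

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a rank-3 array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.field_name == "elf":
            v = self.values
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("ELF values must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self):
        return tuple(self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
                     for d in range(3))

    def points(self):
        """All grid points as an (N, 3) array (C order, matching values.ravel())."""
        ax = self.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def point(self, idx):
        """Coordinates of a (i, j, k) voxel."""
        return self.origin + self.spacing * np.asarray(idx, float)

    def like(self, values: np.ndarray, field_name: str) -> "FieldGrid":
        return FieldGrid(self.origin.copy(), self.spacing.copy(), values, field_name)


def bounding_box(coords: np.ndarray, margin: float = 5.0):
    """Axis-aligned box enclosing the nuclei plus a vacuum margin (bohr)."""
    coords = np.asarray(coords, float)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate bounding box")
    return lo, hi


def default_box(coords: np.ndarray, margin: float = 3.0, thin_margin: float = 5.0):
    """The analysis box: ``margin`` bohr beyond the nuclei on the two
    largest-extent axes (those two expanded to equal length, so mirror
    symmetries of planar rings fall on grid planes), and ``thin_margin`` on
    the smallest-extent axis (which for a planar aromatic is the pi-system
    normal, whose density tails reach further than the in-plane ones)."""
    coords = np.asarray(coords, float)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    ext = hi - lo
    thin = int(np.argmin(ext))
    c = 0.5 * (hi + lo)
    wide = [d for d in range(3) if d != thin]
    target = max(ext[d] for d in wide) + 2 * margin
    out_lo = np.empty(3)
    out_hi = np.empty(3)
    for d in wide:
        out_lo[d] = c[d] - target / 2
        out_hi[d] = c[d] + target / 2
    out_lo[thin] = lo[thin] - thin_margin
    out_hi[thin] = hi[thin] + thin_margin
    return out_lo, out_hi


def grid_from_box(lo, hi, n_points) -> tuple[np.ndarray, np.ndarray]:
    """Origin and spacing for an n-per-axis grid spanning [lo, hi] inclusively."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    n = np.broadcast_to(np.asarray(n_points, int), (3,))
    if np.any(n < 2):
        raise ValueError("need at least 2 points per axis")
    spacing = (hi - lo) / (n - 1)
    if np.any(spacing <= 0):
        raise ValueError("degenerate bounding box")
    return lo, spacing


def write_cube(path, grid: FieldGrid, nuclei, comment: str = ""):
    """Write a Gaussian cube file (bohr units, voxel vectors, nuclei block)."""
    nx, ny, nz = grid.shape
    lines = [f"elfiqa {grid.field_name} cube", comment or "generated by elfiqa"]
    lines.append(f"{len(nuclei):5d}{grid.origin[0]:12.6f}{grid.origin[1]:12.6f}"
                 f"{grid.origin[2]:12.6f}")
    lines.append(f"{nx:5d}{grid.spacing[0]:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{ny:5d}{0.0:12.6f}{grid.spacing[1]:12.6f}{0.0:12.6f}")
    lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{grid.spacing[2]:12.6f}")
    for n in nuclei:
        z = int(n.charge) if float(n.charge).is_integer() else 0
        lines.append(f"{z:5d}{n.charge:12.6f}{n.xyz[0]:12.6f}{n.xyz[1]:12.6f}"
                     f"{n.xyz[2]:12.6f}")
    vals = grid.values
    for i in range(nx):
        for j in range(ny):
            row = vals[i, j]
            for k0 in range(0, nz, 6):
                lines.append("".join(f"{v:13.5E}" for v in row[k0:k0 + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path):
    """Read a cube file back into (FieldGrid, nuclei-as-arrays). Test helper."""
    lines = Path(path).read_text().splitlines()
    natom = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]])
    ns, spacing = [], []
    for d in range(3):
        parts = lines[3 + d].split()
        ns.append(int(parts[0]))
        spacing.append(float(parts[1 + d]))
    nuc = []
    for a in range(natom):
        parts = lines[6 + a].split()
        nuc.append((int(parts[0]), np.array([float(v) for v in parts[2:5]])))
    data = np.array([float(v) for ln in lines[6 + natom:] for v in ln.split()])
    values = data.reshape(ns)
    return FieldGrid(origin, np.array(spacing), values), nuc
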