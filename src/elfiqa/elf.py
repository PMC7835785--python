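"""The electron localization function (ELF).

The kernel chi compares the Pauli kinetic energy density
D = tau - |grad rho|^2 / (8 rho) with the homogeneous-electron-gas value
D0 = c_F rho^(5/3), c_F = (3/10)(3 pi^2)^(2/3); the ELF itself is the
Lorentzian map eta = 1 / (1 + chi^2), bounded in [0, 1].  This is the
standard Becke-Edgecombe closed-shell form, evaluated from the total
density of a doubly-occupied determinant.
"""
from __future__ import annotations

import numpy as np

from .grids import FieldGrid, grid_from_box
from .wavefunction import Wavefunction

__all__ = ["C_F", "DENSITY_FLOOR", "chi_kernel", "elf", "elf_on_grid",
           "fields_on_grid"]

C_F = 0.3 * (3.0 * np.pi ** 2) ** (2.0 / 3.0)
DENSITY_FLOOR = 1e-10   # e/bohr^3; below this eta := 0 (vacuum)


def chi_kernel(rho, grad_rho, tau, floor: float = DENSITY_FLOOR):
    """ELF kernel chi = D / D0; +inf where the density is below the floor."""
    rho = np.asarray(rho, float)
    tau = np.asarray(tau, float)
    grad_rho = np.asarray(grad_rho, float)
    g2 = (grad_rho ** 2).sum(axis=-1)
    chi = np.full(rho.shape, np.inf)
    ok = rho > floor
    D = tau[ok] - g2[ok] / (8.0 * rho[ok])
    # tiny negative D from roundoff in one-orbital regions is clamped
    D = np.maximum(D, 0.0)
    chi[ok] = D / (C_F * rho[ok] ** (5.0 / 3.0))
    return chi


def elf(chi):
    """Lorentzian map eta = 1/(1 + chi^2); the +inf sentinel maps to 0."""
    chi = np.asarray(chi, float)
    eta = np.zeros(chi.shape)
    fin = np.isfinite(chi)
    eta[fin] = 1.0 / (1.0 + chi[fin] ** 2)
    return eta


def fields_on_grid(wf: Wavefunction, box=None, n_points: int = 150,
                   margin: float = 3.0, batch: int = 100_000,
                   keep_mo: bool = False) -> dict:
    """Evaluate rho, tau, chi and ELF on a uniform grid.

    Returns a dict of FieldGrid objects sharing origin/spacing.  The default
    box follows :func:`elfiqa.grids.default_box` with the given in-plane
    ``margin``.  With ``keep_mo`` the occupied-MO amplitudes on the grid are
    returned as well (float32, (npts, nmo)) so downstream basin integration
    can reuse the single evaluation pass.
    """
    if box is None:
        from .grids import default_box
        box = default_box(wf.coords, margin)
    lo, hi = box
    origin, spacing = grid_from_box(lo, hi, n_points)
    n = np.broadcast_to(np.asarray(n_points, int), (3,))
    shape = tuple(int(v) for v in n)
    npts = int(np.prod(shape))
    rho = np.empty(npts)
    tau = np.empty(npts)
    g2 = np.empty(npts)
    mo = np.empty((npts, wf.nmo), dtype=np.float32) if keep_mo else None
    ax = tuple(origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3))
    # stream in x-slabs to bound memory
    nz_per = max(1, batch // (shape[1] * shape[2]))
    pos = 0
    for x0 in range(0, shape[0], nz_per):
        x1 = min(x0 + nz_per, shape[0])
        X, Y, Z = np.meshgrid(ax[0][x0:x1], ax[1], ax[2], indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        ev = wf.evaluate(pts, batch=batch)
        m = len(pts)
        rho[pos:pos + m] = ev.rho
        tau[pos:pos + m] = ev.tau
        g2[pos:pos + m] = (ev.grad_rho ** 2).sum(axis=1)
        if keep_mo:
            mo[pos:pos + m] = ev.mo_values
        pos += m
    rho = rho.reshape(shape)
    tau = tau.reshape(shape)
    g2 = g2.reshape(shape)
    chi = np.full(shape, np.inf)
    ok = rho > DENSITY_FLOOR
    D = np.maximum(tau[ok] - g2[ok] / (8.0 * rho[ok]), 0.0)
    chi[ok] = D / (C_F * rho[ok] ** (5.0 / 3.0))
    eta = elf(chi)
    mk = lambda v, name: FieldGrid(origin, spacing, v, name)
    out = {"rho": mk(rho, "rho"), "tau": mk(tau, "tau"),
           "chi": mk(np.where(np.isfinite(chi), chi, 0.0), "chi"),
           "elf": mk(eta, "elf")}
    if keep_mo:
        out["mo"] = mo
    return out


def elf_on_grid(wf: Wavefunction, box=None, n_points: int = 150,
                margin: float = 3.0) -> FieldGrid:
    """ELF field on a uniform grid (150 points per axis by default)."""
    return fields_on_grid(wf, box=box, n_points=n_points, margin=margin)["elf"]
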