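"""Single-determinant wavefunctions over Gaussian-type orbitals.

Everything downstream (ELF, basins, populations, delocalization indices,
IQA terms) is computed from a closed-shell determinant: a set of contracted
cartesian Gaussian shells, the occupied molecular-orbital coefficients and
integer occupations.  All quantities are in atomic units (bohr, hartree).

Cartesian component order follows the Molden convention:
s; p: x, y, z; d: xx, yy, zz, xy, xz, yz.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Nucleus", "Shell", "Wavefunction", "PointBatchEvaluation",
    "make_toy_wavefunction", "ANGSTROM",
]

ANGSTROM = 1.8897261254578281  # bohr per angstrom

ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "Br": 35, "X": 0,
}
SYMBOLS = {v: k for k, v in ELEMENTS.items()}

# cartesian monomial exponents per angular momentum, Molden order
_COMP = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}
NCART = {0: 1, 1: 3, 2: 6}


def _double_fact(n: int) -> float:
    r = 1.0
    while n > 1:
        r *= n
        n -= 2
    return r


class WavefunctionError(Exception):
    """Raised for invalid or unsupported wavefunction input."""


@dataclass(frozen=True)
class Nucleus:
    symbol: str
    charge: float
    xyz: np.ndarray  # bohr

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, float))


@dataclass(frozen=True)
class Shell:
    """Contracted cartesian Gaussian shell.

    ``coefficients`` multiply *normalized* primitives and are scaled so the
    (l,0,0) component of the contraction has unit self-overlap; the
    remaining cartesian components receive a per-component factor so that
    every basis function is individually normalized.
    """
    center: int
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.exponents, float)
        c = np.asarray(self.coefficients, float)
        if self.l not in NCART:
            raise WavefunctionError(f"unsupported angular momentum l={self.l}")
        if np.any(e <= 0):
            raise WavefunctionError("primitive exponents must be positive")
        if e.shape != c.shape:
            raise WavefunctionError("exponent/coefficient length mismatch")
        object.__setattr__(self, "exponents", e)
        object.__setattr__(self, "coefficients", c)

    @property
    def ncart(self) -> int:
        return NCART[self.l]

    def normalized_coefficients(self) -> np.ndarray:
        """Contraction coefficients with primitive + contraction norms folded in."""
        l, e, c = self.l, self.exponents, self.coefficients.copy()
        c = c * (2 * e / np.pi) ** 0.75 * (4 * e) ** (l / 2.0) / np.sqrt(_double_fact(2 * l - 1))
        p = e[:, None] + e[None, :]
        self_ov = ((np.pi / p) ** 1.5 * _double_fact(2 * l - 1) / (2 * p) ** l
                   * c[:, None] * c[None, :]).sum()
        return c / np.sqrt(self_ov)

    def component_scales(self) -> np.ndarray:
        out = np.empty(self.ncart)
        for k, (lx, ly, lz) in enumerate(_COMP[self.l]):
            out[k] = np.sqrt(_double_fact(2 * self.l - 1) /
                             (_double_fact(2 * lx - 1) * _double_fact(2 * ly - 1)
                              * _double_fact(2 * lz - 1)))
        return out


@dataclass
class PointBatchEvaluation:
    """Fields evaluated on a batch of points (atomic units).

    rho: electron density; grad_rho: its gradient; tau: the positive-definite
    kinetic-energy density t = 1/2 sum_i n_i |grad phi_i|^2; mo_values:
    per-orbital amplitudes (npoints x nmo).
    """
    rho: np.ndarray
    grad_rho: np.ndarray
    tau: np.ndarray
    mo_values: np.ndarray


@dataclass
class Wavefunction:
    nuclei: list[Nucleus]
    shells: list[Shell]
    mo_coefficients: np.ndarray   # (nbf, nmo) occupied MOs only
    mo_occupations: np.ndarray    # electrons per MO
    net_charge: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mo_coefficients = np.asarray(self.mo_coefficients, float)
        self.mo_occupations = np.asarray(self.mo_occupations, float)
        if self.mo_coefficients.shape[0] != self.nbf:
            raise WavefunctionError(
                f"MO coefficient rows ({self.mo_coefficients.shape[0]}) do not match "
                f"basis size ({self.nbf})")
        if self.mo_coefficients.shape[1] != len(self.mo_occupations):
            raise WavefunctionError("MO count does not match occupation count")

    # ---------------------------------------------------------------- sizes
    @property
    def nbf(self) -> int:
        return sum(s.ncart for s in self.shells)

    @property
    def nmo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def total_electrons(self) -> float:
        return float(self.mo_occupations.sum())

    @property
    def coords(self) -> np.ndarray:
        return np.array([n.xyz for n in self.nuclei])

    # ------------------------------------------------------------- validity
    def overlap_matrix(self) -> np.ndarray:
        """Analytic basis overlap via 1D Hermite recursion."""
        nbf = self.nbf
        S = np.zeros((nbf, nbf))
        offs = np.cumsum([0] + [s.ncart for s in self.shells])
        for i, si in enumerate(self.shells):
            Ai = self.nuclei[si.center].xyz
            ci = si.normalized_coefficients()
            fi = si.component_scales()
            for j, sj in enumerate(self.shells[: i + 1]):
                Aj = self.nuclei[sj.center].xyz
                cj = sj.normalized_coefficients()
                fj = sj.component_scales()
                blk = np.zeros((si.ncart, sj.ncart))
                for ea, ca in zip(si.exponents, ci):
                    for eb, cb in zip(sj.exponents, cj):
                        p = ea + eb
                        P = (ea * Ai + eb * Aj) / p
                        e1d = [_hermite_e(si.l, sj.l, ea, eb, Ai[d] - Aj[d],
                                          P[d] - Ai[d], P[d] - Aj[d]) for d in range(3)]
                        pref = ca * cb * (np.pi / p) ** 1.5
                        for a, (lxa, lya, lza) in enumerate(_COMP[si.l]):
                            for b, (lxb, lyb, lzb) in enumerate(_COMP[sj.l]):
                                blk[a, b] += (pref * e1d[0][lxa, lxb, 0]
                                              * e1d[1][lya, lyb, 0] * e1d[2][lza, lzb, 0])
                blk *= fi[:, None] * fj[None, :]
                S[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = blk
                S[offs[j]:offs[j + 1], offs[i]:offs[i + 1]] = blk.T
        return S

    def orthonormality_residual(self) -> float:
        S = self.overlap_matrix()
        C = self.mo_coefficients
        return float(np.abs(C.T @ S @ C - np.eye(self.nmo)).max())

    def validate(self, tol: float = 1e-6):
        if np.any(self.mo_occupations <= 0):
            raise WavefunctionError("non-positive MO occupation")
        if not np.allclose(self.mo_occupations, 2.0):
            raise WavefunctionError(
                "only closed-shell determinants (occupation 2.0) are supported")
        r = self.orthonormality_residual()
        if r > tol:
            raise WavefunctionError(f"occupied MOs not orthonormal (residual {r:.2e})")
        nelec_nuc = sum(n.charge for n in self.nuclei) - self.net_charge
        if abs(self.total_electrons - nelec_nuc) > 1e-8:
            raise WavefunctionError(
                f"electron count {self.total_electrons} inconsistent with nuclei/charge "
                f"({nelec_nuc})")
        return self

    # ------------------------------------------------------------ evaluation
    def _flat_basis(self):
        """Flat numba-friendly shell arrays (built once, cached)."""
        if getattr(self, "_flat", None) is not None:
            return self._flat
        comp_off = np.array([0, 1, 4], dtype=np.int64)
        comp_lx = np.array([c[0] for l in (0, 1, 2) for c in _COMP[l]], dtype=np.int64)
        comp_ly = np.array([c[1] for l in (0, 1, 2) for c in _COMP[l]], dtype=np.int64)
        comp_lz = np.array([c[2] for l in (0, 1, 2) for c in _COMP[l]], dtype=np.int64)
        sc, sl, sps, snp, sao = [], [], [], [], []
        pe, pc, scale = [], [], []
        nbf = 0
        for sh in self.shells:
            cn = sh.normalized_coefficients()
            sc.append(sh.center)
            sl.append(sh.l)
            sps.append(len(pe))
            snp.append(len(sh.exponents))
            sao.append(nbf)
            pe.extend(sh.exponents)
            pc.extend(cn)
            scale.extend(sh.component_scales())
            nbf += sh.ncart
        self._flat = {
            "centers": np.array([n.xyz for n in self.nuclei], float),
            "shell_center": np.array(sc, np.int64),
            "shell_l": np.array(sl, np.int64),
            "shell_pstart": np.array(sps, np.int64),
            "shell_nprim": np.array(snp, np.int64),
            "shell_ao": np.array(sao, np.int64),
            "prim_exp": np.array(pe, float),
            "prim_coef": np.array(pc, float),
            "comp_lx": comp_lx, "comp_ly": comp_ly, "comp_lz": comp_lz,
            "comp_off": comp_off,
            "comp_scale": np.array(scale, float),
        }
        return self._flat

    def _basis_on_points(self, points: np.ndarray, deriv: bool = True):
        """Basis values and gradients at points: (npts, nbf) arrays."""
        from ._fast import eval_basis
        pts = np.ascontiguousarray(np.asarray(points, float))
        npts = len(pts)
        nbf = self.nbf
        fb = self._flat_basis()
        phi = np.empty((npts, nbf))
        grads = np.empty((3, npts, nbf))
        eval_basis(pts, fb["centers"], fb["shell_center"], fb["shell_l"],
                   fb["shell_pstart"], fb["shell_nprim"], fb["prim_exp"],
                   fb["prim_coef"], fb["comp_lx"], fb["comp_ly"], fb["comp_lz"],
                   fb["comp_off"], fb["comp_scale"], fb["shell_ao"], nbf,
                   phi, grads[0], grads[1], grads[2])
        if not deriv:
            return phi, None
        return phi, grads

    def evaluate(self, points: np.ndarray, batch: int = 100_000) -> PointBatchEvaluation:
        """Evaluate rho, grad rho, tau and MO amplitudes at arbitrary points."""
        pts = np.asarray(points, float)
        if pts.ndim == 1:
            pts = pts[None, :]
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        n = len(pts)
        occ = self.mo_occupations
        rho = np.empty(n)
        grad = np.empty((n, 3))
        tau = np.empty(n)
        mos = np.empty((n, self.nmo))
        C = self.mo_coefficients
        for s in range(0, n, batch):
            sl = slice(s, min(s + batch, n))
            phi, g = self._basis_on_points(pts[sl])
            mo = phi @ C
            mog = np.stack([g[m] @ C for m in range(3)])   # (3, b, nmo)
            rho[sl] = (occ * mo ** 2).sum(axis=1)
            for m in range(3):
                grad[sl, m] = 2.0 * (occ * mo * mog[m]).sum(axis=1)
            tau[sl] = 0.5 * (occ * (mog ** 2).sum(axis=0)).sum(axis=1)
            mos[sl] = mo
        return PointBatchEvaluation(rho=rho, grad_rho=grad, tau=tau, mo_values=mos)


def evaluate_fields(wf: Wavefunction, points: np.ndarray) -> PointBatchEvaluation:
    """Functional form of :meth:`Wavefunction.evaluate`."""
    return wf.evaluate(points)


def _hermite_e(l1, l2, a, b, AB, XPA, XPB):
    """1D Hermite expansion coefficients e[i, j, t] (overlap only needs t=0)."""
    p = a + b
    e = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 1))
    e[0, 0, 0] = np.exp(-a * b / p * AB * AB)
    inv2p = 0.5 / p
    for i in range(l1):
        for t in range(i + 2):
            v = XPA * e[i, 0, t]
            if t > 0:
                v += inv2p * e[i, 0, t - 1]
            if t + 1 <= i:
                v += (t + 1) * e[i, 0, t + 1]
            e[i + 1, 0, t] = v
    for i in range(l1 + 1):
        for j in range(l2):
            for t in range(i + j + 2):
                v = XPB * e[i, j, t]
                if t > 0:
                    v += inv2p * e[i, j, t - 1]
                if t + 1 <= i + j:
                    v += (t + 1) * e[i, j, t + 1]
                e[i, j + 1, t] = v
    return e


# --------------------------------------------------------------------- toys
def make_toy_wavefunction(kind: str, **params) -> Wavefunction:
    """Analytic toy determinants with closed-form properties.

    one_orbital_bond: two s-Gaussians on two centers combined into a single
        doubly occupied bonding MO; ELF is identically 1 wherever the density
        is above the floor (single-orbital closed shell).
    two_orbital_model: two doubly occupied orthogonal MOs (g/u combinations
        of the same two s-Gaussians), 4 electrons.
    atomlike: two well-separated radial shells on one center (a tight and a
        diffuse s-orbital), giving a core/valence-like ELF shell structure.
    """
    if kind == "one_orbital_bond":
        alpha = params.get("alpha", 1.0)
        dist = params.get("distance", 1.4)
        return _two_center_toy(alpha, dist, n_mo=1)
    if kind == "two_orbital_model":
        alpha = params.get("alpha", 1.0)
        dist = params.get("distance", 3.0)
        return _two_center_toy(alpha, dist, n_mo=2)
    if kind == "atomlike":
        a_core = params.get("alpha_core", 40.0)
        a_val = params.get("alpha_valence", 0.6)
        nuc = [Nucleus("X", 4.0, np.zeros(3))]
        shells = [Shell(0, 0, np.array([a_core]), np.array([1.0])),
                  Shell(0, 0, np.array([a_val]), np.array([1.0]))]
        wf = Wavefunction(nuc, shells, np.zeros((2, 2)), np.array([2.0, 2.0]), 0,
                          meta={"kind": kind})
        S = wf.overlap_matrix()
        C = _symmetric_orthonormalize(np.eye(2), S)
        wf.mo_coefficients = C
        return wf
    raise WavefunctionError(f"unknown toy kind: {kind!r}")


def _two_center_toy(alpha: float, dist: float, n_mo: int) -> Wavefunction:
    if alpha <= 0:
        raise WavefunctionError("exponent must be positive")
    za = n_mo  # formal nuclear charge per center to balance electrons
    nuc = [Nucleus("X", float(za), np.array([0.0, 0.0, -dist / 2])),
           Nucleus("X", float(za), np.array([0.0, 0.0, +dist / 2]))]
    shells = [Shell(0, 0, np.array([alpha]), np.array([1.0])),
              Shell(1, 0, np.array([alpha]), np.array([1.0]))]
    wf = Wavefunction(nuc, shells, np.zeros((2, n_mo)), np.full(n_mo, 2.0), 0,
                      meta={"kind": "one_orbital_bond" if n_mo == 1 else "two_orbital_model",
                            "alpha": alpha, "distance": dist})
    S = wf.overlap_matrix()
    s = S[0, 1]
    cols = [np.array([1.0, 1.0]) / np.sqrt(2 * (1 + s))]
    if n_mo == 2:
        cols.append(np.array([1.0, -1.0]) / np.sqrt(2 * (1 - s)))
    wf.mo_coefficients = np.column_stack(cols)
    return wf


def _symmetric_orthonormalize(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Lowdin-orthonormalize the column span of C under metric S."""
    M = C.T @ S @ C
    w, U = np.linalg.eigh(M)
    return C @ U @ np.diag(w ** -0.5) @ U.T
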