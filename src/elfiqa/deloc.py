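"""Delocalization indices from domain overlap matrices.

For a closed-shell single determinant the number of electron pairs shared
between domains A and B is delta(A,B) = 4 sum_ij S^A_ij S^B_ij, and the
localization index lambda(A) = 2 sum_ij (S^A_ij)^2; together they satisfy
lambda(A) + 1/2 sum_B delta(A,B) = n_A.  delta(A,B) equals -2 cov(n_A, n_B),
the (negative twice) covariance of the basin electron populations, which the
grid-based oracle below verifies by brute force on small systems.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basins import BasinPartition, RingLabeling
from .observables import BasinObservables
from .wavefunction import Wavefunction

__all__ = ["DIMatrix", "di_matrix", "vicinal_di", "covariance_oracle"]


@dataclass
class DIMatrix:
    basin_ids: np.ndarray
    delta: np.ndarray       # (nb, nb), zero diagonal
    lam: np.ndarray         # (nb,) localization indices
    names: list

    def get(self, a: int, b: int) -> float:
        ia = int(np.flatnonzero(self.basin_ids == a)[0])
        ib = int(np.flatnonzero(self.basin_ids == b)[0])
        return float(self.delta[ia, ib])

    def sum_rule_residual(self, populations: np.ndarray) -> np.ndarray:
        """lambda(A) + 1/2 sum_B delta(A,B) - n_A per basin."""
        return self.lam + 0.5 * self.delta.sum(axis=1) - populations

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.delta, index=self.names, columns=self.names)


def di_matrix(obs: BasinObservables) -> DIMatrix:
    """delta(A,B) = 4 sum_ij S^A_ij S^B_ij (A != B), lambda(A) = 2 sum (S^A)^2."""
    S = obs.overlaps
    nb = S.shape[0]
    flat = S.reshape(nb, -1)
    cross = flat @ flat.T
    delta = 4.0 * cross
    lam = 2.0 * np.diag(cross).copy()
    np.fill_diagonal(delta, 0.0)
    return DIMatrix(basin_ids=obs.basin_ids.copy(), delta=delta, lam=lam,
                    names=list(obs.names))


def vicinal_di(di: DIMatrix, ring: RingLabeling, average: bool = True) -> dict:
    """DI between adjacent ring bond basins, keyed by the shared carbon.

    DI(i) couples b61/b12 (shared atom C1, the ipso carbon); DI(o) averages
    the two ortho-centred pairs (b12,b23) and (b56,b61); DI(m) the two
    meta-centred pairs; DI(p) is the single para pair (b34,b45).
    """
    b = {k: ring.bond_basin_map[k] for k in RingLabeling.BOND_KEYS}
    pairs = {
        "i": [("b61", "b12")],
        "o": [("b12", "b23"), ("b56", "b61")],
        "m": [("b23", "b34"), ("b45", "b56")],
        "p": [("b34", "b45")],
    }
    out = {}
    raw = {}
    for key, plist in pairs.items():
        vals = [di.get(b[x], b[y]) for x, y in plist]
        raw[key] = vals
        out[key] = float(np.mean(vals)) if average else vals
    out["raw"] = raw
    return out


def covariance_oracle(partition: BasinPartition, wf: Wavefunction,
                      basin_a: int, basin_b: int, block: int = 4096) -> float:
    """-2 cov(n_A, n_B) by brute-force pair-density integration on the grid.

    The closed-shell single-determinant pair density is
    rho2(r1, r2) = rho(r1) rho(r2) - |rho1(r1; r2)|^2 / 2 with
    rho1(r1; r2) = 2 sum_i phi_i(r1) phi_i(r2); the one-matrix square is
    summed voxel-by-voxel over A x B without factorizing through overlap
    matrices.  Restricted to small toys (<= 2 occupied MOs).
    """
    if wf.nmo > 2:
        raise ValueError("covariance oracle is restricted to toys with <= 2 MOs")
    grid = partition.labels
    labels = grid.values.ravel()
    dv = grid.voxel_volume
    pts = grid.points()
    in_a = labels == basin_a
    in_b = labels == basin_b
    ev_a = wf.evaluate(pts[in_a])
    ev_b = wf.evaluate(pts[in_b]) if basin_b != basin_a else ev_a
    # integral over AxB of |rho1|^2 / 2, blockwise outer products
    phi_a = ev_a.mo_values
    phi_b = ev_b.mo_values
    acc = 0.0
    for s in range(0, len(phi_a), block):
        rho1_blk = 2.0 * phi_a[s:s + block] @ phi_b.T
        acc += float((rho1_blk ** 2).sum())
    int_rho1sq = 0.5 * acc * dv * dv
    n_a = ev_a.rho.sum() * dv
    n_b = ev_b.rho.sum() * dv
    # cov(n_A, n_B) = int_AxB (rho2 - rho rho) + delta_AB n_A
    cov = (n_a * n_b - int_rho1sq) - n_a * n_b
    if basin_a == basin_b:
        cov += n_a
    return -2.0 * cov
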