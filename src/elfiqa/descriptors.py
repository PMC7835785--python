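"""Ring descriptors for electrophilic aromatic substitution.

From the labeled ring-bond basins this module assembles: symmetry-averaged
bond populations n_ij and kinetic energies t_ij, their changes against an
unsubstituted-benzene reference, the vicinal delocalization descriptors
DI(a) for a = ipso/ortho/meta/para, the inductive-vs-mesomeric pattern of
the population profile, the predicted attack orientation, and the
correlation of DI(m) - DI(p) with Hammett sigma_m - sigma_p constants.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["symmetry_average", "classify_pattern", "predict_orientation",
           "hammett_regression", "build_report", "RingDescriptorSet",
           "HammettRecord", "RegressionError", "ReferenceMismatchError",
           "POP_EPS", "DI_EPS"]

POP_EPS = 0.01    # e: tolerance for population pattern classification
DI_EPS = 0.005    # tolerance on delta-DI signs
SPREAD_WARN = 0.1  # e: intra-pair spread above this flags possible mislabeling


class RegressionError(Exception):
    pass


class ReferenceMismatchError(Exception):
    pass


@dataclass
class HammettRecord:
    substituent: str
    sigma_m: float
    sigma_p: float
    di_m: float
    di_p: float


@dataclass
class RingDescriptorSet:
    molecule: str
    n_ij: dict                    # b12..b61 -> population
    t_ij: dict                    # b12..b61 -> kinetic energy
    n_avg: dict                   # q12, q23, q34 symmetry-averaged populations
    t_avg: dict
    mean_ring_population: float
    spread_flags: list
    di: dict                      # i/o/m/p -> DI(a)
    delta_n: dict | None = None
    delta_di: dict | None = None
    delta_t_over_n: dict | None = None   # keyed 12/23/34
    pattern: str = "unclassified"
    orientation: str = "unclassified"
    settings_hash: str = ""

    def as_dict(self):
        return asdict(self)


def symmetry_average(values: dict, warn_spread: float = SPREAD_WARN):
    """Average the mirror-equivalent ring bond pairs.

    q12 = mean(b12, b61), q23 = mean(b23, b56), q34 = mean(b34, b45);
    near-equivalent values can come out slightly dissimilar on a finite grid
    and are averaged, with the intra-pair spread reported (flagged above the
    threshold, still computed).
    """
    missing = [k for k in ("b12", "b23", "b34", "b45", "b56", "b61")
               if k not in values]
    if missing:
        raise KeyError(f"missing ring bond values: {missing}")
    pairs = {"q12": ("b12", "b61"), "q23": ("b23", "b56"), "q34": ("b34", "b45")}
    out, spreads, flags = {}, {}, []
    for q, (x, y) in pairs.items():
        out[q] = 0.5 * (values[x] + values[y])
        spreads[q] = abs(values[x] - values[y])
        if spreads[q] > warn_spread:
            flags.append(q)
    return out, spreads, flags


def classify_pattern(q12: float, q23: float, q34: float,
                     eps: float = POP_EPS) -> str:
    """Inductive decay (monotone fall-off with distance from the substituent)
    versus mesomeric oscillation (maximum at the 2-3 bond)."""
    if q12 > q23 + eps and q23 > q34 + eps:
        return "inductive_decay"
    if q23 > q12 + eps and q23 > q34 + eps:
        return "mesomeric_oscillatory"
    return "mixed"


def predict_orientation(d_o: float, d_m: float, d_p: float,
                        eps: float = DI_EPS) -> str:
    """Orientation from the signs of the delta-DI(o/m/p) descriptors:
    (+,-,+) marks ortho/para directors; negative ortho and para marks meta."""
    if d_o > eps and d_m < -eps and d_p > eps:
        return "ortho_para"
    if d_o < -eps and d_p < -eps:
        return "meta"
    return "indeterminate"


def hammett_regression(records):
    """OLS of (sigma_m - sigma_p) on (DI(m) - DI(p)) across substituents."""
    recs = list(records)
    if len(recs) < 3:
        raise RegressionError("need at least 3 substituents for the regression")
    x = np.array([r.di_m - r.di_p for r in recs])
    y = np.array([r.sigma_m - r.sigma_p for r in recs])
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in DI(m) - DI(p)")
    from scipy import stats
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "residuals": resid,
            "substituents": [r.substituent for r in recs]}


def build_report(analysis, reference=None, name: str = "") -> RingDescriptorSet:
    """Assemble the descriptor set for one analyzed molecule.

    ``analysis`` is a RingAnalysis (see pipeline); ``reference`` the benzene
    RingDescriptorSet computed with identical settings (hash-checked), or
    None to emit absolute values only.
    """
    nij = analysis.bond_populations()
    tij = analysis.bond_kinetic()
    n_avg, n_spread, flags_n = symmetry_average(nij)
    t_avg, _, flags_t = symmetry_average(tij)
    di = analysis.vicinal_di()
    out = RingDescriptorSet(
        molecule=name or analysis.name,
        n_ij=nij, t_ij=tij, n_avg=n_avg, t_avg=t_avg,
        mean_ring_population=float(np.mean(list(nij.values()))),
        spread_flags=sorted(set(flags_n + flags_t)),
        di={k: di[k] for k in ("i", "o", "m", "p")},
        settings_hash=analysis.settings_hash,
    )
    out.pattern = classify_pattern(n_avg["q12"], n_avg["q23"], n_avg["q34"])
    if reference is not None:
        if reference.settings_hash != analysis.settings_hash:
            raise ReferenceMismatchError(
                f"reference computed with different settings "
                f"({reference.settings_hash} != {analysis.settings_hash})")
        out.delta_n = {q: out.n_avg[q] - reference.n_avg[q] for q in out.n_avg}
        out.delta_di = {a: out.di[a] - reference.di[a] for a in out.di}
        out.delta_t_over_n = {
            q[1:]: out.t_avg[q] / out.n_avg[q] - reference.t_avg[q] / reference.n_avg[q]
            for q in ("q12", "q23", "q34")}
        out.orientation = predict_orientation(
            out.delta_di["o"], out.delta_di["m"], out.delta_di["p"])
    return out
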