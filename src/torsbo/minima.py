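"""Local-minima extraction from the learned surrogate and duplicate purging.

Conformers beyond the global minimum are the local minima of the GP
posterior mean.  They are located by multi-start L-BFGS-B minimization
(acquisition locations as default starts) using the analytic posterior
gradient; near-identical hits are merged by greedy periodic-distance
clustering, keeping the deepest representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import periodic_distance, wrap_angle

#: gradient-norm tolerance defining "is a minimum" on the surrogate, eV/deg
GRAD_TOL = 1e-4

#: duplicate-merging defaults: periodic angular and energy tolerance
D_TOL_DEFAULT = 15.0
E_TOL_DEFAULT = 0.01


@dataclass
class MinimumCandidate:
    torsions: np.ndarray
    energy: float               # surrogate posterior-mean energy, eV
    start_index: int
    grad_norm: float
    converged: bool

    def distance_to(self, other: "MinimumCandidate") -> np.ndarray:
        return np.array([periodic_distance(a, b)
                         for a, b in zip(self.torsions, other.torsions)])


def extract_minima(model, start_points=None, *,
                   grad_tol: float = GRAD_TOL) -> list[MinimumCandidate]:
    """Multi-start local minimization of the posterior mean.

    `start_points` defaults to all training (acquisition) inputs.  Starts
    whose minimizer does not reach `grad_tol` are flagged and dropped.
    """
    starts = model.X if start_points is None else np.atleast_2d(start_points)
    out = []
    for idx, x0 in enumerate(starts):
        res = minimize(model.posterior_mean_and_gradient, np.asarray(x0, float),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "gtol": grad_tol * 1e-2})
        grad = model.posterior_gradient(res.x)
        gnorm = float(np.linalg.norm(grad))
        # a quasi-Newton start placed exactly on a saddle or maximum is a
        # fixed point too: require non-negative curvature as well
        is_min = gnorm < grad_tol and _is_local_minimum(model, res.x)
        cand = MinimumCandidate(
            torsions=np.atleast_1d(wrap_angle(np.asarray(res.x))),
            energy=float(res.fun), start_index=idx,
            grad_norm=gnorm, converged=is_min)
        if cand.converged:
            out.append(cand)
    return out


def _is_local_minimum(model, x, h: float = 0.5, tol: float = 1e-8) -> bool:
    """Positive-semidefinite numeric Hessian of the posterior mean at x."""
    x = np.asarray(x, float)
    d = len(x)
    H = np.empty((d, d))
    for j in range(d):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (model.posterior_gradient(xp)
                   - model.posterior_gradient(xm)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    eigs = np.linalg.eigvalsh(H)
    scale = max(np.max(np.abs(eigs)), 1.0)
    return bool(eigs[0] > -tol * scale)


def purge_duplicates(candidates: list[MinimumCandidate],
                     d_tol: float = D_TOL_DEFAULT,
                     E_tol: float = E_TOL_DEFAULT) -> list[MinimumCandidate]:
    """Greedy clustering in ascending energy order.

    Two candidates are duplicates when every dihedral differs by less than
    `d_tol` (periodic) and their energies by less than `E_tol`; the
    lowest-energy representative survives.  Idempotent; output sorted
    ascending by energy.
    """
    if d_tol <= 0 or E_tol <= 0:
        raise ValueError("tolerances must be > 0")
    ordered = sorted(candidates, key=lambda c: c.energy)
    kept: list[MinimumCandidate] = []
    for cand in ordered:
        dup = False
        for rep in kept:
            if (abs(cand.energy - rep.energy) < E_tol
                    and np.all(cand.distance_to(rep) < d_tol)):
                dup = True
                break
        if not dup:
            kept.append(cand)
    return kept


def energy_vs_index_curve(minima_by_budget: dict[int, list[MinimumCandidate]],
                          ceiling: float = 0.25):
    """Energy-versus-conformer-index curves and their budget-to-budget drift.

    For each budget the minima energies are sorted ascending and referenced
    to that budget's own minimum.  The returned deviation between consecutive
    budgets is the symmetric Hausdorff distance between the two sets of
    relative energies below `ceiling` (eV): it is 0 for identical or
    uniformly shifted sets, and equals the relative energy scale of any
    minimum present in one budget but absent from the other.
    """
    curves: dict[int, np.ndarray] = {}
    for budget, minima in minima_by_budget.items():
        e = np.sort([m.energy for m in minima])
        curves[budget] = e - e[0] if len(e) else e
    budgets = sorted(curves)
    deviations = {}
    for b0, b1 in zip(budgets[:-1], budgets[1:]):
        a = curves[b0][curves[b0] < ceiling]
        b = curves[b1][curves[b1] < ceiling]
        deviations[(b0, b1)] = _hausdorff(a, b)
    return curves, deviations


def _hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return float(np.max(np.concatenate([a, b])))
    d_ab = np.max([np.min(np.abs(b - x)) for x in a])
    d_ba = np.max([np.min(np.abs(a - x)) for x in b])
    return float(max(d_ab, d_ba))


def minima_to_dataframe(minima: list[MinimumCandidate]):
    import pandas as pd
    rows = []
    e0 = min((m.energy for m in minima), default=0.0)
    for i, m in enumerate(sorted(minima, key=lambda c: c.energy)):
        row = {"index": i}
        for k, v in enumerate(m.torsions):
            row[f"d{k + 1}"] = v
        row["surrogate_E"] = m.energy
        row["relative_E"] = m.energy - e0
        rows.append(row)
    return pd.DataFrame(rows)
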