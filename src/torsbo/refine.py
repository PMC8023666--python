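"""Candidate refinement: relaxation, harmonic vibrations, energy hierarchy.

After the torsion-space search, every surviving conformer candidate is
(1) relaxed with all Cartesian degrees of freedom free until the maximum
residual per-atom force drops below ``fmax`` (default 0.01 eV/Å),
(2) given a harmonic vibrational analysis — mass-weighted Hessian from
central finite differences of the forces (displacement 0.0025 Å),
rigid-body modes projected out, frequencies from the eigenvalues — and
(3) assigned harmonic free-energy corrections

    F_vib(T) = sum_i [ hbar w_i / 2 + k_B T ln(1 - exp(-hbar w_i / k_B T)) ]

whose T = 0 limit is the zero-point energy.  Optional high-level
single-point deltas (e.g. a coupled-cluster correction, Delta = E_high -
E_opt) refine the final ranking.  The staged hierarchy — search energy,
relaxed, +VE(0 K), +VE(300 K), +Delta — references each stage to its own
most stable conformer.

Units: energies eV, forces eV/Å, masses amu, temperatures K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.optimize import minimize

from .errors import CalculatorError, NonConvergenceError, TorsboError

K_B = 8.617333262e-5                       # eV / K

# hbar * sqrt(eV / (amu * A^2)) in eV: converts sqrt(Hessian eigenvalue)
# in our internal units to a vibrational quantum hbar*omega in eV
_HBAR_EVS = constants.hbar / constants.eV
_OMEGA_TO_EV = _HBAR_EVS * math.sqrt(
    constants.eV / (constants.atomic_mass * 1e-20))

#: modes with |hbar w| below 10 cm^-1 are treated as numerically zero
ZERO_MODE_EV = 10.0 * 1.239841984e-4

FMAX_DEFAULT = 0.01                        # eV/A
DELTA_DEFAULT = 0.0025                     # A, finite-difference displacement

STAGES = ("search", "optimized", "+VE(0K)", "+VE(300K)", "+delta")


def relax_structure(calculator, coords: np.ndarray,
                    fmax: float = FMAX_DEFAULT,
                    max_steps: int = 500) -> tuple[np.ndarray, float]:
    """Quasi-Newton relaxation of all Cartesian degrees of freedom.

    Stops when the maximum per-atom force norm is below `fmax`; an input
    already below `fmax` is returned unchanged in zero steps.  Raises
    :class:`NonConvergenceError` (carrying the last geometry) on step-limit
    exhaustion.
    """
    if fmax <= 0:
        raise ValueError("fmax must be > 0")
    x0 = np.asarray(coords, dtype=float)
    n = len(x0)
    e0, f0 = calculator.energy_and_forces(x0)
    if not np.isfinite(e0) or not np.all(np.isfinite(f0)):
        raise CalculatorError("non-finite energy/forces at the start geometry")
    if _fmax(f0) < fmax:
        return x0.copy(), float(e0)

    def fun(flat):
        e, f = calculator.energy_and_forces(flat.reshape(n, 3))
        if not np.isfinite(e):
            raise CalculatorError("non-finite energy during relaxation")
        return e, -f.ravel()

    res = minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_steps, "maxcor": 20,
                            "ftol": 1e-14, "gtol": 1e-10})
    geom = res.x.reshape(n, 3)
    e, f = calculator.energy_and_forces(geom)
    if _fmax(f) >= fmax:
        raise NonConvergenceError(
            f"relaxation stalled at fmax={_fmax(f):.2e} eV/A "
            f"after {res.nit} steps", geometry=geom, energy=float(e))
    return geom, float(e)


def _fmax(forces: np.ndarray) -> float:
    return float(np.max(np.linalg.norm(np.atleast_2d(forces), axis=1)))


def hessian_finite_difference(calculator, coords: np.ndarray,
                              masses: np.ndarray,
                              delta: float = DELTA_DEFAULT) -> np.ndarray:
    """Mass-weighted Hessian from central finite differences of the forces.

    H_ij = -dF_j/dx_i evaluated as (F(x - d e_i) - F(x + d e_i)) / (2 d),
    symmetrized as (H + H^T)/2 and weighted by 1/sqrt(m_i m_j).
    Units: eV / (amu Å^2).
    """
    if delta <= 0:
        raise ValueError("displacement delta must be > 0")
    x = np.asarray(coords, dtype=float)
    n = len(x)
    ndof = 3 * n
    H = np.empty((ndof, ndof))
    flat = x.ravel()
    for i in range(ndof):
        for sign, store in ((+1, 0), (-1, 1)):
            disp = flat.copy()
            disp[i] += sign * delta
            try:
                _, f = calculator.energy_and_forces(disp.reshape(n, 3))
            except Exception as exc:
                raise CalculatorError(
                    f"calculator failed at displacement {i} "
                    f"({'+' if sign > 0 else '-'}{delta} A): {exc}") from exc
            if store == 0:
                fplus = np.asarray(f).ravel()
            else:
                fminus = np.asarray(f).ravel()
        H[i, :] = (fminus - fplus) / (2.0 * delta)
    H = 0.5 * (H + H.T)
    m = np.repeat(np.asarray(masses, dtype=float), 3)
    return H / np.sqrt(np.outer(m, m))


def _rigid_body_vectors(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation + rotation vectors (Eckart)."""
    x = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    n = len(x)
    sq = np.sqrt(m)
    com = np.sum(x * m[:, None], axis=0) / np.sum(m)
    r = x - com
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = sq
        vecs.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        v = np.cross(r, e) * sq[:, None]
        vecs.append(v.ravel())
    V = np.array(vecs).T                   # (3n, 6)
    # orthonormalize, dropping rank-deficient directions (atoms, linear mols)
    q, s, _ = np.linalg.svd(V, full_matrices=False)
    keep = s > 1e-8 * s[0]
    return q[:, keep]


@dataclass
class VibrationalResult:
    """Harmonic normal-mode analysis of one relaxed conformer."""

    frequencies: np.ndarray        # retained hbar*omega_i, eV
    n_imaginary: int
    n_zero: int
    suspicious: bool = False       # more rigid-body-like modes than expected
    imaginary_frequencies: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    @property
    def zero_point_energy(self) -> float:
        return float(np.sum(self.frequencies) / 2.0)

    def free_energy(self, T: float) -> float:
        return vibrational_free_energy(self.frequencies, T)


def normal_modes(hessian_mw: np.ndarray, coords: np.ndarray,
                 masses: np.ndarray,
                 zero_mode_ev: float = ZERO_MODE_EV) -> VibrationalResult:
    """Frequencies from a mass-weighted Hessian with rigid-body projection.

    Translations and rotations are projected out before diagonalization.
    Eigenvalues whose |hbar w| falls below `zero_mode_ev` count as zero;
    more negative ones are imaginary — reported, flagged and excluded from
    the thermodynamics.
    """
    H = np.asarray(hessian_mw, dtype=float)
    if not np.allclose(H, H.T, atol=1e-10):
        H = 0.5 * (H + H.T)
    Q = _rigid_body_vectors(coords, masses)
    P = np.eye(H.shape[0]) - Q @ Q.T
    eigvals = np.linalg.eigvalsh(P @ H @ P)
    n_rigid = Q.shape[1]
    # drop the projected-out rigid modes (the n_rigid eigenvalues nearest 0)
    order = np.argsort(np.abs(eigvals))
    internal = np.sort(eigvals[order[n_rigid:]])
    lam_zero = (zero_mode_ev / _OMEGA_TO_EV) ** 2
    freqs, n_zero, imag = [], 0, []
    for lam in internal:
        if lam > lam_zero:
            freqs.append(math.sqrt(lam) * _OMEGA_TO_EV)
        elif lam < -lam_zero:
            imag.append(math.sqrt(-lam) * _OMEGA_TO_EV)
        else:
            n_zero += 1
    # after projection every remaining near-zero or negative mode is suspect:
    # the geometry is probably not a true minimum, or the Hessian is noisy
    suspicious = (n_zero + len(imag)) > 0
    return VibrationalResult(
        frequencies=np.array(freqs), n_imaginary=len(imag), n_zero=n_zero,
        suspicious=suspicious, imaginary_frequencies=np.array(imag))


def vibrational_free_energy(frequencies: np.ndarray, T: float) -> float:
    """Harmonic vibrational free energy (eV) of a discrete mode set.

    F_vib(T) = sum_i [hbar w_i/2 + k_B T ln(1 - exp(-hbar w_i/(k_B T)))];
    at T = 0 the thermal term vanishes and F_vib equals the zero-point
    energy.  Strictly decreasing in T for any nonempty mode set.
    """
    w = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(w <= 0):
        raise ValueError("frequencies must be positive")
    if T < 0:
        raise ValueError("temperature must be >= 0")
    zpe = float(np.sum(w) / 2.0)
    if T == 0 or len(w) == 0:
        return zpe
    kt = K_B * T
    return zpe + float(kt * np.sum(np.log1p(-np.exp(-w / kt))))


# ---------------------------------------------------------------------------
# hierarchy assembly
# ---------------------------------------------------------------------------

@dataclass
class ConformerRecord:
    """One conformer with its per-stage energies and corrections."""

    label: str
    geometry: np.ndarray | None = None
    search_energy: float | None = None     # surrogate energy from the search
    e_opt: float | None = None             # relaxed energy
    zpe: float | None = None
    f_vib: float | None = None             # F_vib(T), includes the ZPE
    temperature: float = 300.0
    delta_highlevel: float | None = None   # E_high - E_opt

    def stage_energy(self, stage: str) -> float | None:
        if stage == "search":
            return self.search_energy
        if self.e_opt is None:
            return None
        if stage == "optimized":
            return self.e_opt
        if stage == "+VE(0K)":
            return None if self.zpe is None else self.e_opt + self.zpe
        if stage == "+VE(300K)":
            return None if self.f_vib is None else self.e_opt + self.f_vib
        if stage == "+delta":
            if self.f_vib is None or self.delta_highlevel is None:
                return None
            return self.e_opt + self.f_vib + self.delta_highlevel
        raise ValueError(f"unknown stage {stage!r}")


def apply_singlepoint_delta(records: list[ConformerRecord],
                            highlevel_energies: dict[str, float]
                            ) -> list[ConformerRecord]:
    """Attach high-level single-point corrections Delta = E_high - E_opt.

    The mapping usually covers only the lowest-energy conformers; records
    without a delta are simply excluded from the final stage.  A label in
    the mapping with no matching record is an error.
    """
    labels = {r.label for r in records}
    unmatched = sorted(set(highlevel_energies) - labels)
    if unmatched:
        raise TorsboError(f"high-level energies for unknown labels: {unmatched}")
    for r in records:
        if r.label in highlevel_energies:
            if r.e_opt is None:
                raise TorsboError(f"record {r.label} has no relaxed energy")
            r.delta_highlevel = highlevel_energies[r.label] - r.e_opt
    return records


def assemble_hierarchy(records: list[ConformerRecord]):
    """Staged ranking table as a pandas DataFrame.

    For each stage the most stable conformer defines the zero of energy;
    ranks ascend with energy, ties broken by label.  Records missing a
    stage's ingredients are absent from that stage's columns (NaN).
    """
    import pandas as pd
    if not records:
        raise ValueError("no conformer records")
    recs = sorted(records, key=lambda r: r.label)
    out = pd.DataFrame({"label": [r.label for r in recs],
                        "E_opt": [r.e_opt for r in recs],
                        "ZPE": [r.zpe for r in recs],
                        "F_vib": [r.f_vib for r in recs],
                        "delta": [r.delta_highlevel for r in recs]})
    for stage in STAGES:
        e = np.array([r.stage_energy(stage) for r in recs], dtype=object)
        e = np.array([np.nan if v is None else float(v) for v in e])
        if np.all(np.isnan(e)):
            out[f"rel_{stage}"] = e
            out[f"rank_{stage}"] = np.nan
            continue
        rel = e - np.nanmin(e)
        out[f"rel_{stage}"] = rel
        valid = ~np.isnan(rel)
        order = sorted(np.flatnonzero(valid),
                       key=lambda i: (rel[i], recs[i].label))
        rank = np.full(len(recs), np.nan)
        for pos, i in enumerate(order, start=1):
            rank[i] = pos
        out[f"rank_{stage}"] = rank
    return out
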