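"""Active-learning Bayesian-optimization loop over torsion space.

Each iteration fits the GP surrogate to all energies observed so far
(shifted to be relative to the lowest observation and damped through the
high-energy log transform), minimizes the exploratory lower confidence
bound acquisition function

    eLCB(x) = mu(x) - sqrt(beta_t) * sigma(x)

by seeded multi-start L-BFGS-B, evaluates the true energy there, and
tracks the surrogate's predicted global minimum.  Convergence is declared
when, over a trailing window, the predicted-minimum energy moves by less
than dE_tol and every predicted dihedral by less than dd_tol (periodic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from . import gp
from .errors import AcquisitionError, CalculatorError
from .geometry import periodic_distance, wrap_angle

logger = logging.getLogger(__name__)

#: relative energy assigned to failed (non-finite) evaluations, eV
FAILURE_ENERGY = 1e6


@dataclass
class SearchConfig:
    """Knobs of the BO search; defaults are the adopted study conditions."""

    budget: int = 50                    # total evaluations incl. initial design
    n_init: int | None = None           # default max(5, 2N)
    e_cut: float = 2.0                  # eV, high-energy damping threshold
    de_tol: float = 0.025               # eV, convergence energy tolerance
    dd_tol: float = 10.0                # deg, convergence dihedral tolerance
    window: int = 5                     # trailing iterations for convergence
    seed: int = 0
    n_acq_starts: int = 12              # multi-start count for acquisition
    refit_every_after: int = 200        # refit every iter up to here, then /10
    continuous_transform: bool = False  # smooth variant of the damping
    stop_on_convergence: bool = True
    beta_delta: float = 0.1             # exploration schedule confidence level

    def initial_points(self, dim: int) -> int:
        n = self.n_init if self.n_init is not None else max(5, 2 * dim)
        if not self.budget >= n >= 2:
            raise ValueError("budget >= n_init >= 2 required")
        return n

    def validate(self):
        if self.e_cut <= 0:
            raise ValueError("e_cut must be > 0")
        if self.de_tol <= 0 or self.dd_tol <= 0:
            raise ValueError("convergence tolerances must be > 0")


@dataclass
class IterationRecord:
    iteration: int                      # 1-based, counts every evaluation
    torsions: np.ndarray
    energy_raw: float
    energy_transformed: float
    best_energy: float                  # lowest raw energy so far
    predicted_min_torsions: np.ndarray | None = None
    predicted_min_energy: float | None = None
    transformed: bool = False           # damping branch taken
    failed: bool = False


@dataclass
class SearchTrace:
    records: list[IterationRecord] = field(default_factory=list)
    convergence_iteration: int | None = None
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def best_energy(self) -> float:
        return self.records[-1].best_energy

    @property
    def fraction_transformed(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.transformed for r in self.records) / len(self.records)

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for r in self.records:
            row = {"iteration": r.iteration}
            for k, v in enumerate(r.torsions):
                row[f"d{k + 1}"] = v
            row.update(E_raw=r.energy_raw, E_transformed=r.energy_transformed,
                       best_E=r.best_energy, transformed=r.transformed,
                       failed=r.failed)
            if r.predicted_min_torsions is not None:
                for k, v in enumerate(r.predicted_min_torsions):
                    row[f"pred_d{k + 1}"] = v
                row["pred_E"] = r.predicted_min_energy
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "iterations": self.n_iterations,
            "best_energy": self.best_energy if self.records else None,
            "fraction_transformed": self.fraction_transformed,
            "convergence_iteration": self.convergence_iteration,
            "seed": self.seed,
        }


def transform_energy(E: float, e_cut: float, *,
                     continuous: bool = False) -> float:
    """Damp a relative energy above the cutoff: E_new = E_cut + log10(E).

    `E` must be a non-negative energy relative to the running minimum.  The
    damping is applied only above `e_cut`; as printed it is discontinuous
    there, and the `continuous` variant E_cut + log10(1 + (E - E_cut))
    (equal at the cutoff, same asymptotics) is offered behind the flag.
    """
    if e_cut <= 0:
        raise ValueError("e_cut must be > 0")
    if not np.isfinite(E):
        raise ValueError("energy must be finite")
    if E <= e_cut:
        return float(E)
    if continuous:
        return float(e_cut + math.log10(1.0 + (E - e_cut)))
    if E <= 0:
        raise ValueError("log transform undefined for E <= 0")
    return float(e_cut + math.log10(E))


def beta_schedule(iteration: int, dim: int, delta: float = 0.1) -> float:
    """Exploration weight beta_t = 2 log(t^(d/2+2) pi^2 / (3 delta))."""
    t = max(int(iteration), 1)
    return 2.0 * math.log(t ** (dim / 2.0 + 2.0) * math.pi**2 / (3.0 * delta))


def elcb(model: gp.SurrogateModel, x: np.ndarray, beta: float) -> float:
    """Exploratory lower confidence bound mu(x) - sqrt(beta) sigma(x)."""
    mu, var = model.posterior(np.asarray(x, dtype=float))
    return float(mu - math.sqrt(beta) * math.sqrt(max(var, 0.0)))


def _elcb_and_grad(x, model, beta):
    mu, var, dmu, dvar = model.posterior_with_gradients(x)
    sigma = math.sqrt(max(var, 1e-16))
    val = mu - math.sqrt(beta) * sigma
    grad = dmu - math.sqrt(beta) * dvar / (2.0 * sigma)
    return val, grad


def _multistart_minimize(fun_and_grad, starts, dim):
    best_x, best_f = None, np.inf
    failures = []
    for x0 in starts:
        try:
            res = minimize(fun_and_grad, np.asarray(x0, float), jac=True,
                           method="L-BFGS-B", options={"maxiter": 200})
        except Exception as exc:       # pragma: no cover - scipy internal
            failures.append(str(exc))
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f = float(res.fun)
            best_x = wrap_angle(np.asarray(res.x))
    if best_x is None:
        raise AcquisitionError(
            f"all {len(starts)} minimizer starts failed: {failures[:3]}")
    return np.atleast_1d(best_x), best_f


def next_acquisition(model: gp.SurrogateModel, iteration: int,
                     rng: np.random.Generator, *, n_starts: int = 12,
                     beta: float | None = None,
                     delta: float = 0.1) -> np.ndarray:
    """Minimize the eLCB by multi-start local optimization.

    Starts are seeded uniform draws plus the best training input; the
    search is unconstrained (the kernel is periodic) and the result is
    wrapped back into [-180, 180)^N.  Deterministic given the rng state.
    """
    dim = model.dim
    if beta is None:
        beta = beta_schedule(iteration, dim, delta)
    starts = list(rng.uniform(-180.0, 180.0, size=(n_starts, dim)))
    starts.append(model.X[int(np.argmin(model.y))])
    x, _ = _multistart_minimize(
        lambda x: _elcb_and_grad(x, model, beta), starts, dim)
    return x


def predict_global_minimum(model: gp.SurrogateModel,
                           rng: np.random.Generator,
                           n_random_starts: int = 5,
                           n_data_starts: int = 5):
    """Surrogate's predicted global minimum: multi-start minimization of the
    posterior mean from the best observed inputs plus seeded random starts."""
    order = np.argsort(model.y)
    starts = [model.X[i] for i in order[:n_data_starts]]
    starts.extend(rng.uniform(-180.0, 180.0,
                              size=(n_random_starts, model.dim)))

    def mean_and_grad(x):
        return model.posterior_mean_and_gradient(x)

    return _multistart_minimize(mean_and_grad, starts, model.dim)


def sobol_initial_design(dim: int, n: int, seed: int) -> np.ndarray:
    """Sobol points scaled to the torsion box [-180, 180)^N."""
    sampler = qmc.Sobol(d=dim, scramble=True, seed=seed)
    m = max(int(np.ceil(np.log2(max(n, 1)))), 0)
    u = sampler.random_base2(m)[:n] if n > 1 else sampler.random(1)
    return -180.0 + 360.0 * u


def run_search(energy_fn, dim: int, config: SearchConfig,
               molecule=None, calculator=None) -> tuple[SearchTrace, list]:
    """Run the full active-learning loop.

    Parameters
    ----------
    energy_fn : callable mapping a torsion vector (degrees) to an energy (eV);
        build one with :func:`torsbo.calculators.torsion_energy_function`.
    dim : number of searchable dihedrals N.
    config : search configuration.

    Returns the trace and the list of (torsions, raw_energy) samples.
    """
    config.validate()
    n_init = config.initial_points(dim)
    rng = np.random.default_rng(config.seed)
    trace = SearchTrace(seed=config.seed)

    X: list[np.ndarray] = []
    raw: list[float] = []
    failed_flags: list[bool] = []

    def evaluate(t):
        t = wrap_angle(np.atleast_1d(np.asarray(t, float)))
        try:
            e = float(energy_fn(t))
        except Exception as exc:
            logger.warning("calculator failure at %s: %s", t, exc)
            e = math.nan
        ok = np.isfinite(e)
        X.append(t)
        raw.append(e if ok else math.nan)
        failed_flags.append(not ok)
        return ok

    def transformed_energies():
        finite = [e for e in raw if np.isfinite(e)]
        if not finite:
            raise CalculatorError("every evaluation failed")
        e0 = min(finite)
        out, flags = [], []
        for e in raw:
            rel = (e - e0) if np.isfinite(e) else FAILURE_ENERGY
            te = transform_energy(rel, config.e_cut,
                                  continuous=config.continuous_transform)
            out.append(te)
            flags.append(rel > config.e_cut)
        return np.array(out), flags

    for t in sobol_initial_design(dim, n_init, config.seed):
        evaluate(t)

    model = None
    # initial-design records (no model yet for the very first ones)
    y_t, tflags = transformed_energies()
    for i in range(n_init):
        trace.records.append(IterationRecord(
            iteration=i + 1, torsions=X[i], energy_raw=raw[i],
            energy_transformed=y_t[i],
            best_energy=float(np.nanmin([e for e in raw[:i + 1]
                                         if np.isfinite(e)] or [math.nan])),
            transformed=tflags[i], failed=failed_flags[i]))

    while True:
        y_t, tflags = transformed_energies()
        refit = (model is None or len(X) <= config.refit_every_after
                 or len(X) % 10 == 0)
        if refit:
            model = gp.fit(np.array(X), y_t, seed=config.seed,
                           warm_start=model)
        else:
            # reuse previous hyperparameters, refresh data and factorization
            model = gp.SurrogateModel(
                lengthscales=model.lengthscales,
                signal_variance=model.signal_variance,
                noise_variance=model.noise_variance,
                X=wrap_angle(np.array(X)), y=y_t,
                mean=float(np.mean(y_t)), seed=config.seed)
            model._factorize()
        pred_x, pred_e = predict_global_minimum(model, rng)
        rec = trace.records[len(X) - 1]
        rec.predicted_min_torsions = pred_x
        rec.predicted_min_energy = pred_e

        conv = check_convergence(trace, config)
        if conv is not None:
            trace.convergence_iteration = conv
            if config.stop_on_convergence:
                break
        if len(X) >= config.budget:
            break

        x_next = next_acquisition(model, iteration=len(X) + 1, rng=rng,
                                  n_starts=config.n_acq_starts,
                                  delta=config.beta_delta)
        evaluate(x_next)
        it = len(X)
        y_t, tflags = transformed_energies()
        best = float(np.nanmin([e for e in raw if np.isfinite(e)]))
        trace.records.append(IterationRecord(
            iteration=it, torsions=X[-1], energy_raw=raw[-1],
            energy_transformed=y_t[-1], best_energy=best,
            transformed=tflags[-1], failed=failed_flags[-1]))
        logger.info("iteration %d: t=%s E=%.6f best=%.6f (seed %s)",
                    it, np.round(X[-1], 2), raw[-1], best, config.seed)

    samples = list(zip(X, raw))
    trace._model = model    # stash for post-processing convenience
    return trace, samples


def check_convergence(trace: SearchTrace, config: SearchConfig) -> int | None:
    """First iteration whose trailing window satisfies both tolerances.

    Over the `config.window` most recent records ending at iteration i, the
    predicted-global-minimum energy must vary by less than de_tol and every
    predicted dihedral by less than dd_tol (periodic distance).
    """
    recs = [r for r in trace.records if r.predicted_min_energy is not None]
    if len(recs) < config.window:
        return None
    for end in range(config.window - 1, len(recs)):
        win = recs[end - config.window + 1:end + 1]
        energies = [r.predicted_min_energy for r in win]
        if max(energies) - min(energies) >= config.de_tol:
            continue
        tors = np.array([r.predicted_min_torsions for r in win])
        ok = True
        for k in range(tors.shape[1]):
            col = tors[:, k]
            spread = max(periodic_distance(a, b)
                         for a in col for b in col)
            if spread >= config.dd_tol:
                ok = False
                break
        if ok:
            return win[-1].iteration
    return None
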