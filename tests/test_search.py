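import numpy as np
import pytest

from torsbo import gp
from torsbo.calculators import AnalyticTorsionalPES, cysteine_like_d1_profile
from torsbo.geometry import periodic_distance
from torsbo.search import (IterationRecord, SearchConfig, SearchTrace,
                           beta_schedule, check_convergence, elcb,
                           next_acquisition, run_search, transform_energy)


def two_well_pes():
    """E = 0.15 cos(2 d) + 0.05 cos(d): two wells of different depth."""
    return AnalyticTorsionalPES(np.array([[0.05, 0.15, 0.0]]),
                                np.zeros((1, 3)), np.zeros((1, 1)))


@pytest.mark.parametrize("E, e_cut, expected", [
    (1.5, 2.0, 1.5),
    (10.0, 2.0, 3.0),
    (100.0, 2.0, 4.0),
    (2.0, 2.0, 2.0),       # at the cutoff: identity branch
    (0.0, 2.0, 0.0),
])
def test_transform_energy_examples(E, e_cut, expected):
    assert transform_energy(E, e_cut) == pytest.approx(expected)


def test_transform_energy_monotone_on_each_branch():
    es = np.linspace(0.0, 50.0, 400)
    te = [transform_energy(e, 2.0) for e in es]
    below = [t for e, t in zip(es, te) if e <= 2.0]
    above = [t for e, t in zip(es, te) if e > 2.0]
    assert np.all(np.diff(below) >= 0)
    assert np.all(np.diff(above) >= 0)


def test_transform_energy_continuous_variant_joins_at_cutoff():
    eps = 1e-9
    lo = transform_energy(2.0 - eps, 2.0, continuous=True)
    hi = transform_energy(2.0 + eps, 2.0, continuous=True)
    assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_transform_energy_domain_errors():
    with pytest.raises(ValueError):
        transform_energy(1.0, -1.0)
    with pytest.raises(ValueError):
        transform_energy(float("nan"), 2.0)


def _fit_model(fun, n=13, seed=0):
    X = np.linspace(-180, 180, n, endpoint=False).reshape(-1, 1)
    y = np.array([fun(x[0]) for x in X])
    return gp.fit(X, y, seed=seed)


def test_elcb_reduces_to_mean_at_zero_exploration():
    model = _fit_model(lambda d: 0.2 * np.cos(np.radians(2 * d)))
    for x in (-150.0, -20.0, 60.0):
        assert elcb(model, [x], beta=0.0) == pytest.approx(
            model.posterior([x])[0])


def test_elcb_is_a_lower_bound_on_the_mean():
    model = _fit_model(lambda d: 0.2 * np.cos(np.radians(3 * d)))
    beta = beta_schedule(10, 1)
    for x in np.linspace(-180, 180, 50):
        assert elcb(model, [x], beta=beta) <= model.posterior([x])[0] + 1e-12


def test_elcb_equals_observation_at_interpolated_point():
    model = _fit_model(lambda d: 0.3 * np.cos(np.radians(d)))
    # noise floor is tiny, sigma ~ 0 at training inputs
    x0 = model.X[0]
    y0 = model.y[0]
    assert elcb(model, x0, beta=beta_schedule(5, 1)) == pytest.approx(
        y0, abs=2e-3)


def test_next_acquisition_matches_dense_grid_argmin():
    # asymmetric profile so the eLCB has a unique global minimizer
    model = _fit_model(
        lambda d: (0.2 * np.cos(np.radians(3 * d))
                   + 0.07 * np.cos(np.radians(d))
                   + 0.05 * np.sin(np.radians(2 * d))),
        n=11)
    beta = beta_schedule(12, 1)
    grid = np.arange(-180.0, 180.0, 1.0)
    vals = [elcb(model, [x], beta=beta) for x in grid]
    target = grid[int(np.argmin(vals))]
    rng = np.random.default_rng(0)
    x = next_acquisition(model, iteration=12, rng=rng, n_starts=30)
    assert periodic_distance(x[0], target) <= 1.0


def test_next_acquisition_deterministic_given_seed():
    model = _fit_model(lambda d: 0.2 * np.cos(np.radians(2 * d)), n=9)
    x1 = next_acquisition(model, 3, np.random.default_rng(42))
    x2 = next_acquisition(model, 3, np.random.default_rng(42))
    assert np.array_equal(x1, x2)


def test_run_search_constant_landscape():
    const = lambda t: 0.7
    cfg = SearchConfig(budget=10, seed=0, stop_on_convergence=False)
    trace, samples = run_search(const, 1, cfg)
    assert trace.n_iterations == 10
    best = [r.best_energy for r in trace.records]
    assert np.allclose(best, 0.7)
    # the surrogate works on energies relative to the lowest observation,
    # so a constant landscape is the constant 0 there
    model = trace._model
    assert model.posterior([33.0])[0] == pytest.approx(0.0, abs=1e-3)


def test_run_search_two_well_reaches_grid_oracle():
    pes = two_well_pes()
    grid = np.arange(-180.0, 180.0, 0.1)
    e_true = min(pes.energy([x]) for x in grid)
    cfg = SearchConfig(budget=30, seed=1, stop_on_convergence=False)
    trace, _ = run_search(pes, 1, cfg)
    assert trace.best_energy <= e_true + 0.01


def test_run_search_best_energy_monotone_non_increasing():
    pes = cysteine_like_d1_profile()
    cfg = SearchConfig(budget=20, seed=3, stop_on_convergence=False)
    trace, _ = run_search(pes, 1, cfg)
    best = [r.best_energy for r in trace.records]
    assert np.all(np.diff(best) <= 1e-12)
    assert trace.n_iterations == 20
    assert 0.0 <= trace.fraction_transformed <= 1.0


def test_run_search_handles_calculator_failures():
    pes = cysteine_like_d1_profile()
    calls = {"n": 0}

    def flaky(t):
        calls["n"] += 1
        if calls["n"] == 7:
            return float("nan")
        return pes.energy(t)

    cfg = SearchConfig(budget=12, seed=0, stop_on_convergence=False)
    trace, _ = run_search(flaky, 1, cfg)
    failed = [r for r in trace.records if r.failed]
    assert len(failed) == 1
    assert failed[0].transformed        # damped as far-above-cutoff
    assert np.isfinite(trace.best_energy)


def _synthetic_trace(pred_energies, pred_torsions):
    trace = SearchTrace()
    for i, (e, t) in enumerate(zip(pred_energies, pred_torsions), start=1):
        trace.records.append(IterationRecord(
            iteration=i, torsions=np.atleast_1d(t), energy_raw=e,
            energy_transformed=e, best_energy=min(pred_energies[:i]),
            predicted_min_torsions=np.atleast_1d(t), predicted_min_energy=e))
    return trace


def test_convergence_immediate_for_constant_prediction():
    trace = _synthetic_trace([1.0] * 8, [10.0] * 8)
    cfg = SearchConfig(budget=8, window=5)
    assert check_convergence(trace, cfg) == 5


def test_convergence_never_for_oscillating_dihedral():
    torsions = [0.0 if i % 2 else 20.0 for i in range(12)]
    trace = _synthetic_trace([1.0] * 12, torsions)
    cfg = SearchConfig(budget=12, window=5, dd_tol=10.0)
    assert check_convergence(trace, cfg) is None


def test_convergence_reports_first_satisfying_window():
    # energies settle from iteration 6 onward; window 3 -> converged at 8
    energies = [2.0, 1.5, 1.0, 0.5, 0.3, 0.1, 0.1, 0.1, 0.1]
    torsions = [0.0] * 9
    trace = _synthetic_trace(energies, torsions)
    cfg = SearchConfig(budget=9, window=3, de_tol=0.025)
    assert check_convergence(trace, cfg) == 8


def test_convergence_uses_periodic_dihedral_distance():
    # -179 and +179 are 2 degrees apart, within dd_tol
    torsions = [-179.0, 179.0, -178.0, 179.5, -179.5]
    trace = _synthetic_trace([0.5] * 5, torsions)
    cfg = SearchConfig(budget=5, window=5, dd_tol=10.0)
    assert check_convergence(trace, cfg) == 5


def test_trace_dataframe_and_summary_round_trip():
    pes = cysteine_like_d1_profile()
    cfg = SearchConfig(budget=8, seed=0, stop_on_convergence=False)
    trace, _ = run_search(pes, 1, cfg)
    df = trace.to_dataframe()
    assert list(df["iteration"]) == list(range(1, 9))
    assert {"d1", "E_raw", "E_transformed", "best_E"} <= set(df.columns)
    s = trace.summary()
    assert s["iterations"] == 8 and s["seed"] == 0
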