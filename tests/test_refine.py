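import numpy as np
import pytest

from conftest import DiatomicSpring, IsotropicWell, WaterLikeToy
from torsbo.errors import CalculatorError, NonConvergenceError, TorsboError
from torsbo.refine import (ConformerRecord, _OMEGA_TO_EV, K_B,
                           apply_singlepoint_delta, assemble_hierarchy,
                           hessian_finite_difference, normal_modes,
                           relax_structure, vibrational_free_energy)

M_H, M_F = 1.008, 18.998


def _diatomic_setup(k=30.0, r=1.1):
    calc = DiatomicSpring(k=k, r0=1.1)
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    masses = np.array([M_H, M_F])
    return calc, coords, masses


# -- relaxation --------------------------------------------------------------

def test_relax_converged_input_returned_unchanged():
    calc, coords, _ = _diatomic_setup(r=1.1)   # exactly at the minimum
    geom, e = relax_structure(calc, coords, fmax=0.01)
    assert np.array_equal(geom, coords)
    assert e == pytest.approx(0.0, abs=1e-12)


def test_relax_single_atom_in_isotropic_well():
    calc = IsotropicWell(k=5.0)
    start = np.array([[0.3, -0.2, 0.5]])
    geom, e = relax_structure(calc, start, fmax=1e-4)
    assert np.linalg.norm(geom) < 1e-4
    assert e <= calc.energy(start) + 1e-8


def test_relax_reaches_fmax_and_lowers_energy():
    calc, coords, _ = _diatomic_setup()
    start = coords.copy()
    start[1, 0] = 1.5
    geom, e = relax_structure(calc, start, fmax=0.01)
    r = np.linalg.norm(geom[1] - geom[0])
    assert r == pytest.approx(1.1, abs=1e-3)
    _, f = calc.energy_and_forces(geom)
    assert np.max(np.linalg.norm(f, axis=1)) < 0.01


def test_relax_non_finite_energy_raises():
    class Bad:
        def energy_and_forces(self, c):
            return float("nan"), np.zeros_like(np.asarray(c, float))

    with pytest.raises(CalculatorError):
        relax_structure(Bad(), np.zeros((1, 3)))


def test_relax_step_limit_carries_last_geometry():
    class ConstantSlope:
        """Uniform downhill force: no minimum exists, fmax never reached."""

        def energy_and_forces(self, c):
            c = np.asarray(c, float)
            return float(c[0, 0]), np.array([[-1.0, 0.0, 0.0]])

    with pytest.raises(NonConvergenceError) as err:
        relax_structure(ConstantSlope(), np.zeros((1, 3)), fmax=0.5,
                        max_steps=3)
    assert err.value.geometry is not None


# -- Hessian and normal modes ------------------------------------------------

def test_hessian_1d_particle_recovers_k_over_m():
    """Isotropic well: every eigenvalue of the mass-weighted Hessian is k/m."""
    k, m = 5.0, 12.011
    calc = IsotropicWell(k=k)
    H = hessian_finite_difference(calc, np.zeros((1, 3)), np.array([m]))
    eig = np.linalg.eigvalsh(H)
    assert np.allclose(eig, k / m, rtol=1e-6)


def test_hessian_diatomic_reduced_mass_frequency():
    calc, coords, masses = _diatomic_setup(k=30.0)
    H = hessian_finite_difference(calc, coords, masses)
    assert np.allclose(H, H.T)
    vib = normal_modes(H, coords, masses)
    mu = 1.0 / (1.0 / M_H + 1.0 / M_F)
    expected = np.sqrt(30.0 / mu) * _OMEGA_TO_EV
    assert len(vib.frequencies) == 1           # 3*2 - 5 for a linear molecule
    assert vib.frequencies[0] == pytest.approx(expected, rel=1e-6)
    assert vib.n_imaginary == 0


def test_free_atom_has_no_internal_modes():
    calc = IsotropicWell(k=0.0)

    class Free:
        def energy_and_forces(self, c):
            return 0.0, np.zeros_like(np.asarray(c, float))

    H = hessian_finite_difference(Free(), np.zeros((1, 3)), np.array([4.0]))
    vib = normal_modes(H, np.zeros((1, 3)), np.array([4.0]))
    assert len(vib.frequencies) == 0


def test_water_like_toy_has_three_modes():
    calc = WaterLikeToy()
    r0, th = 0.96, np.radians(104.5)
    coords = np.array([[0.0, 0.0, 0.0],
                       [r0, 0.0, 0.0],
                       [r0 * np.cos(th), r0 * np.sin(th), 0.0]])
    masses = np.array([15.999, M_H, M_H])
    H = hessian_finite_difference(calc, coords, masses)
    vib = normal_modes(H, coords, masses)
    assert len(vib.frequencies) == 3           # 3*3 - 6
    assert np.all(vib.frequencies > 0)


def test_hessian_richardson_consistency():
    """Frequencies converge as the displacement shrinks (O(delta^2) FD)."""
    calc, coords, masses = _diatomic_setup(k=30.0)

    def freq(delta):
        H = hessian_finite_difference(calc, coords, masses, delta=delta)
        return normal_modes(H, coords, masses).frequencies[0]

    f1, f2, f4 = freq(0.01), freq(0.005), freq(0.0025)
    assert abs(f2 - f4) <= abs(f1 - f2) + 1e-12
    assert abs(f1 - f4) / f4 < 1e-4


def test_hessian_reports_failing_displacement():
    class FailsOnce:
        def __init__(self):
            self.n = 0

        def energy_and_forces(self, c):
            self.n += 1
            if self.n == 3:
                raise RuntimeError("boom")
            return 0.0, np.zeros_like(np.asarray(c, float))

    with pytest.raises(CalculatorError, match="displacement"):
        hessian_finite_difference(FailsOnce(), np.zeros((1, 3)),
                                  np.array([1.0]))


# -- vibrational free energy -------------------------------------------------

def test_single_mode_zpe_at_zero_temperature():
    assert vibrational_free_energy([0.1], 0.0) == pytest.approx(0.05)


def test_single_mode_closed_form_at_300K():
    kt = K_B * 300.0
    expected = 0.05 + kt * np.log(1.0 - np.exp(-0.1 / kt))
    assert vibrational_free_energy([0.1], 300.0) == pytest.approx(
        expected, rel=1e-12)


def test_free_energy_additivity_over_modes():
    f = vibrational_free_energy
    assert f([0.1, 0.25], 300.0) == pytest.approx(
        f([0.1], 300.0) + f([0.25], 300.0), rel=1e-12)


def test_free_energy_strictly_decreasing_in_temperature():
    temps = [0.0, 50.0, 150.0, 300.0, 600.0]
    vals = [vibrational_free_energy([0.05, 0.2], T) for T in temps]
    assert np.all(np.diff(vals) < 0)


def test_negative_frequency_rejected():
    with pytest.raises(ValueError):
        vibrational_free_energy([-0.1], 300.0)


# -- hierarchy ---------------------------------------------------------------

def _records():
    return [
        ConformerRecord(label="a", e_opt=-3.0, zpe=0.5, f_vib=0.45),
        ConformerRecord(label="b", e_opt=-2.9, zpe=0.52, f_vib=0.40),
        ConformerRecord(label="c", e_opt=-2.5, zpe=0.48, f_vib=0.46),
    ]


def test_singleton_record_is_zero_everywhere():
    table = assemble_hierarchy([ConformerRecord(label="x", e_opt=1.0,
                                                zpe=0.1, f_vib=0.09)])
    for stage in ("optimized", "+VE(0K)", "+VE(300K)"):
        assert table[f"rel_{stage}"].iloc[0] == pytest.approx(0.0)
        assert table[f"rank_{stage}"].iloc[0] == 1


def test_global_shift_leaves_relative_energies_unchanged():
    t1 = assemble_hierarchy(_records())
    shifted = _records()
    for r in shifted:
        r.e_opt += 123.456
    t2 = assemble_hierarchy(shifted)
    for stage in ("optimized", "+VE(0K)", "+VE(300K)"):
        assert np.allclose(t1[f"rel_{stage}"], t2[f"rel_{stage}"])


def test_zero_corrections_preserve_relaxed_ordering():
    recs = [ConformerRecord(label=l, e_opt=e, zpe=0.0, f_vib=0.0)
            for l, e in [("a", -1.0), ("b", -0.5), ("c", -1.7)]]
    refine_deltas = {r.label: r.e_opt for r in recs}   # delta = 0
    apply_singlepoint_delta(recs, refine_deltas)
    t = assemble_hierarchy(recs)
    for stage in ("+VE(0K)", "+VE(300K)", "+delta"):
        assert list(t[f"rank_{stage}"]) == list(t["rank_optimized"])


def test_uniform_delta_is_shift_invariant():
    recs = _records()
    apply_singlepoint_delta(recs, {r.label: r.e_opt + 0.3 for r in recs})
    t = assemble_hierarchy(recs)
    assert np.allclose(t["rel_+delta"], t["rel_+VE(300K)"])


def test_delta_can_swap_a_close_pair():
    recs = [ConformerRecord(label="a", e_opt=0.0, zpe=0.0, f_vib=0.0),
            ConformerRecord(label="b", e_opt=0.02, zpe=0.0, f_vib=0.0)]
    apply_singlepoint_delta(recs, {"a": 0.0, "b": 0.02 - 0.05})
    t = assemble_hierarchy(recs).set_index("label")
    assert t.loc["a", "rank_optimized"] == 1
    assert t.loc["b", "rank_+delta"] == 1


def test_records_without_delta_excluded_from_final_stage():
    recs = _records()
    apply_singlepoint_delta(recs, {"a": -2.95})
    t = assemble_hierarchy(recs).set_index("label")
    assert np.isnan(t.loc["b", "rel_+delta"])
    assert not np.isnan(t.loc["a", "rel_+delta"])


def test_unmatched_delta_label_raises():
    with pytest.raises(TorsboError, match="ghost"):
        apply_singlepoint_delta(_records(), {"ghost": 1.0})


def test_hierarchy_invariant_under_input_order():
    t1 = assemble_hierarchy(_records())
    t2 = assemble_hierarchy(list(reversed(_records())))
    assert t1.equals(t2)
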