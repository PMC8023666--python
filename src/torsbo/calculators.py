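"""Pluggable energy backends and reference-grid mapping.

Two calculator flavours exist:

* **Torsion calculators** evaluate an energy directly from a torsion vector
  (degrees).  The built-in :class:`AnalyticTorsionalPES` is a smooth,
  360-degree-periodic multi-well landscape whose minima can be enumerated by
  brute-force grid scan — it makes the whole search/refinement toolkit
  testable without any quantum-chemistry software.
* **Cartesian calculators** evaluate energy (and optionally forces) from a
  Cartesian geometry: the RDKit MMFF94 adapter and the file-exchange stub
  that bridges to external codes through the filesystem.

All energies are eV, forces eV/Å, angles degrees.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import CalculatorError, TorsboError

KCAL_TO_EV = 0.0433641153


# ---------------------------------------------------------------------------
# analytic torsional PES
# ---------------------------------------------------------------------------

@dataclass
class AnalyticTorsionalPES:
    """Cosine-series torsional landscape, periodic in every dimension.

    E(d) = sum_j sum_k a[j,k] * cos(k * (d_j - phi[j,k]))
         + sum_{i<j} c[i,j] * cos(d_i - d_j)        (angles in degrees)

    Orders k run 1..3, matching the 1-, 2- and 3-fold barriers of real
    torsional profiles; the pairwise difference coupling introduces
    correlation between dihedrals without destroying enumerability.
    """

    amplitudes: np.ndarray      # (dim, 3)
    phases: np.ndarray          # (dim, 3), degrees
    couplings: np.ndarray       # (dim, dim), upper triangle used
    seed: int | None = None
    provides_forces: bool = False
    deterministic: bool = True

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, float))
        self.phases = np.atleast_2d(np.asarray(self.phases, float))
        self.couplings = np.atleast_2d(np.asarray(self.couplings, float))

    @property
    def dim(self) -> int:
        return self.amplitudes.shape[0]

    def energy(self, torsions: np.ndarray) -> float:
        t = np.deg2rad(np.atleast_1d(np.asarray(torsions, float)))
        ph = np.deg2rad(self.phases)
        orders = np.arange(1, self.amplitudes.shape[1] + 1)
        e = float(np.sum(self.amplitudes *
                         np.cos(orders[None, :] * (t[:, None] - ph))))
        for i in range(self.dim):
            for j in range(i + 1, self.dim):
                if self.couplings[i, j] != 0.0:
                    e += self.couplings[i, j] * np.cos(t[i] - t[j])
        return e

    __call__ = energy

    def energy_batch(self, points: np.ndarray) -> np.ndarray:
        """Vectorized energies for row-stacked torsion vectors."""
        t = np.deg2rad(np.atleast_2d(np.asarray(points, float)))  # (m, dim)
        ph = np.deg2rad(self.phases)
        orders = np.arange(1, self.amplitudes.shape[1] + 1)
        arg = orders[None, None, :] * (t[:, :, None] - ph[None, :, :])
        e = np.sum(self.amplitudes[None, :, :] * np.cos(arg), axis=(1, 2))
        for i in range(self.dim):
            for j in range(i + 1, self.dim):
                if self.couplings[i, j] != 0.0:
                    e += self.couplings[i, j] * np.cos(t[:, i] - t[:, j])
        return e

    def gradient(self, torsions: np.ndarray) -> np.ndarray:
        """dE/dd in eV/deg."""
        t = np.deg2rad(np.atleast_1d(np.asarray(torsions, float)))
        ph = np.deg2rad(self.phases)
        orders = np.arange(1, self.amplitudes.shape[1] + 1)
        g = -np.sum(self.amplitudes * orders[None, :] *
                    np.sin(orders[None, :] * (t[:, None] - ph)), axis=1)
        for i in range(self.dim):
            for j in range(i + 1, self.dim):
                cij = self.couplings[i, j]
                if cij != 0.0:
                    s = np.sin(t[i] - t[j])
                    g[i] -= cij * s
                    g[j] += cij * s
        return g * (np.pi / 180.0)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"amplitudes": self.amplitudes.tolist(),
                       "phases": self.phases.tolist(),
                       "couplings": self.couplings.tolist(),
                       "seed": self.seed}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "AnalyticTorsionalPES":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["amplitudes"]), np.array(d["phases"]),
                   np.array(d["couplings"]), seed=d.get("seed"))


def grid_step_for_dim(dimension: int) -> float:
    """Brute-force enumeration grid spacing by dimensionality (degrees)."""
    if dimension <= 2:
        return 1.0
    if dimension <= 4:
        return 5.0
    return 15.0


def count_grid_minima(pes, step: float | None = None) -> int:
    """Number of strict local minima of `pes` on a periodic dense grid."""
    dim = pes.dim
    step = grid_step_for_dim(dim) if step is None else step
    n = int(round(360.0 / step))
    axes = [np.arange(n) * step - 180.0 for _ in range(dim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    if hasattr(pes, "energy_batch"):
        E = pes.energy_batch(pts).reshape([n] * dim)
    else:
        E = np.array([pes.energy(p) for p in pts]).reshape([n] * dim)
    is_min = np.ones_like(E, dtype=bool)
    for ax in range(dim):
        is_min &= E < np.roll(E, 1, axis=ax)
        is_min &= E < np.roll(E, -1, axis=ax)
    return int(np.count_nonzero(is_min))


def generate_test_pes(dimension: int, seed: int,
                      minima_range: tuple[int, int] = (2, 8),
                      coupling_scale: float = 0.05,
                      max_draws: int = 50) -> AnalyticTorsionalPES:
    """Draw a random multi-well PES whose grid-enumerated minima count lies
    in `minima_range`.  Amplitudes are eV-scale (tenths of eV), matching
    typical torsional barriers.  Reproducible: coefficients are a pure
    function of the seed and the draw index.
    """
    if not 1 <= dimension <= 6:
        raise ValueError("dimension must be in 1..6")
    lo, hi = minima_range
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        amps = rng.uniform(0.02, 0.25, size=(dimension, 3)) * \
            rng.choice([-1.0, 1.0], size=(dimension, 3))
        phases = rng.uniform(-180.0, 180.0, size=(dimension, 3))
        coup = np.zeros((dimension, dimension))
        if dimension > 1 and coupling_scale > 0:
            iu = np.triu_indices(dimension, k=1)
            coup[iu] = rng.uniform(-coupling_scale, coupling_scale,
                                   size=len(iu[0]))
        pes = AnalyticTorsionalPES(amps, phases, coup, seed=seed)
        if lo <= count_grid_minima(pes) <= hi:
            return pes
    raise TorsboError(
        f"no PES with {lo}..{hi} grid minima found in {max_draws} draws "
        f"(dimension {dimension}, seed {seed})")


def cysteine_like_d1_profile() -> AnalyticTorsionalPES:
    """1D torsional profile emulating rotation about an sp3-sp3 backbone bond.

    Dominant 3-fold term with 1- and 2-fold asymmetry: three staggered wells
    of distinct depth separated by 0.2-0.3 eV barriers, a unique global
    minimum near -57 degrees.  Coefficients are fixed so the profile is a
    stable benchmark landscape.
    """
    amps = np.array([[0.060, 0.035, 0.110]])
    phases = np.array([[150.0, 40.0, 0.0]])
    return AnalyticTorsionalPES(amps, phases, np.zeros((1, 1)), seed=0)


def contrast_transform(E: np.ndarray, power: float = 0.75) -> np.ndarray:
    """E**(3/4) contrast stretch for PES map plotting only (never used in
    any computation); input must be relative energies >= 0."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("contrast transform expects relative energies >= 0")
    return E ** power


# ---------------------------------------------------------------------------
# grid reference mapper
# ---------------------------------------------------------------------------

@dataclass
class GridMap:
    """Regular-grid reference map over one or two dihedrals."""

    dims: tuple[int, ...]
    axes: list[np.ndarray]
    energies: np.ndarray          # relative to grid minimum; NaN where failed
    n_evaluations: int
    n_failed: int

    def to_csv(self, path: str) -> None:
        import pandas as pd
        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {f"d{k + 1}": m.ravel() for k, m in zip(self.dims, mesh)}
        data["relative_energy_eV"] = self.energies.ravel()
        pd.DataFrame(data).to_csv(path, index=False)


def grid_reference_map(energy_fn, ndim: int, dims: tuple[int, ...],
                       n: int, fixed: np.ndarray | None = None) -> GridMap:
    """Evaluate `energy_fn` (torsion vector -> eV) on a full regular grid.

    Grid points sit at -180 + 360*i/n per mapped dimension (left-closed,
    periodic, no duplicated endpoint).  Non-mapped dihedrals are held at
    `fixed`.  Failures are recorded as NaN; the evaluation count is always
    exactly n**len(dims).
    """
    dims = tuple(int(d) for d in dims)
    if not 1 <= len(dims) <= 2:
        raise ValueError("maps cover 1 or 2 dihedrals")
    if n < 2:
        raise ValueError("need n >= 2 grid points per dimension")
    base = np.zeros(ndim) if fixed is None else np.asarray(fixed, float).copy()
    axes = [(-180.0 + 360.0 * np.arange(n) / n) for _ in dims]
    shape = tuple(n for _ in dims)
    energies = np.full(shape, np.nan)
    n_eval = 0
    n_failed = 0
    for idx in np.ndindex(shape):
        t = base.copy()
        for k, d in enumerate(dims):
            t[d] = axes[k][idx[k]]
        n_eval += 1
        try:
            e = float(energy_fn(t))
            if not np.isfinite(e):
                raise CalculatorError("non-finite energy")
            energies[idx] = e
        except Exception:
            n_failed += 1
    if np.any(np.isfinite(energies)):
        energies = energies - np.nanmin(energies)
    return GridMap(dims=dims, axes=axes, energies=energies,
                   n_evaluations=n_eval, n_failed=n_failed)


# ---------------------------------------------------------------------------
# cartesian calculators
# ---------------------------------------------------------------------------

class MMFFCalculator:
    """RDKit MMFF94 adapter: deterministic energies and forces for a molecule
    whose bonding is perceived once from the reference geometry."""

    provides_forces = True
    deterministic = True

    def __init__(self, elements: list[str], coords: np.ndarray, charge: int = 0):
        from rdkit import Chem
        from rdkit.Chem import AllChem, rdDetermineBonds

        xyz_lines = [str(len(elements)), "torsbo"]
        for el, (x, y, z) in zip(elements, np.asarray(coords, float)):
            xyz_lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
        mol = Chem.MolFromXYZBlock("\n".join(xyz_lines) + "\n")
        if mol is None:
            raise CalculatorError("RDKit could not read the geometry")
        rdDetermineBonds.DetermineBonds(mol, charge=charge)
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise CalculatorError("MMFF94 parameters unavailable for molecule")
        self._mol = mol
        self._props = props
        self._n = len(elements)

    def _ff(self, coords: np.ndarray):
        from rdkit.Chem import AllChem
        conf = self._mol.GetConformer()
        for i, (x, y, z) in enumerate(np.asarray(coords, float)):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        return AllChem.MMFFGetMoleculeForceField(self._mol, self._props)

    def energy(self, coords: np.ndarray) -> float:
        return self._ff(coords).CalcEnergy() * KCAL_TO_EV

    def energy_and_forces(self, coords: np.ndarray):
        ff = self._ff(coords)
        e = ff.CalcEnergy() * KCAL_TO_EV
        grad = np.array(ff.CalcGrad()).reshape(self._n, 3) * KCAL_TO_EV
        return e, -grad


class FileExchangeCalculator:
    """Bridge to an external code through the filesystem.

    For each evaluation *i* the stub writes ``point_<i>.xyz`` and
    ``point_<i>.request`` (JSON: what is needed) into `workdir`, then polls
    for ``point_<i>.result`` and parses it.  Result format (plain text)::

        energy <eV>
        force <fx> <fy> <fz>     # one line per atom, only when requested

    A malformed result raises a parse error naming the offending line;
    absence within `timeout` seconds raises a timeout error.
    """

    deterministic = False

    def __init__(self, workdir: str, elements: list[str], *,
                 want_forces: bool = False, timeout: float = 60.0,
                 poll: float = 0.05):
        if not os.path.isdir(workdir):
            raise CalculatorError(f"workdir does not exist: {workdir}")
        self.workdir = workdir
        self.elements = list(elements)
        self.want_forces = want_forces
        self.provides_forces = want_forces
        self.timeout = timeout
        self.poll = poll
        self._counter = 0

    def _paths(self, i: int):
        stem = os.path.join(self.workdir, f"point_{i:05d}")
        return stem + ".xyz", stem + ".request", stem + ".result"

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_and_forces(coords)[0]

    def energy_and_forces(self, coords: np.ndarray):
        from .xyz import write_xyz
        i = self._counter
        self._counter += 1
        xyz_path, req_path, res_path = self._paths(i)
        write_xyz(xyz_path, self.elements, coords,
                  comment=f"torsbo request {i}")
        with open(req_path, "w") as fh:
            json.dump({"index": i, "forces": self.want_forces}, fh)
        deadline = time.monotonic() + self.timeout
        while not os.path.exists(res_path):
            if time.monotonic() >= deadline:
                raise TimeoutError(f"no result file {res_path} "
                                   f"within {self.timeout} s")
            time.sleep(self.poll)
        return self._parse(res_path)

    def _parse(self, path: str):
        energy = None
        forces = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if parts[0] == "energy" and len(parts) == 2:
                    try:
                        energy = float(parts[1])
                    except ValueError:
                        raise CalculatorError(
                            f"{path}:{lineno}: bad energy value {parts[1]!r}")
                elif parts[0] == "force" and len(parts) == 4:
                    try:
                        forces.append([float(v) for v in parts[1:]])
                    except ValueError:
                        raise CalculatorError(
                            f"{path}:{lineno}: bad force line {line!r}")
                else:
                    raise CalculatorError(
                        f"{path}:{lineno}: unrecognized line {line!r}")
        if energy is None:
            raise CalculatorError(f"{path}: missing energy line")
        if self.want_forces:
            if len(forces) != len(self.elements):
                raise CalculatorError(
                    f"{path}: expected {len(self.elements)} force lines, "
                    f"got {len(forces)}")
            return energy, np.array(forces)
        return energy, None


@dataclass
class TorsionEnergyFunction:
    """Adapter: torsion vector -> energy via a molecule + Cartesian backend."""

    molecule: object            # MoleculeModel
    calculator: object          # Cartesian calculator with .energy(coords)
    n_evaluations: int = field(default=0)

    def __call__(self, torsions: np.ndarray) -> float:
        coords = self.molecule.set_torsions(torsions)
        self.n_evaluations += 1
        return self.calculator.energy(coords)


def torsion_energy_function(molecule, calculator):
    """Energy-of-torsions callable for the search loop.

    Torsion calculators (with a ``dim`` attribute) are used directly;
    Cartesian calculators are wrapped through ``set_torsions``.
    """
    if hasattr(calculator, "dim") and hasattr(calculator, "gradient"):
        return calculator
    return TorsionEnergyFunction(molecule, calculator)
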