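import numpy as np
import pytest
from hypothesis import settings

from torsbo.calculators import AnalyticTorsionalPES
from torsbo.geometry import MoleculeModel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


class DiatomicSpring:
    """Harmonic bond between two atoms: E = k/2 (r - r0)^2."""

    provides_forces = True
    deterministic = True

    def __init__(self, k=30.0, r0=1.1):
        self.k, self.r0 = k, r0

    def energy_and_forces(self, coords):
        c = np.asarray(coords, dtype=float)
        d = c[1] - c[0]
        r = np.linalg.norm(d)
        e = 0.5 * self.k * (r - self.r0) ** 2
        g = self.k * (r - self.r0) * d / r
        return e, np.array([g, -g])

    def energy(self, coords):
        return self.energy_and_forces(coords)[0]


class IsotropicWell:
    """Single atom in an isotropic harmonic well centered at the origin."""

    provides_forces = True
    deterministic = True

    def __init__(self, k=5.0):
        self.k = k

    def energy_and_forces(self, coords):
        c = np.asarray(coords, dtype=float).reshape(-1, 3)
        e = 0.5 * self.k * float(np.sum(c ** 2))
        return e, -self.k * c

    def energy(self, coords):
        return self.energy_and_forces(coords)[0]


class WaterLikeToy:
    """3-atom quadratic toy potential: two bonds plus an angle spring."""

    provides_forces = True
    deterministic = True

    def __init__(self, kb=35.0, ka=3.0, r0=0.96, theta0=np.radians(104.5)):
        self.kb, self.ka, self.r0, self.theta0 = kb, ka, r0, theta0

    def energy(self, coords):
        c = np.asarray(coords, dtype=float)
        r1 = np.linalg.norm(c[1] - c[0])
        r2 = np.linalg.norm(c[2] - c[0])
        v1 = (c[1] - c[0]) / r1
        v2 = (c[2] - c[0]) / r2
        theta = np.arccos(np.clip(v1 @ v2, -1, 1))
        return (0.5 * self.kb * ((r1 - self.r0) ** 2 + (r2 - self.r0) ** 2)
                + 0.5 * self.ka * (theta - self.theta0) ** 2)

    def energy_and_forces(self, coords):
        c = np.asarray(coords, dtype=float)
        e = self.energy(c)
        g = np.zeros_like(c)
        h = 1e-6
        for i in range(c.size):
            cp = c.copy().ravel()
            cm = c.copy().ravel()
            cp[i] += h
            cm[i] -= h
            g.ravel()[i] = (self.energy(cp.reshape(-1, 3))
                            - self.energy(cm.reshape(-1, 3))) / (2 * h)
        return e, -g


def six_well_pes() -> AnalyticTorsionalPES:
    """Separable 2D landscape with exactly 3 x 2 = 6 equal-depth wells."""
    amps = np.array([[0.0, 0.0, 0.10],
                     [0.0, 0.10, 0.0]])
    return AnalyticTorsionalPES(amps, np.zeros((2, 3)), np.zeros((2, 2)),
                                seed=0)


@pytest.fixture
def chain4():
    """Four-carbon chain with a single searchable dihedral."""
    coords = np.array([[0.0, 0.0, 0.0],
                       [1.54, 0.0, 0.0],
                       [2.05, 1.45, 0.0],
                       [3.59, 1.45, 0.1]])
    return MoleculeModel(["C", "C", "C", "C"], coords, [(0, 1, 2, 3)],
                         bonds=[(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def chain5():
    """Five-carbon chain with two searchable dihedrals."""
    coords = np.array([[0.0, 0.0, 0.0],
                       [1.54, 0.0, 0.0],
                       [2.05, 1.45, 0.0],
                       [3.59, 1.45, 0.1],
                       [4.10, 2.86, 0.2]])
    return MoleculeModel(["C"] * 5, coords,
                         [(0, 1, 2, 3), (1, 2, 3, 4)],
                         bonds=[(0, 1), (1, 2), (2, 3), (3, 4)])
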