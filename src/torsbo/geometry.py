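"""Internal-coordinate molecular model and torsion-space geometry construction.

A molecule is represented by its Cartesian reference geometry plus a bond
graph and a list of searchable proper dihedrals d_1..d_N.  During a search
all bond lengths and bond angles stay frozen at their reference values
("building-block approximation"); only the listed dihedrals rotate.  Angles
are degrees everywhere, canonicalized to the half-open interval [-180, 180).

The dihedral sign convention is the IUPAC right-hand rule: for atoms
(i, j, k, l), looking down the j->k bond, a positive angle is a clockwise
rotation of the far plane — equivalently the signed angle returned by the
standard atan2 construction below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import DegenerateGeometryError, NonRotatableBondError, TorsboError

_PT = Chem.GetPeriodicTable()

#: scale factor applied to summed covalent radii when deriving connectivity
COVALENT_SCALE = 1.2

_COLLINEAR_TOL = 1e-8


def wrap_angle(angle: float) -> float:
    """Canonicalize an angle in degrees to [-180, 180)."""
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite angle: {angle!r}")
    wrapped = (a + 180.0) % 360.0 - 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def periodic_distance(a: float, b: float) -> float:
    """Shortest angular distance |a - b| on the 360-degree circle, in [0, 180]."""
    d = wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    out = np.abs(d)
    # wrap_angle maps the antipode to -180; its distance is +180
    return out if out.ndim else float(out)


def _atomic_number(symbol: str) -> int:
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        z = 0
    if z <= 0:
        raise TorsboError(f"unknown element symbol: {symbol!r}")
    return z


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in amu; raises for unknown element symbols."""
    return _PT.GetAtomicWeight(_atomic_number(symbol))


def covalent_radius(symbol: str) -> float:
    return _PT.GetRcovalent(_atomic_number(symbol))


def derive_connectivity(elements: list[str], coords: np.ndarray,
                        scale: float = COVALENT_SCALE) -> list[tuple[int, int]]:
    """Bond list from a covalent-radius distance criterion.

    Atoms i, j are bonded when |r_i - r_j| < scale * (R_cov,i + R_cov,j).
    Explicitly supplied connectivity always wins over this heuristic.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([covalent_radius(e) for e in elements])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonds = []
    n = len(elements)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < cutoff[i, j]:
                bonds.append((i, j))
    return bonds


def measure_dihedral(coords: np.ndarray, quad: tuple[int, int, int, int]) -> float:
    """Signed dihedral (degrees, in [-180, 180)) for atom indices (i, j, k, l)."""
    i, j, k, l = quad
    c = np.asarray(coords, dtype=float)
    b1 = c[j] - c[i]
    b2 = c[k] - c[j]
    b3 = c[l] - c[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            f"collinear atom triplet in dihedral {quad}; angle undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def measure_torsions(coords: np.ndarray,
                     dihedrals: list[tuple[int, int, int, int]]) -> np.ndarray:
    """Measure every searchable dihedral; returns a canonical torsion vector."""
    return np.array([measure_dihedral(coords, q) for q in dihedrals])


def _bond_angle(coords, i, j, k):
    v1 = coords[i] - coords[j]
    v2 = coords[k] - coords[j]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class MoleculeModel:
    """A molecule in internal coordinates with searchable dihedrals.

    Parameters
    ----------
    elements : element symbols, one per atom.
    coords : reference Cartesian coordinates, Å, shape (n_atoms, 3).
    dihedrals : searchable proper dihedrals as 0-based atom index quadruples.
    bonds : bond list; derived from covalent radii when omitted.
    """

    elements: list[str]
    coords: np.ndarray
    dihedrals: list[tuple[int, int, int, int]]
    bonds: list[tuple[int, int]] | None = None
    masses: np.ndarray = field(init=False)
    _downstream: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TorsboError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != len(self.coords):
            raise TorsboError("elements and coords length mismatch")
        if len(self.dihedrals) < 1:
            raise TorsboError("at least one searchable dihedral is required")
        self.dihedrals = [tuple(int(a) for a in q) for q in self.dihedrals]
        self.masses = np.array([atomic_mass(e) for e in self.elements])
        if self.bonds is None:
            self.bonds = derive_connectivity(self.elements, self.coords)
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in self.bonds]
        self._validate_dihedrals()
        self._downstream = [self._downstream_atoms(q) for q in self.dihedrals]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_torsions(self) -> int:
        return len(self.dihedrals)

    def _adjacency(self, skip: tuple[int, int] | None = None):
        adj = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            if skip is not None and {i, j} == set(skip):
                continue
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def _validate_dihedrals(self):
        bondset = {frozenset(b) for b in self.bonds}
        for q in self.dihedrals:
            if len(set(q)) != 4:
                raise TorsboError(f"dihedral {q} must reference 4 distinct atoms")
            if any(a < 0 or a >= self.n_atoms for a in q):
                raise TorsboError(f"dihedral {q} has out-of-range atom index")
            for a, b in zip(q[:-1], q[1:]):
                if frozenset((a, b)) not in bondset:
                    raise TorsboError(
                        f"dihedral {q}: atoms {a}-{b} are not bonded")

    def _downstream_atoms(self, quad) -> np.ndarray:
        """Atoms that move when the central bond of `quad` rotates.

        The component containing atom k after cutting the j-k bond.  If the
        cut does not split the graph the bond lies in a ring — rejected.
        """
        _, j, k, _ = quad
        adj = self._adjacency(skip=(j, k))
        seen = {k}
        stack = [k]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        if j in seen:
            raise NonRotatableBondError(
                f"bond {j}-{k} of dihedral {quad} lies in a ring")
        moving = np.array(sorted(seen - {k}), dtype=int)
        return moving

    # -- torsion construction -------------------------------------------------

    def set_torsions(self, torsions: np.ndarray,
                     coords: np.ndarray | None = None) -> np.ndarray:
        """Cartesian coordinates with the searchable dihedrals set to `torsions`.

        Bond lengths and angles are untouched: each dihedral change is a rigid
        rotation of the downstream fragment about its central bond.
        """
        t = np.atleast_1d(np.asarray(torsions, dtype=float))
        if t.shape != (self.n_torsions,):
            raise TorsboError(
                f"torsion vector length {t.shape} != {self.n_torsions}")
        out = np.array(self.coords if coords is None else coords, dtype=float)
        for idx, quad in enumerate(self.dihedrals):
            current = measure_dihedral(out, quad)
            delta = wrap_angle(t[idx] - current)
            if delta == 0.0:
                continue
            _, j, k, _ = quad
            axis = out[k] - out[j]
            axis = axis / np.linalg.norm(axis)
            moving = self._downstream[idx]
            rot = _rotation_matrix(axis, np.radians(delta))
            out[moving] = (out[moving] - out[k]) @ rot.T + out[k]
        return out

    def measure_torsions(self, coords: np.ndarray) -> np.ndarray:
        return measure_torsions(coords, self.dihedrals)

    def bond_lengths(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        return np.array([np.linalg.norm(c[i] - c[j]) for i, j in self.bonds])

    def bond_angles(self, coords: np.ndarray) -> np.ndarray:
        """All angles i-j-k over bonded triples, degrees."""
        adj = self._adjacency()
        c = np.asarray(coords, dtype=float)
        angles = []
        for j in range(self.n_atoms):
            neigh = sorted(adj[j])
            for a in range(len(neigh)):
                for b in range(a + 1, len(neigh)):
                    angles.append(_bond_angle(c, neigh[a], j, neigh[b]))
        return np.array(angles)

    def zmatrix_rows(self, coords: np.ndarray | None = None) -> list[str]:
        """Simple text Z-matrix (bond / angle / dihedral per atom) for export."""
        c = self.coords if coords is None else np.asarray(coords, dtype=float)
        adj = self._adjacency()
        rows = []
        for i, el in enumerate(self.elements):
            if i == 0:
                rows.append(el)
                continue
            refs = [b for b in sorted(adj[i]) if b < i] or [i - 1]
            j = refs[0]
            length = np.linalg.norm(c[i] - c[j])
            if i == 1:
                rows.append(f"{el} {j + 1} {length:.6f}")
                continue
            k = next((b for b in sorted(adj[j]) if b < i and b != i), 0)
            if k == i or k == j:
                k = 0 if j != 0 else 1
            ang = _bond_angle(c, i, j, k)
            if i == 2:
                rows.append(f"{el} {j + 1} {length:.6f} {k + 1} {ang:.4f}")
                continue
            l = next((b for b in range(i) if b not in (i, j, k)), 0)
            try:
                dih = measure_dihedral(c, (l, k, j, i))
            except DegenerateGeometryError:
                dih = 0.0
            rows.append(
                f"{el} {j + 1} {length:.6f} {k + 1} {ang:.4f} {l + 1} {dih:.4f}")
        return rows


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Right-handed rotation by theta (radians) about the unit vector axis."""
    ux, uy, uz = axis
    c, s = np.cos(theta), np.sin(theta)
    C = 1.0 - c
    return np.array([
        [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
        [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
        [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
    ])
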