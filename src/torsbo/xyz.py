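"""Minimal strict XYZ reader/writer (Å, multi-frame, line-numbered errors)."""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .errors import XYZParseError

_PT = Chem.GetPeriodicTable()


def read_xyz(path: str) -> list[tuple[list[str], np.ndarray, str]]:
    """Parse a (possibly multi-frame) XYZ file.

    Returns a list of frames ``(elements, coords, comment)`` in file order.
    Raises :class:`XYZParseError` with the 1-based line number on a count
    mismatch, an unknown element symbol, or a malformed coordinate record.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"expected an atom count, got {lines[i]!r}", line=i + 1)
        if natoms <= 0:
            raise XYZParseError(f"atom count must be positive: {natoms}",
                                line=i + 1)
        if i + 1 >= n_lines:
            raise XYZParseError("missing comment line", line=i + 2)
        comment = lines[i + 1]
        elements, coords = [], []
        for k in range(natoms):
            lineno = i + 2 + k
            if lineno >= n_lines or not lines[lineno].strip():
                raise XYZParseError(
                    f"frame declares {natoms} atoms but ends after {k}",
                    line=lineno + 1)
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"expected 'symbol x y z', got {lines[lineno]!r}",
                    line=lineno + 1)
            sym = parts[0]
            try:
                known = _PT.GetAtomicNumber(sym) > 0
            except Exception:
                known = False
            if not known:
                raise XYZParseError(f"unknown element symbol {sym!r}",
                                    line=lineno + 1)
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"bad coordinate in {lines[lineno]!r}", line=lineno + 1)
            elements.append(sym)
            coords.append(xyz)
        frames.append((elements, np.array(coords), comment))
        i += 2 + natoms
    if not frames:
        raise XYZParseError("empty XYZ file", line=1)
    return frames


def write_xyz(path: str, elements: list[str], coords: np.ndarray,
              comment: str = "", append: bool = False) -> None:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, coords):
            fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def write_frames(path: str, frames) -> None:
    for k, (elements, coords, comment) in enumerate(frames):
        write_xyz(path, elements, coords, comment=comment, append=k > 0)
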