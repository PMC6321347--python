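"""Atoms, Cartesian geometries and multi-frame XYZ trajectories.

A :class:`Geometry` is an ordered list of atoms plus an N x 3 array of
Cartesian coordinates in Angstrom; a :class:`Trajectory` is an ordered list
of geometries sharing the same atom sequence.  XYZ files follow the plain
dialect: atom count, comment line, then ``symbol x y z`` records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Geometry",
    "Trajectory",
    "UnknownElementError",
    "read_xyz",
    "read_trajectory",
    "write_xyz",
    "write_trajectory",
]


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the bundled periodic table."""


def _load_periodic_table():
    with resources.files("mechkit.data").joinpath("covalent_radii.json").open() as fh:
        data = json.load(fh)
    return data["radii"], data["atomic_numbers"]


COVALENT_RADII, ATOMIC_NUMBERS = _load_periodic_table()


@dataclass(frozen=True)
class Atom:
    """A chemical element with atomic number and covalent radius (Angstrom)."""

    symbol: str
    Z: int
    r_cov: float

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.r_cov <= 0:
            raise ValueError(f"covalent radius must be > 0, got {self.r_cov}")

    @classmethod
    def from_symbol(cls, symbol: str) -> "Atom":
        sym = symbol.capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise UnknownElementError(
                f"unknown element symbol {symbol!r}: not in bundled periodic table"
            )
        return cls(symbol=sym, Z=ATOMIC_NUMBERS[sym], r_cov=COVALENT_RADII[sym])


@dataclass
class Geometry:
    """Ordered atoms plus Cartesian coordinates (Angstrom)."""

    atoms: list[Atom]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N x 3, got shape {self.coords.shape}")
        if len(self.atoms) != len(self.coords):
            raise ValueError(
                f"{len(self.atoms)} atoms but {len(self.coords)} coordinate rows"
            )
        if len(self.atoms) == 0:
            raise ValueError("geometry must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_symbols(
        cls, symbols: Sequence[str], coords, label: str = ""
    ) -> "Geometry":
        return cls([Atom.from_symbol(s) for s in symbols], np.asarray(coords, float), label)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix (Angstrom)."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Geometry":
        return Geometry(self.atoms, coords, self.label if label is None else label)


@dataclass
class Trajectory:
    """Ordered frames with a constant atom sequence; ``dt`` in femtoseconds."""

    frames: list[Geometry]
    dt: float | None = None

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        ref = self.frames[0].symbols
        for i, frame in enumerate(self.frames[1:], start=1):
            if frame.symbols != ref:
                raise ValueError(
                    f"frame {i} has a different atom sequence than frame 0"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms


# ---------------------------------------------------------------------------
# XYZ I/O


def _parse_frames(lines: list[str], path: str) -> Iterable[Geometry]:
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"{path}: frame {frame_idx}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n >= len(lines) + 1 and i + 2 + n > len(lines):
            raise ValueError(f"{path}: frame {frame_idx} is truncated")
        comment = lines[i + 1].rstrip("\n")
        symbols, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: frame {frame_idx}, atom {j}: malformed record "
                    f"{lines[i + 2 + j]!r}"
                )
            symbols.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        yield Geometry.from_symbols(symbols, np.array(coords), label=comment)
        i += 2 + n
        frame_idx += 1


def read_xyz(path) -> Geometry:
    """Read a single-frame XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames = list(_parse_frames(lines, str(path)))
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return frames[0]


def read_trajectory(path, dt: float | None = None) -> Trajectory:
    """Read a multi-frame XYZ file, validating the atom sequence per frame."""
    lines = Path(path).read_text().splitlines()
    frames = []
    for idx, geom in enumerate(_parse_frames(lines, str(path))):
        if frames and geom.symbols != frames[0].symbols:
            raise ValueError(
                f"{path}: frame {idx} has a different element order than frame 0"
            )
        frames.append(geom)
    if not frames:
        raise ValueError(f"{path}: empty trajectory file")
    if len(frames) < 2:
        raise ValueError(f"{path}: a trajectory needs at least 2 frames, got 1")
    return Trajectory(frames, dt=dt)


def write_xyz(path, geom: Geometry) -> None:
    Path(path).write_text(_format_frame(geom))


def write_trajectory(path, traj: Trajectory) -> None:
    Path(path).write_text("".join(_format_frame(f) for f in traj.frames))


def _format_frame(geom: Geometry) -> str:
    out = [f"{geom.n_atoms}\n{geom.label}\n"]
    for atom, (x, y, z) in zip(geom.atoms, geom.coords):
        out.append(f"{atom.symbol:<3s} {x:16.6f} {y:16.6f} {z:16.6f}\n")
    return "".join(out)
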