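"""Reaction-coordinate geometry: centers of mass and inter-group distances.

The dimerization reaction coordinate xi is the distance between the center
of mass (COM) of the acceptor hydrophobic pocket and the COM of the donor
Val-beta6 side chain.  These operations take explicit atom groups; which
atoms constitute "the pocket" (all atoms, heavy atoms, side chains) is the
caller's decision.

Coordinates are in nm and masses in u.  Inputs are assumed whole/unwrapped;
no periodic-boundary minimum-image convention is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomGroup",
    "TimeSeries",
    "center_of_mass",
    "com_distance",
    "min_distance",
    "group_from_pdb",
]


@dataclass(frozen=True)
class AtomGroup:
    """A set of atoms with labels, coordinates (nm) and masses (u)."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n, 3), nm
    masses: np.ndarray  # (n,), u

    def __init__(
        self,
        labels: Sequence[str],
        coordinates: np.ndarray,
        masses: np.ndarray,
    ) -> None:
        coords = np.asarray(coordinates, dtype=float)
        m = np.asarray(masses, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got shape {coords.shape}")
        n = coords.shape[0]
        if n < 1:
            raise ValueError("atom group must contain at least one atom")
        if m.shape != (n,):
            raise ValueError(
                f"masses length {m.shape} does not match {n} coordinates"
            )
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if not np.all(m > 0):
            raise ValueError("all masses must be positive")
        object.__setattr__(self, "labels", tuple(str(x) for x in labels))
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "masses", m)

    def __len__(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class TimeSeries:
    """A scalar time series: times in ps (strictly increasing), values in nm."""

    times: np.ndarray
    values: np.ndarray

    def __init__(self, times, values) -> None:
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("time series must be non-empty")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def tail(self, fraction: float) -> "TimeSeries":
        """The final `fraction` of the series (at least one point)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n = max(1, int(round(fraction * len(self))))
        return TimeSeries(self.times[-n:], self.values[-n:])

    def discard_burn_in(self, fraction: float) -> "TimeSeries":
        """Drop the first `fraction` of points (equilibration phase)."""
        if not 0 <= fraction < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        start = int(fraction * len(self))
        if start >= len(self):
            raise ValueError("burn-in removes all samples")
        return TimeSeries(self.times[start:], self.values[start:])


def center_of_mass(group: AtomGroup) -> np.ndarray:
    """Mass-weighted mean position of an atom group, in nm."""
    return group.masses @ group.coordinates / group.masses.sum()


def com_distance(group_a: AtomGroup, group_b: AtomGroup) -> float:
    """Euclidean distance between the two groups' centers of mass (nm).

    This is the reaction coordinate xi when applied to the pocket group and
    the Val-beta6 group.  Symmetric and non-negative.
    """
    return float(np.linalg.norm(center_of_mass(group_a) - center_of_mass(group_b)))


def min_distance(group_a: AtomGroup, group_b: AtomGroup) -> float:
    """Minimum distance over all inter-group atom pairs (nm)."""
    return float(cdist(group_a.coordinates, group_b.coordinates).min())


def group_from_pdb(path, selection: str) -> AtomGroup:
    """Build an AtomGroup from a PDB file via an MDAnalysis selection.

    PDB coordinates (Angstrom) are converted to nm.  Requires MDAnalysis,
    which is an optional dependency (`pip install pmfkit[pdb]`).
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "PDB support requires MDAnalysis (install extra 'pdb')"
        ) from exc
    universe = mda.Universe(str(path))
    atoms = universe.select_atoms(selection)
    if len(atoms) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms in {path}")
    return AtomGroup(
        labels=[f"{a.resname}{a.resid}:{a.name}" for a in atoms],
        coordinates=atoms.positions / 10.0,
        masses=atoms.masses,
    )
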