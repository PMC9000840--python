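"""Core domain types for crowded-solution trajectory analysis.

The package models a periodic simulation box containing a mixture of
protein, water, PEG-4 (tetraethylene glycol) crowder, and counter-ions.
Everything downstream (diffusion, viscosity, solvation observables)
consumes the small set of containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np


class UnsupportedFeatureError(ValueError):
    """Raised for inputs outside the supported feature set (e.g. triclinic boxes)."""


class MoleculeClass(str, Enum):
    PROTEIN = "protein"
    WATER = "water"
    PEG4 = "peg4"
    ION = "ion"


#: Default residue-name -> molecule-class map.  Unmapped residues raise,
#: never guess.
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}

DEFAULT_RESIDUE_CLASS_MAP: dict[str, MoleculeClass] = {
    **{aa: MoleculeClass.PROTEIN for aa in STANDARD_AMINO_ACIDS},
    "SOL": MoleculeClass.WATER,
    "WAT": MoleculeClass.WATER,
    "HOH": MoleculeClass.WATER,
    "TIP3": MoleculeClass.WATER,
    "PEG": MoleculeClass.PEG4,
    "TEG": MoleculeClass.PEG4,
    "PRT": MoleculeClass.PROTEIN,
    "CL": MoleculeClass.ION,
    "NA": MoleculeClass.ION,
    "CL-": MoleculeClass.ION,
    "NA+": MoleculeClass.ION,
    "K": MoleculeClass.ION,
    "K+": MoleculeClass.ION,
}


def classify_residue(residue_name: str,
                     class_map: dict[str, MoleculeClass] | None = None) -> MoleculeClass:
    """Map a residue name to a molecule class; unmapped names are an error."""
    cmap = DEFAULT_RESIDUE_CLASS_MAP if class_map is None else class_map
    key = residue_name.strip().upper()
    try:
        return cmap[key]
    except KeyError:
        raise KeyError(
            f"residue name {residue_name!r} has no molecule-class mapping; "
            "extend the residue class map explicitly instead of guessing"
        ) from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, mass (g/mol), partial charge (e), LJ parameters (nm, kJ/mol)."""

    index: int
    name: str
    residue_name: str
    residue_index: int
    molecule_class: MoleculeClass
    mass: float
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index} ({self.name}): mass must be > 0, got {self.mass}")
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.index} ({self.name}): charge must be finite")


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or any(l <= 0 for l in self.lengths):
            raise ValueError(f"box lengths must be three positive values, got {self.lengths}")
        object.__setattr__(self, "lengths", tuple(float(l) for l in self.lengths))

    @property
    def volume(self) -> float:
        lx, ly, lz = self.lengths
        return lx * ly * lz

    def as_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @classmethod
    def cubic(cls, length: float) -> "Box":
        return cls((length, length, length))


@dataclass
class Frame:
    """One trajectory frame: time (ps), positions (nm), optional velocities (nm/ps)."""

    time: float
    positions: np.ndarray
    box: Box
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n_atoms, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology."""

    topology: list[AtomRecord]
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} atoms but topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def time_step(self) -> float:
        """Frame spacing in ps (requires >= 2 frames, uniform spacing assumed)."""
        t = self.times
        if len(t) < 2:
            raise ValueError("time_step undefined for < 2 frames")
        return float(t[1] - t[0])

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked positions."""
        return np.stack([fr.positions for fr in self.frames])

    def select(self, molecule_class: MoleculeClass | str) -> np.ndarray:
        """Indices of atoms belonging to the given molecule class."""
        mc = MoleculeClass(molecule_class)
        return np.array([a.index for a in self.topology if a.molecule_class is mc],
                        dtype=int)


def molecules_of(topology: Sequence[AtomRecord],
                 molecule_class: MoleculeClass | str) -> list[np.ndarray]:
    """Group atom indices into molecules (contiguous residue_index runs) of one class.

    Residue index identifies the molecule for water/PEG-4/ions; the whole
    protein (all protein-class atoms) is treated as a single molecule.
    """
    mc = MoleculeClass(molecule_class)
    if mc is MoleculeClass.PROTEIN:
        idx = np.array([a.index for a in topology if a.molecule_class is mc], dtype=int)
        return [idx] if len(idx) else []
    groups: dict[int, list[int]] = {}
    for a in topology:
        if a.molecule_class is mc:
            groups.setdefault(a.residue_index, []).append(a.index)
    return [np.array(groups[k], dtype=int) for k in sorted(groups)]


def masses_of(topology: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.mass for a in topology])


def charges_of(topology: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.charge for a in topology])


@dataclass
class PressureTensorSeries:
    """Off-diagonal pressure tensor components over time.

    times in ps, components in bar, box volume in nm^3, temperature in K.
    ``components`` maps the six labels (xy, xz, yz, yx, zx, zy) to arrays.
    """

    times: np.ndarray
    components: dict[str, np.ndarray]
    box_volume: float
    temperature: float

    LABELS = ("xy", "xz", "yz", "yx", "zx", "zy")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        missing = [l for l in self.LABELS if l not in self.components]
        if missing:
            raise ValueError(f"missing pressure components: {missing}")
        n = len(self.times)
        for label in self.LABELS:
            arr = np.asarray(self.components[label], dtype=float)
            if len(arr) != n:
                raise ValueError(
                    f"component {label} has length {len(arr)}, times has {n}"
                )
            self.components[label] = arr
        if n >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def stacked(self) -> np.ndarray:
        """(6, n) array of components in label order."""
        return np.stack([self.components[l] for l in self.LABELS])
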