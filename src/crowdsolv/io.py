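"""Readers and writers for coordinates, trajectories, and pressure-tensor series.

Supported formats:

* GRO / PDB single configurations (box from the GRO box line / ``CRYST1``);
* XTC trajectories (via MDAnalysis) and a plain-text ``frames_text`` format
  used as a dependency-free fixture format;
* GROMACS XVG (``#`` comments, ``@`` directives) and CSV pressure-tensor
  series.

All coordinates are converted to nm on read (PDB is stored in Å).  Only
orthorhombic boxes are supported; triclinic input raises
:class:`~crowdsolv.model.UnsupportedFeatureError`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import NM_PER_ANGSTROM, ANGSTROM_PER_NM
from .model import (
    AtomRecord,
    Box,
    Frame,
    MoleculeClass,
    PressureTensorSeries,
    Trajectory,
    UnsupportedFeatureError,
    classify_residue,
)


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending line."""


#: Minimal element mass table (g/mol) for atoms named by element-leading
#: convention; used when no explicit topology table is supplied.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CL": 35.45, "NA": 22.990, "K": 39.098, "F": 18.998,
    "BR": 79.904, "I": 126.904, "M": 0.0,
}


def guess_element(atom_name: str) -> str:
    """Guess the element from an atom name (leading letters, two-letter ions first)."""
    stripped = atom_name.strip().lstrip("0123456789")
    upper = stripped.upper()
    for two in ("CL", "NA", "BR"):
        if upper.startswith(two):
            return two
    for ch in upper:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot guess element for atom name {atom_name!r}")


def guess_mass(atom_name: str) -> float:
    elem = guess_element(atom_name)
    try:
        mass = ELEMENT_MASSES[elem]
    except KeyError:
        raise ValueError(f"no mass for element {elem!r} (atom {atom_name!r})") from None
    if mass <= 0:
        raise ValueError(f"element {elem!r} has non-positive mass")
    return mass


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

def read_configuration(path: str | Path, format: str | None = None, *,
                       box: Box | None = None,
                       class_map=None) -> tuple[list[AtomRecord], Frame]:
    """Read a GRO or PDB configuration into a topology and a single frame.

    Masses are guessed from element names; charges and LJ parameters default
    to zero and are typically filled in from a separate topology table.
    ``box`` overrides/provides the periodic box when the file lacks one.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "gro":
        return _read_gro(path, box_override=box, class_map=class_map)
    if format == "pdb":
        return _read_pdb(path, box_override=box, class_map=class_map)
    raise ValueError(f"unsupported configuration format {format!r} (use 'gro' or 'pdb')")


def _read_gro(path: Path, box_override: Box | None, class_map) -> tuple[list[AtomRecord], Frame]:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: GRO file needs title, atom count, atoms, box line")
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"{path}, line 2: expected atom count, got {lines[1]!r}") from None
    if len(lines) < natoms + 3:
        raise ParseError(f"{path}: declared {natoms} atoms but file has "
                         f"{len(lines) - 3} atom lines")
    topology: list[AtomRecord] = []
    positions = np.zeros((natoms, 3))
    velocities = np.zeros((natoms, 3))
    has_velocities = False
    for i in range(natoms):
        lineno = i + 3
        line = lines[lineno - 1]
        # fixed columns: resid(5) resname(5) atomname(5) serial(5) x,y,z (%8.3f)
        if len(line) < 44:
            raise ParseError(f"{path}, line {lineno}: truncated GRO atom record "
                             f"({len(line)} chars, need >= 44)")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            x = float(line[20:28]); y = float(line[28:36]); z = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: malformed GRO atom record: {exc}") from None
        positions[i] = (x, y, z)
        if len(line) >= 68:
            try:
                velocities[i] = (float(line[44:52]), float(line[52:60]), float(line[60:68]))
                has_velocities = True
            except ValueError:
                pass
        topology.append(AtomRecord(
            index=i, name=name, residue_name=resname, residue_index=resid,
            molecule_class=classify_residue(resname, class_map),
            mass=guess_mass(name)))
    box_line = lines[natoms + 2].split()
    if box_override is not None:
        frame_box = box_override
    else:
        if not box_line:
            raise ParseError(
                f"{path}: missing GRO box line; pass an explicit box override")
        vals = [float(v) for v in box_line]
        if len(vals) > 3 and any(abs(v) > 1e-12 for v in vals[3:]):
            raise UnsupportedFeatureError(
                f"{path}: triclinic box not supported (off-diagonal terms {vals[3:]})")
        frame_box = Box(tuple(vals[:3]))
    frame = Frame(time=0.0, positions=positions, box=frame_box,
                  velocities=velocities if has_velocities else None)
    return topology, frame


def _read_pdb(path: Path, box_override: Box | None, class_map) -> tuple[list[AtomRecord], Frame]:
    topology: list[AtomRecord] = []
    positions: list[tuple[float, float, float]] = []
    frame_box = box_override
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record == "CRYST1":
            try:
                a = float(line[6:15]); b = float(line[15:24]); c = float(line[24:33])
                alpha = float(line[33:40]); beta = float(line[40:47]); gamma = float(line[47:54])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: malformed CRYST1: {exc}") from None
            if any(abs(ang - 90.0) > 1e-6 for ang in (alpha, beta, gamma)):
                raise UnsupportedFeatureError(
                    f"{path}, line {lineno}: triclinic cell (angles {alpha}, {beta}, "
                    f"{gamma}) not supported")
            if box_override is None:
                frame_box = Box((a * NM_PER_ANGSTROM, b * NM_PER_ANGSTROM,
                                 c * NM_PER_ANGSTROM))
        elif record in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"{path}, line {lineno}: truncated {record} record")
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip()
                resid = int(line[22:26])
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: malformed {record} record: "
                                 f"{exc}") from None
            positions.append((x * NM_PER_ANGSTROM, y * NM_PER_ANGSTROM,
                              z * NM_PER_ANGSTROM))
            topology.append(AtomRecord(
                index=len(topology), name=name, residue_name=resname,
                residue_index=resid,
                molecule_class=classify_residue(resname, class_map),
                mass=guess_mass(name)))
    if not topology:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if frame_box is None:
        raise ParseError(f"{path}: no CRYST1 record; pass an explicit box override")
    frame = Frame(time=0.0, positions=np.array(positions), box=frame_box)
    return topology, frame


def write_gro(path: str | Path, topology: Sequence[AtomRecord], frame: Frame,
              title: str = "crowdsolv configuration") -> None:
    lines = [title, f"{len(topology):5d}"]
    vel = frame.velocities
    for atom, pos in zip(topology, frame.positions):
        base = (f"{atom.residue_index % 100000:5d}{atom.residue_name:<5s}"
                f"{atom.name:>5s}{(atom.index + 1) % 100000:5d}"
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}")
        if vel is not None:
            v = vel[atom.index]
            base += f"{v[0]:8.4f}{v[1]:8.4f}{v[2]:8.4f}"
        lines.append(base)
    lx, ly, lz = frame.box.lengths
    lines.append(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# topology tables
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = ("index", "name", "residue_name", "residue_index",
                     "molecule_class", "mass", "charge", "lj_sigma", "lj_epsilon")


def write_topology_table(path: str | Path, topology: Sequence[AtomRecord]) -> None:
    """CSV topology table: per-atom identity, mass, charge, LJ parameters."""
    with open(path, "w") as fh:
        fh.write(",".join(_TOPOLOGY_COLUMNS) + "\n")
        for a in topology:
            fh.write(f"{a.index},{a.name},{a.residue_name},{a.residue_index},"
                     f"{a.molecule_class.value},{a.mass!r},{a.charge!r},"
                     f"{a.lj_sigma!r},{a.lj_epsilon!r}\n")


def read_topology_table(path: str | Path) -> list[AtomRecord]:
    import csv

    topology = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        missing = set(_TOPOLOGY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: topology table missing columns {sorted(missing)}")
        for row in reader:
            topology.append(AtomRecord(
                index=int(row["index"]), name=row["name"],
                residue_name=row["residue_name"],
                residue_index=int(row["residue_index"]),
                molecule_class=MoleculeClass(row["molecule_class"]),
                mass=float(row["mass"]), charge=float(row["charge"]),
                lj_sigma=float(row["lj_sigma"]),
                lj_epsilon=float(row["lj_epsilon"])))
    return topology


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, topology: Sequence[AtomRecord],
                    format: str | None = None) -> Trajectory:
    """Read an XTC or frames_text trajectory onto an existing topology."""
    path = Path(path)
    if format is None:
        format = "xtc" if path.suffix.lower() == ".xtc" else "frames_text"
    if format == "xtc":
        frames = _read_xtc_frames(path, len(topology))
    elif format == "frames_text":
        frames = _read_frames_text(path, len(topology))
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    return Trajectory(topology=list(topology), frames=frames)


def _read_xtc_frames(path: Path, natoms: int) -> list[Frame]:
    from MDAnalysis.coordinates.XTC import XTCReader

    frames = []
    with XTCReader(str(path)) as reader:
        if reader.n_atoms != natoms:
            raise ValueError(
                f"atom-count mismatch: topology has {natoms} atoms, "
                f"XTC {path} has {reader.n_atoms}")
        for ts in reader:
            dims = ts.dimensions
            if dims is None or not np.any(dims[:3]):
                raise ParseError(f"{path}: XTC frame {ts.frame} lacks box dimensions")
            if any(abs(ang - 90.0) > 1e-3 for ang in dims[3:6]):
                raise UnsupportedFeatureError(f"{path}: triclinic XTC box not supported")
            frames.append(Frame(
                time=float(ts.time),
                positions=ts.positions.astype(float) * NM_PER_ANGSTROM,
                box=Box(tuple(float(d) * NM_PER_ANGSTROM for d in dims[:3]))))
    return frames


def write_xtc(path: str | Path, trajectory: Trajectory) -> None:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.XTC import XTCWriter

    n = trajectory.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with XTCWriter(str(path), n_atoms=n) as writer:
        for i, fr in enumerate(trajectory.frames):
            lx, ly, lz = fr.box.lengths
            u.atoms.positions = (fr.positions * ANGSTROM_PER_NM).astype(np.float32)
            u.trajectory.ts.dimensions = np.array(
                [lx * ANGSTROM_PER_NM, ly * ANGSTROM_PER_NM,
                 lz * ANGSTROM_PER_NM, 90.0, 90.0, 90.0])
            u.trajectory.ts.time = fr.time
            u.trajectory.ts.frame = i
            writer.write(u.atoms)


def _read_frames_text(path: Path, natoms: int) -> list[Frame]:
    frames = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            fields = header.split()
            if len(fields) != 5:
                raise ParseError(f"{path}, line {lineno}: frame header needs "
                                 f"'natoms time Lx Ly Lz', got {header!r}")
            n = int(fields[0])
            if n != natoms:
                raise ValueError(f"atom-count mismatch: topology has {natoms} atoms, "
                                 f"{path} frame declares {n}")
            time = float(fields[1])
            box = Box((float(fields[2]), float(fields[3]), float(fields[4])))
            pos = np.zeros((n, 3))
            vel = np.zeros((n, 3))
            has_vel = False
            for i in range(n):
                line = fh.readline()
                lineno += 1
                vals = line.split()
                if len(vals) not in (3, 6):
                    raise ParseError(f"{path}, line {lineno}: expected 'x y z [vx vy vz]', "
                                     f"got {line!r}")
                pos[i] = [float(v) for v in vals[:3]]
                if len(vals) == 6:
                    vel[i] = [float(v) for v in vals[3:]]
                    has_vel = True
            frames.append(Frame(time=time, positions=pos, box=box,
                                velocities=vel if has_vel else None))
    return frames


def write_frames_text(path: str | Path, trajectory: Trajectory) -> None:
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            lx, ly, lz = fr.box.lengths
            fh.write(f"{fr.n_atoms} {fr.time:.10g} {lx:.10g} {ly:.10g} {lz:.10g}\n")
            vel = fr.velocities
            for i in range(fr.n_atoms):
                x, y, z = fr.positions[i]
                if vel is not None:
                    vx, vy, vz = vel[i]
                    fh.write(f"{x:.10g} {y:.10g} {z:.10g} {vx:.10g} {vy:.10g} {vz:.10g}\n")
                else:
                    fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

def unwrap(trajectory: Trajectory) -> Trajectory:
    """Remove periodic jumps so displacements are continuous across frames.

    Each consecutive displacement is replaced by its minimum image; the
    first frame is kept as-is.  Requires sampling fine enough that no true
    displacement reaches half a box length; an exact half-box minimum-image
    displacement is ambiguous and triggers a warning.
    """
    if len(trajectory) == 0:
        return trajectory
    new_frames = [Frame(time=trajectory.frames[0].time,
                        positions=trajectory.frames[0].positions.copy(),
                        box=trajectory.frames[0].box,
                        velocities=trajectory.frames[0].velocities)]
    prev_raw = trajectory.frames[0].positions
    for fidx in range(1, len(trajectory)):
        fr = trajectory.frames[fidx]
        L = fr.box.as_array()
        d = fr.positions - prev_raw
        d_min = d - L * np.round(d / L)
        ambiguous = np.abs(d_min) >= L / 2 - 1e-12
        if np.any(ambiguous):
            atoms = np.unique(np.nonzero(ambiguous)[0])
            warnings.warn(
                f"ambiguous unwrap at frame {fidx} for atom(s) {atoms.tolist()}: "
                "displacement reaches half the box length", stacklevel=2)
        new_frames.append(Frame(time=fr.time,
                                positions=new_frames[-1].positions + d_min,
                                box=fr.box, velocities=fr.velocities))
        prev_raw = fr.positions
    return Trajectory(topology=trajectory.topology, frames=new_frames)


def wrap(trajectory: Trajectory) -> Trajectory:
    """Wrap all coordinates into [0, L) per axis."""
    frames = []
    for fr in trajectory.frames:
        L = fr.box.as_array()
        frames.append(Frame(time=fr.time, positions=np.mod(fr.positions, L),
                            box=fr.box, velocities=fr.velocities))
    return Trajectory(topology=trajectory.topology, frames=frames)


# ---------------------------------------------------------------------------
# pressure tensor series
# ---------------------------------------------------------------------------

#: Order in which six-column files list the off-diagonal components
#: (GROMACS ``gmx energy`` order), and the 3-column mirrored map.
SIX_COLUMN_ORDER = ("xy", "xz", "yz", "yx", "zx", "zy")
THREE_COLUMN_MIRROR = {"xy": "yx", "xz": "zx", "yz": "zy"}


def read_pressure_series(path: str | Path, format: str | None = None, *,
                         box_volume: float, temperature: float) -> PressureTensorSeries:
    """Read a pressure-tensor time series (time ps + 6 or 3 off-diagonal columns, bar).

    With three columns the mirrored components are duplicated
    (P_xy = P_yx etc.), matching the symmetric-virial convention of MD
    engine output.
    """
    path = Path(path)
    if format is None:
        format = "xvg" if path.suffix.lower() == ".xvg" else "csv"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if format == "xvg" and (s.startswith("#") or s.startswith("@")):
                continue
            if format == "csv" and lineno == 1 and any(
                    c.isalpha() for c in s.replace("e", "").replace("E", "")):
                continue  # header row
            sep = "," if format == "csv" else None
            vals = [float(v) for v in (s.split(sep))]
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no numeric rows found")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ParseError(f"{path}: inconsistent column counts")
    if ncol not in (4, 7):
        raise ParseError(f"{path}: need time + 3 or 6 pressure columns, got {ncol} columns")
    data = np.asarray(rows)
    times = data[:, 0]
    comps: dict[str, np.ndarray] = {}
    if ncol == 7:
        for j, label in enumerate(SIX_COLUMN_ORDER):
            comps[label] = data[:, j + 1]
    else:
        for j, label in enumerate(("xy", "xz", "yz")):
            comps[label] = data[:, j + 1]
            comps[THREE_COLUMN_MIRROR[label]] = data[:, j + 1]
    return PressureTensorSeries(times=times, components=comps,
                                box_volume=box_volume, temperature=temperature)


def write_pressure_csv(path: str | Path, series: PressureTensorSeries) -> None:
    with open(path, "w") as fh:
        fh.write("time_ps," + ",".join(f"P{l}_bar" for l in SIX_COLUMN_ORDER) + "\n")
        stacked = series.stacked()
        for i, t in enumerate(series.times):
            fh.write(f"{float(t)!r}," + ",".join(repr(float(stacked[j, i]))
                                          for j in range(6)) + "\n")
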