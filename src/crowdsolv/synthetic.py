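"""Synthetic-data generators with known ground truth.

Each generator stands in for an MD production run at desk scale and
embeds its target parameter and seed in the returned metadata, so every
analysis estimator in the package can be validated against a known answer:

* :func:`brownian_trajectory` — overdamped Brownian particles of prescribed
  diffusion constant in a periodic box (MSD/diffusion chain);
* :func:`cosine_flow_trajectory` — steady cosine velocity profile of
  prescribed viscosity with Gaussian noise (periodic-perturbation chain);
* :func:`ou_pressure_series` — stationary exponentially correlated
  (Ornstein–Uhlenbeck/AR(1)) pressure-tensor components with a closed-form
  Green–Kubo viscosity (Einstein–Helfand chain);
* :func:`toy_solution` — a packed protein-bead/water/PEG-4 configuration
  with partial charges straddling the 0.2 e hydrophobicity threshold
  (solvation, H-bond, energy, SASA observables).

Brownian rather than inertial dynamics is deliberate: the MSD is linear
from the first step, so fit-window behavior can be tested without modeling
the ballistic short-time regime of real MD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import K_B, M3_PER_NM3, MPAS_PER_PAS, PA_PER_BAR, S_PER_PS
from .model import (
    AtomRecord,
    Box,
    Frame,
    MoleculeClass,
    PressureTensorSeries,
    Trajectory,
)


@dataclass
class SyntheticResult:
    """A generated object plus self-describing metadata (seed, targets)."""

    metadata: dict
    trajectory: Trajectory | None = None
    wrapped: Trajectory | None = None
    pressure_series: PressureTensorSeries | None = None
    topology: list[AtomRecord] | None = None
    frame: Frame | None = None


def _point_topology(n: int, residue_name: str = "SOL", name: str = "OW",
                    mass: float = 18.015) -> list[AtomRecord]:
    cls = MoleculeClass.WATER if residue_name == "SOL" else MoleculeClass.ION
    return [AtomRecord(index=i, name=name, residue_name=residue_name,
                       residue_index=i + 1, molecule_class=cls, mass=mass)
            for i in range(n)]


def brownian_trajectory(n_particles: int, n_steps: int, dt: float, box: Box,
                        D_target: float, seed: int) -> SyntheticResult:
    """Brownian point particles with diffusion constant ``D_target`` (1e-5 cm²/s).

    Per-axis Gaussian increments of variance 2·D·dt; returns both the
    continuous (unwrapped) trajectory and its wrapped variant.
    """
    if D_target < 0:
        raise ValueError("D_target must be non-negative")
    rng = np.random.default_rng(seed)
    D_nm2_ps = D_target / 1000.0  # 1e-5 cm^2/s -> nm^2/ps
    sd = np.sqrt(2.0 * D_nm2_ps * dt)
    L = box.as_array()
    start = rng.uniform(0.0, L, size=(n_particles, 3))
    if sd > 0:
        steps = rng.normal(0.0, sd, size=(n_steps, n_particles, 3))
    else:
        steps = np.zeros((n_steps, n_particles, 3))
    path = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    topology = _point_topology(n_particles)
    times = np.arange(n_steps + 1) * dt
    frames = [Frame(time=float(t), positions=path[i], box=box)
              for i, t in enumerate(times)]
    wrapped = [Frame(time=float(t), positions=np.mod(path[i], L), box=box)
               for i, t in enumerate(times)]
    meta = {"generator": "brownian", "seed": seed, "D_target": D_target,
            "n_particles": n_particles, "n_steps": n_steps, "dt_ps": dt,
            "step_sd_nm": float(sd)}
    return SyntheticResult(metadata=meta,
                           trajectory=Trajectory(topology, frames),
                           wrapped=Trajectory(topology, wrapped))


def cosine_flow_amplitude(eta_target: float, density: float, amplitude: float,
                          box_height: float) -> float:
    """Velocity amplitude V (nm/ps) of the steady cosine flow for a given
    viscosity (mPa·s), density (g/mL), and forcing amplitude (nm/ps²)."""
    rho_si = density * 1000.0
    a_si = amplitude * 1e-9 / S_PER_PS ** 2
    lz_si = box_height * 1e-9
    v_si = rho_si * a_si * (lz_si / (2.0 * np.pi)) ** 2 / (eta_target * 1e-3)
    return v_si * S_PER_PS / 1e-9  # m/s -> nm/ps


def cosine_flow_trajectory(n_atoms: int, box: Box, eta_target: float,
                           seed: int, density: float = 1.0,
                           amplitude: float = 0.05, noise_sd: float = 0.0,
                           n_frames: int = 1) -> SyntheticResult:
    """Atoms with x-velocities ``V·cos(2πz/l_z) + noise`` of prescribed viscosity.

    ``eta_target`` in mPa·s; V is the exact inversion of the
    periodic-perturbation relation, so the estimator should recover
    ``eta_target`` up to the noise level.
    """
    if eta_target <= 0:
        raise ValueError("eta_target must be positive")
    rng = np.random.default_rng(seed)
    lz = box.lengths[2]
    V = cosine_flow_amplitude(eta_target, density, amplitude, lz)
    topology = _point_topology(n_atoms)
    frames = []
    for i in range(n_frames):
        pos = rng.uniform(0.0, box.as_array(), size=(n_atoms, 3))
        vel = np.zeros((n_atoms, 3))
        vel[:, 0] = V * np.cos(2.0 * np.pi * pos[:, 2] / lz)
        if noise_sd > 0:
            vel += rng.normal(0.0, noise_sd, size=vel.shape)
        frames.append(Frame(time=float(i), positions=pos, box=box, velocities=vel))
    meta = {"generator": "cosine_flow", "seed": seed, "eta_target": eta_target,
            "density": density, "amplitude": amplitude,
            "velocity_amplitude_nm_ps": float(V), "noise_sd": noise_sd}
    return SyntheticResult(metadata=meta, trajectory=Trajectory(topology, frames))


def ou_pressure_series(n_samples: int, dt: float, sigma_P: float, tau: float,
                       box_volume: float, temperature: float,
                       seed: int) -> SyntheticResult:
    """Six independent AR(1) pressure components with stationary sd ``sigma_P``
    (bar) and correlation time ``tau`` (ps).

    The exponential stress autocorrelation gives the closed-form Green–Kubo
    viscosity ``η = V σ_P² τ / (k_B T)``, recorded in the metadata.
    """
    if sigma_P < 0:
        raise ValueError("sigma_P must be non-negative")
    if tau < dt:
        raise ValueError("correlation time must be at least the sample spacing")
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    innov_sd = sigma_P * np.sqrt(1.0 - a * a)
    comps = {}
    for label in PressureTensorSeries.LABELS:
        if sigma_P > 0:
            x0 = rng.normal(0.0, sigma_P)
            noise = rng.normal(0.0, innov_sd, size=n_samples)
            noise[0] = x0  # stationary start
            x = lfilter([1.0], [1.0, -a], noise)
        else:
            x = np.zeros(n_samples)
        comps[label] = x
    times = np.arange(n_samples) * dt
    eta_closed = (box_volume * M3_PER_NM3) * (sigma_P * PA_PER_BAR) ** 2 \
        * (tau * S_PER_PS) / (K_B * temperature) * MPAS_PER_PAS
    meta = {"generator": "ou_pressure", "seed": seed, "sigma_P_bar": sigma_P,
            "tau_ps": tau, "box_volume_nm3": box_volume,
            "temperature_K": temperature,
            "eta_closed_form_mPas": float(eta_closed)}
    return SyntheticResult(metadata=meta, pressure_series=PressureTensorSeries(
        times=times, components=comps, box_volume=box_volume,
        temperature=temperature))


# ---------------------------------------------------------------------------
# toy solution configurations
# ---------------------------------------------------------------------------

# (name, charge e, mass g/mol, lj_sigma nm, lj_epsilon kJ/mol) per site
_WATER_SITES = [("OW", -0.834, 15.999, 0.315, 0.636),
                ("HW1", 0.417, 1.008, 0.0, 0.0),
                ("HW2", 0.417, 1.008, 0.0, 0.0)]

# 15-bead PEG-4 chain: hydroxyl H/O above the 0.2 e threshold, carbons below
_PEG_SITES = (
    [("O1", -0.60, 15.999, 0.30, 0.71), ("HO1", 0.41, 1.008, 0.0, 0.0)]
    + [(f"C{i}", 0.10, 12.011, 0.35, 0.46) for i in (1, 2)]
    + [("O2", -0.40, 15.999, 0.30, 0.71)]
    + [(f"C{i}", 0.10, 12.011, 0.35, 0.46) for i in (3, 4)]
    + [("O3", -0.40, 15.999, 0.30, 0.71)]
    + [(f"C{i}", 0.10, 12.011, 0.35, 0.46) for i in (5, 6)]
    + [("O4", -0.40, 15.999, 0.30, 0.71)]
    + [(f"C{i}", 0.10, 12.011, 0.35, 0.46) for i in (7, 8)]
    + [("O5", -0.60, 15.999, 0.30, 0.71), ("HO2", 0.41, 1.008, 0.0, 0.0)]
)
assert len(_PEG_SITES) == 15

# protein bead pattern: polar N-H and carbonyl O straddle the charge threshold
_PROTEIN_PATTERN = [("N", -0.40, 14.007, 0.33, 0.71),
                    ("H", 0.25, 1.008, 0.11, 0.066),
                    ("C", 0.05, 12.011, 0.34, 0.46),
                    ("O", -0.50, 15.999, 0.30, 0.88)]

MIN_NONBONDED_DISTANCE = 0.15  # nm, enforced between sites of different molecules


def _min_image_dist(a: np.ndarray, b: np.ndarray, L: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= L * np.round(d / L)
    return np.sqrt((d ** 2).sum(axis=2))


def toy_solution(n_water: int, n_peg: int, protein_beads: int, box: Box,
                 seed: int, max_attempts: int = 2000,
                 scripted_water_distance: float | None = None) -> SyntheticResult:
    """Packed toy configuration: protein-bead cluster + waters + PEG-4 chains.

    Protein beads form a compact cluster at the box center; waters are
    rigid 3-site molecules, PEG-4 molecules 15-bead chains.  Rejection
    sampling keeps every pair of sites from different molecules at least
    0.15 nm apart.  ``scripted_water_distance`` places the first water's
    oxygen at exactly that distance (nm) from the cluster center.
    """
    rng = np.random.default_rng(seed)
    L = box.as_array()
    center = L / 2.0
    topology: list[AtomRecord] = []
    positions: list[np.ndarray] = []
    placed = np.empty((0, 3))

    def add_molecule(site_specs, coords, residue_name, residue_index, mol_class):
        nonlocal placed
        for (name, q, m, s, e), xyz in zip(site_specs, coords):
            topology.append(AtomRecord(
                index=len(topology), name=name, residue_name=residue_name,
                residue_index=residue_index, molecule_class=mol_class,
                mass=m, charge=q, lj_sigma=s, lj_epsilon=e))
            positions.append(np.asarray(xyz, dtype=float))
        placed = np.vstack([placed, np.asarray(coords)])

    # --- protein cluster: jittered simple-cubic sites around the center
    if protein_beads > 0:
        side = int(np.ceil(protein_beads ** (1 / 3)))
        grid = []
        for ix in range(side):
            for iy in range(side):
                for iz in range(side):
                    grid.append(center + 0.22 * (np.array([ix, iy, iz])
                                                 - (side - 1) / 2.0))
        coords = [g + rng.normal(0.0, 0.01, 3) for g in grid[:protein_beads]]
        specs = [_PROTEIN_PATTERN[i % len(_PROTEIN_PATTERN)]
                 for i in range(protein_beads)]
        # topology order must keep each H after its heavy donor
        add_molecule(specs, coords, "PRT", 1, MoleculeClass.PROTEIN)

    def try_place(site_specs, local_coords, residue_name, residue_index, mol_class,
                  fixed_origin: np.ndarray | None = None):
        nonlocal placed
        for _ in range(max_attempts):
            origin = fixed_origin if fixed_origin is not None \
                else rng.uniform(0.0, L)
            theta = rng.uniform(0, 2 * np.pi)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
            R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
            coords = np.mod(origin + np.asarray(local_coords) @ R.T, L)
            if placed.shape[0]:
                if _min_image_dist(coords, placed, L).min() < MIN_NONBONDED_DISTANCE:
                    if fixed_origin is not None:
                        continue  # re-randomize orientation only
                    continue
            add_molecule(site_specs, coords, residue_name, residue_index, mol_class)
            return
        raise RuntimeError(
            f"could not place {residue_name} molecule {residue_index} after "
            f"{max_attempts} attempts; use a larger box or fewer molecules")

    # rigid 3-site water geometry (O at origin), bond 0.09572 nm, angle 104.52°
    half = np.radians(104.52 / 2)
    water_local = np.array([[0.0, 0.0, 0.0],
                            [0.09572 * np.sin(half), 0.09572 * np.cos(half), 0.0],
                            [-0.09572 * np.sin(half), 0.09572 * np.cos(half), 0.0]])

    next_res = 2
    for w in range(n_water):
        fixed = None
        if w == 0 and scripted_water_distance is not None:
            direction = np.array([1.0, 0.0, 0.0])
            fixed = np.mod(center + scripted_water_distance * direction, L)
        try_place(_WATER_SITES, water_local, "SOL", next_res,
                  MoleculeClass.WATER, fixed_origin=fixed)
        next_res += 1

    # PEG chain as a bent zig-zag with 0.145 nm bonds
    bond = 0.145
    peg_local = np.zeros((15, 3))
    for i in range(1, 15):
        step = np.array([bond, 0.0, 0.0])
        if i % 2 == 0:
            step = np.array([bond * 0.5, bond * 0.82, 0.0])
        peg_local[i] = peg_local[i - 1] + step * (1 if (i // 4) % 2 == 0 else
                                                  np.array([1, -1, 1]))
    for _ in range(n_peg):
        try_place(_PEG_SITES, peg_local, "PEG", next_res, MoleculeClass.PEG4)
        next_res += 1

    frame = Frame(time=0.0, positions=np.asarray(positions), box=box)
    meta = {"generator": "toy_solution", "seed": seed, "n_water": n_water,
            "n_peg": n_peg, "protein_beads": protein_beads,
            "min_nonbonded_distance_nm": MIN_NONBONDED_DISTANCE,
            "scripted_water_distance_nm": scripted_water_distance}
    return SyntheticResult(metadata=meta, topology=topology, frame=frame)
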