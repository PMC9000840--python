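"""Structural and interaction observables for a solvated protein.

RMSD/RMSF after optimal (Kabsch) superposition, non-normalized radial
distribution functions and solvation-shell coordination numbers, geometric
hydrogen-bond counts by molecular class, pairwise nonbonded interaction
energies (Coulomb + Lennard-Jones with Lorentz–Berthelot combination), and
Shrake–Rupley solvent accessible surface area split into hydrophilic and
hydrophobic parts at the |q| < 0.2 e partial-charge threshold.

Distances use the minimum-image convention in orthorhombic boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import COULOMB_KJMOL_NM_E2
from .model import (
    AtomRecord,
    Box,
    Frame,
    MoleculeClass,
    Trajectory,
    charges_of,
    masses_of,
    molecules_of,
)
from .io import guess_element
from .transport import block_statistics

# ---------------------------------------------------------------------------
# superposition / RMSD / RMSF
# ---------------------------------------------------------------------------


@dataclass
class Superposition:
    """Optimal proper rotation + translation and the residual RMSD (nm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None) -> Superposition:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Minimizes the (optionally mass-)weighted squared deviation over proper
    rotations; a reflection in the SVD solution is corrected by flipping the
    smallest singular direction.  Raises for fewer than 3 atoms or a
    collinear reference.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference and mobile must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 atoms, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_c = ref - w @ ref
    mob_c = mob - w @ mob
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("reference coordinates are collinear; superposition is degenerate")
    H = (mob_c * w[:, None]).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = (w @ ref) - R @ (w @ mob)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(axis=1)).sum()))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def backbone_selection(topology: Sequence[AtomRecord]) -> np.ndarray:
    """Indices of protein backbone atoms (N, CA, C)."""
    idx = [a.index for a in topology
           if a.molecule_class is MoleculeClass.PROTEIN
           and a.name.strip().upper() in ("N", "CA", "C")]
    return np.array(idx, dtype=int)


def rmsd_series(trajectory: Trajectory, reference: Frame | np.ndarray,
                selection: np.ndarray | None = None,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD (nm) after superposition onto a reference structure.

    Default selection is the protein backbone (N, CA, C); default weights
    are atomic masses.
    """
    if selection is None:
        selection = backbone_selection(trajectory.topology)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection for RMSD")
    ref_pos = reference.positions if isinstance(reference, Frame) else np.asarray(reference)
    ref_sel = ref_pos[selection]
    if weights is None:
        weights = masses_of(trajectory.topology)[selection]
    out = np.empty(len(trajectory))
    for i, fr in enumerate(trajectory.frames):
        out[i] = kabsch_superpose(ref_sel, fr.positions[selection], weights).rmsd
    return out


def rmsf(trajectory: Trajectory,
         selection: np.ndarray | None = None) -> dict[int, float]:
    """Per-residue RMSF (nm) about the superposition-averaged structure.

    Frames are superposed onto the raw mean structure, the mean is rebuilt
    from the superposed frames (one refinement pass), and per-atom
    fluctuations are averaged mass-weighted within each residue.
    """
    if len(trajectory) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is None:
        selection = backbone_selection(trajectory.topology)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection for RMSF")
    masses = masses_of(trajectory.topology)[selection]
    coords = trajectory.positions_array()[:, selection, :]
    mean = coords.mean(axis=0)

    def superpose_all(reference: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for i in range(coords.shape[0]):
            sp = kabsch_superpose(reference, coords[i], masses)
            out[i] = sp.apply(coords[i])
        return out

    aligned = superpose_all(mean)
    mean = aligned.mean(axis=0)     # refined reference
    aligned = superpose_all(mean)
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    residues = np.array([trajectory.topology[i].residue_index for i in selection])
    out: dict[int, float] = {}
    for res in np.unique(residues):
        mask = residues == res
        out[int(res)] = float((per_atom[mask] * masses[mask]).sum() / masses[mask].sum())
    return out


# ---------------------------------------------------------------------------
# solvation shell: RDF and coordination number
# ---------------------------------------------------------------------------

def minimum_image_displacements(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """(len(a), len(b), 3) minimum-image displacement vectors b − a."""
    L = box.as_array()
    d = b[None, :, :] - a[:, None, :]
    return d - L * np.round(d / L)


def shell_site_positions(frame: Frame, topology: Sequence[AtomRecord],
                         shell_group: MoleculeClass | str | Sequence[np.ndarray]
                         ) -> np.ndarray:
    """Reference-site positions for the shell molecules.

    Water molecules are represented by their oxygen atom; PEG-4 (and any
    explicit index-array groups) by their mass-weighted center of mass;
    ions by the single atom.
    """
    if isinstance(shell_group, (MoleculeClass, str)):
        mc = MoleculeClass(shell_group)
        groups = molecules_of(topology, mc)
        if mc is MoleculeClass.WATER:
            sites = []
            for g in groups:
                oxy = [i for i in g if guess_element(topology[i].name) == "O"]
                if not oxy:
                    raise ValueError(f"water molecule (atoms {g.tolist()}) has no oxygen")
                sites.append(frame.positions[oxy[0]])
            return np.asarray(sites).reshape(-1, 3)
    else:
        groups = [np.asarray(g, dtype=int) for g in shell_group]
    masses = masses_of(topology)
    sites = []
    for g in groups:
        w = masses[g]
        sites.append((frame.positions[g] * w[:, None]).sum(axis=0) / w.sum())
    return np.asarray(sites).reshape(-1, 3)


def _shell_distances(frame: Frame, topology, center_group, shell_group) -> np.ndarray:
    """Min over center atoms of the minimum-image distance to each shell site."""
    centers = frame.positions[np.asarray(center_group, dtype=int)]
    sites = shell_site_positions(frame, topology, shell_group)
    if len(sites) == 0:
        return np.empty(0)
    d = minimum_image_displacements(centers, sites, frame.box)
    return np.sqrt((d ** 2).sum(axis=2)).min(axis=0)


@dataclass
class DensityRDF:
    """Non-normalized RDF: local number density n(r) and cumulative count N(<r)."""

    bin_edges: np.ndarray
    local_density: np.ndarray     # nm^-3
    cumulative_count: np.ndarray  # average count within r

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def density_rdf(trajectory: Trajectory | Frame, center_group,
                shell_group, bin_width: float = 0.02,
                r_max: float | None = None,
                topology: Sequence[AtomRecord] | None = None) -> DensityRDF:
    """Solvent number density around a central group, not normalized by bulk.

    ``n(r) = ⟨ΔN(r)⟩ / (4π r² Δr)`` averaged over frames, with the shell
    distance taken from the nearest central atom to the shell molecule's
    reference site.  ``r_max`` defaults to (and may not exceed) half the
    smallest box length.
    """
    frames, topo = _frames_and_topology(trajectory, topology)
    L_min = min(min(fr.box.lengths) for fr in frames)
    if r_max is None:
        r_max = L_min / 2
    if r_max > L_min / 2 + 1e-9:
        raise ValueError(f"r_max = {r_max} nm exceeds half the smallest box "
                         f"length ({L_min / 2} nm)")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for fr in frames:
        dist = _shell_distances(fr, topo, center_group, shell_group)
        h, _ = np.histogram(dist, bins=edges)
        hist += h
    hist /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers ** 2 * np.diff(edges)
    local_density = np.where(shell_vol > 0, hist / shell_vol, 0.0)
    return DensityRDF(bin_edges=edges, local_density=local_density,
                      cumulative_count=np.cumsum(hist))


def coordination_number(trajectory: Trajectory | Frame, center_group,
                        shell_group, radius: float = 1.87,
                        topology: Sequence[AtomRecord] | None = None,
                        n_blocks: int = 5) -> tuple[float, float, np.ndarray]:
    """Time-averaged count of shell molecules within ``radius`` (nm).

    Returns (mean, block-derived uncertainty, per-frame counts); the
    uncertainty is 0 when there are fewer frames than blocks.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    frames, topo = _frames_and_topology(trajectory, topology)
    counts = np.array([
        float((_shell_distances(fr, topo, center_group, shell_group) <= radius).sum())
        for fr in frames])
    if len(counts) >= n_blocks:
        mean, err = block_statistics(counts, n_blocks)
    else:
        mean, err = float(counts.mean()), 0.0
    return mean, err, counts


def _frames_and_topology(traj_or_frame, topology):
    if isinstance(traj_or_frame, Trajectory):
        return traj_or_frame.frames, traj_or_frame.topology
    if topology is None:
        raise ValueError("topology must be given when passing a single Frame")
    return [traj_or_frame], topology


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criterion: donor–acceptor cutoff (nm) and
    hydrogen–donor–acceptor angle cutoff (degrees)."""

    donor_acceptor_cutoff: float = 0.35
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("H-bond cutoffs must be positive")


CLASS_PAIRS = {
    "prot-prot": (MoleculeClass.PROTEIN, MoleculeClass.PROTEIN),
    "prot-wat": (MoleculeClass.PROTEIN, MoleculeClass.WATER),
    "prot-PEG": (MoleculeClass.PROTEIN, MoleculeClass.PEG4),
    "wat-wat": (MoleculeClass.WATER, MoleculeClass.WATER),
}


def hydrogen_attachment_map(topology: Sequence[AtomRecord]) -> dict[int, list[int]]:
    """Heavy-atom index -> attached hydrogen indices, by topology order.

    Hydrogens attach to the most recent preceding heavy atom within the
    same residue (the standard GRO/PDB ordering convention).
    """
    attach: dict[int, list[int]] = {}
    last_heavy: AtomRecord | None = None
    for atom in topology:
        if guess_element(atom.name) == "H":
            if last_heavy is None or last_heavy.residue_index != atom.residue_index:
                raise ValueError(f"hydrogen atom {atom.index} ({atom.name}) has no "
                                 "preceding heavy atom in its residue")
            attach.setdefault(last_heavy.index, []).append(atom.index)
        else:
            last_heavy = atom
    return attach


def hydrogen_bonds(trajectory: Trajectory | Frame,
                   class_pair: str | tuple = "prot-wat",
                   criteria: HBondCriteria = HBondCriteria(),
                   topology: Sequence[AtomRecord] | None = None
                   ) -> np.ndarray:
    """Per-frame hydrogen-bond counts between two molecule classes.

    A bond is counted when the donor–acceptor distance is within the cutoff
    and the hydrogen–donor–acceptor angle is within the angle cutoff, for
    any hydrogen attached to the donor.  Donors are N/O heavy atoms with
    attached hydrogens; acceptors are all N/O heavy atoms.  Both directions
    of a cross-class pair are counted.
    """
    frames, topo = _frames_and_topology(trajectory, topology)
    if isinstance(class_pair, str):
        cls_a, cls_b = CLASS_PAIRS[class_pair]
    else:
        cls_a, cls_b = (MoleculeClass(c) for c in class_pair)
    attach = hydrogen_attachment_map(topo)
    def polar(atom: AtomRecord) -> bool:
        return guess_element(atom.name) in ("N", "O")

    donors_by_class = {
        cls: [a.index for a in topo
              if a.molecule_class is cls and polar(a) and a.index in attach]
        for cls in (cls_a, cls_b)}
    acceptors_by_class = {
        cls: [a.index for a in topo if a.molecule_class is cls and polar(a)]
        for cls in (cls_a, cls_b)}

    directions = [(donors_by_class[cls_a], acceptors_by_class[cls_b])]
    if cls_a is not cls_b:
        directions.append((donors_by_class[cls_b], acceptors_by_class[cls_a]))

    counts = np.zeros(len(frames))
    for fi, fr in enumerate(frames):
        total = 0
        for donors, acceptors in directions:
            if not donors or not acceptors:
                continue
            d_pos = fr.positions[donors]
            a_pos = fr.positions[acceptors]
            disp = minimum_image_displacements(d_pos, a_pos, fr.box)
            dist = np.sqrt((disp ** 2).sum(axis=2))
            for i, don in enumerate(donors):
                close = np.nonzero((dist[i] <= criteria.donor_acceptor_cutoff)
                                   & (dist[i] > 1e-9))[0]
                if close.size == 0:
                    continue
                h_idx = attach[don]
                h_disp = minimum_image_displacements(
                    fr.positions[[don]], fr.positions[h_idx], fr.box)[0]
                for j in close:
                    acc = acceptors[j]
                    if acc == don or acc in h_idx:
                        continue
                    da = disp[i, j]
                    # angle H-D-A at the donor for each attached hydrogen
                    cosang = (h_disp @ da) / (
                        np.linalg.norm(h_disp, axis=1) * np.linalg.norm(da))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if np.any(ang <= criteria.angle_cutoff):
                        total += 1
        counts[fi] = total
    return counts


# ---------------------------------------------------------------------------
# interaction energies
# ---------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    """Group–group nonbonded energy split into Coulomb and van der Waals (kJ/mol)."""

    coulomb: float
    vdw: float

    @property
    def total(self) -> float:
        return self.coulomb + self.vdw


def interaction_energy(frame: Frame, group_a, group_b,
                       topology: Sequence[AtomRecord],
                       cutoff: float = 1.0) -> EnergyDecomposition:
    """Pairwise nonbonded energy between two disjoint atom groups.

    Coulomb: ``f q_i q_j / r`` with the standard electric conversion factor
    f in kJ·mol⁻¹·nm·e⁻²; Lennard-Jones with Lorentz–Berthelot combination
    (σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_i ε_j)); minimum-image distances,
    plain spherical cutoff (nm).
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if np.intersect1d(ga, gb).size:
        raise ValueError("interaction-energy groups must be disjoint")
    for idx in np.concatenate([ga, gb]):
        atom = topology[idx]
        if not (np.isfinite(atom.lj_sigma) and np.isfinite(atom.lj_epsilon)):
            raise ValueError(f"atom {atom.index} ({atom.name}, residue "
                             f"{atom.residue_name}) has missing LJ parameters")
    q = charges_of(topology)
    sig = np.array([topology[i].lj_sigma for i in range(len(topology))])
    eps = np.array([topology[i].lj_epsilon for i in range(len(topology))])
    disp = minimum_image_displacements(frame.positions[ga], frame.positions[gb],
                                       frame.box)
    r = np.sqrt((disp ** 2).sum(axis=2))
    within = (r <= cutoff) & (r > 1e-9)
    if not within.any():
        return EnergyDecomposition(0.0, 0.0)
    qq = np.outer(q[ga], q[gb])[within]
    rr = r[within]
    coulomb = float((COULOMB_KJMOL_NM_E2 * qq / rr).sum())
    sij = 0.5 * (sig[ga][:, None] + sig[gb][None, :])[within]
    eij = np.sqrt(np.outer(eps[ga], eps[gb]))[within]
    lj_mask = eij > 0
    vdw = 0.0
    if lj_mask.any():
        sr6 = (sij[lj_mask] / rr[lj_mask]) ** 6
        vdw = float((4.0 * eij[lj_mask] * (sr6 ** 2 - sr6)).sum())
    return EnergyDecomposition(coulomb=coulomb, vdw=vdw)


def interaction_energy_series(trajectory: Trajectory, group_a, group_b,
                              cutoff: float = 1.0) -> list[EnergyDecomposition]:
    return [interaction_energy(fr, group_a, group_b, trajectory.topology, cutoff)
            for fr in trajectory.frames]


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

#: Bondi van der Waals radii, nm.
BONDI_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "P": 0.180,
    "F": 0.147, "CL": 0.175, "BR": 0.185, "I": 0.198, "NA": 0.227, "K": 0.275,
}

HYDROPHOBIC_CHARGE_THRESHOLD = 0.2  # |q| below this counts as hydrophobic


@dataclass
class SASAResult:
    """Total SASA and its hydrophilic/hydrophobic decomposition (nm²)."""

    total: float
    hydrophilic: float
    hydrophobic: float
    per_atom: np.ndarray


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(frame: Frame, topology: Sequence[AtomRecord],
         selection: np.ndarray | None = None,
         radii: dict[str, float] | None = None,
         probe: float = 0.14, n_sphere_points: int = 960,
         charge_threshold: float = HYDROPHOBIC_CHARGE_THRESHOLD) -> SASAResult:
    """Shrake–Rupley solvent accessible surface area with charge decomposition.

    Per-atom area = (exposed test points / total points) · 4π(r_i + probe)².
    Atoms with |partial charge| < ``charge_threshold`` contribute to the
    hydrophobic area, the rest to the hydrophilic area.
    """
    if radii is None:
        radii = BONDI_RADII_NM
    if selection is None:
        prot = [a.index for a in topology if a.molecule_class is MoleculeClass.PROTEIN]
        selection = np.asarray(prot if prot else [a.index for a in topology], dtype=int)
    selection = np.asarray(selection, dtype=int)
    pos = frame.positions[selection]
    r_atom = np.empty(len(selection))
    for k, idx in enumerate(selection):
        elem = guess_element(topology[idx].name)
        try:
            r_atom[k] = radii[elem]
        except KeyError:
            raise ValueError(f"no van der Waals radius for element {elem!r} "
                             f"(atom {topology[idx].name})") from None
    r_ext = r_atom + probe
    unit = _sphere_points(n_sphere_points)
    per_atom = np.zeros(len(selection))
    for k in range(len(selection)):
        pts = pos[k] + r_ext[k] * unit
        d2 = ((pos[None, :, :] - pts[:, None, :]) ** 2).sum(axis=2)
        occluders = np.ones(len(selection), dtype=bool)
        occluders[k] = False
        # only neighbors can occlude
        close = ((pos - pos[k]) ** 2).sum(axis=1) < (r_ext + r_ext[k]) ** 2
        occluders &= close
        if occluders.any():
            buried = (d2[:, occluders] < (r_ext[occluders] ** 2)[None, :]).any(axis=1)
        else:
            buried = np.zeros(n_sphere_points, dtype=bool)
        exposed_frac = 1.0 - buried.mean()
        per_atom[k] = exposed_frac * 4.0 * np.pi * r_ext[k] ** 2
    charges = charges_of(topology)[selection]
    hydrophobic = float(per_atom[np.abs(charges) < charge_threshold].sum())
    hydrophilic = float(per_atom[np.abs(charges) >= charge_threshold].sum())
    return SASAResult(total=float(per_atom.sum()), hydrophilic=hydrophilic,
                      hydrophobic=hydrophobic, per_atom=per_atom)
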