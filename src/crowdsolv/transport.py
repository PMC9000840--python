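"""Translational diffusion from trajectories, finite-size corrections, and
the hard-sphere crowding reference.

The estimator chain follows the standard solution-MD workflow:

1. mean squared displacement (MSD) of molecular centers of mass over all
   sliding time origins (Einstein relation), computed in O(N log N) per
   particle with the FFT autocorrelation identity;
2. ``D_PBC`` from the slope of the MSD over a fit window;
3. finite-size corrections: the Yeh–Hummer periodic-image term
   ``k_B T ξ / (6 π η L)`` with ξ = 2.837297 for a cubic box, and the
   solute-size variant with the additional ``−4πR²/(3L²)`` bracket term for
   a solute of hydrodynamic radius R;
4. normalization of a concentration series to its dilute reference and the
   Enskog hard-sphere decline ``(1−φ)³/(1−φ/2)`` for comparison;
5. an exponential decline fit ``exp(−k c)`` through the normalized points.

Uncertainties come from block averaging (five contiguous blocks by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .constants import (
    CM_PER_NM,
    D_NM2_PS_TO_1E5_CM2_S,
    K_B,
    M_PER_NM,
    PAS_PER_MPAS,
    S_PER_PS,
    XI_CUBIC,
)
from .model import MoleculeClass, Trajectory, masses_of, molecules_of


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MSDSeries:
    """MSD (nm²) versus lag time (ps), averaged over particles and origins."""

    lag_times: np.ndarray
    msd: np.ndarray
    n_particles: int
    n_origins: np.ndarray

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if self.msd[0] != 0.0 and self.lag_times[0] == 0.0:
            raise ValueError("msd at zero lag must be zero")


@dataclass
class DiffusionEstimate:
    """A diffusion constant in 1e-5 cm²/s with finite-size metadata."""

    D_pbc: float
    D_0: float | None = None
    uncertainty: float = 0.0
    fit_window: tuple[float, float] = (0.0, 0.0)
    correction_inputs: dict = field(default_factory=dict)
    flagged: bool = False


@dataclass
class ConcentrationSeries:
    """A scalar observable over a crowder concentration grid (% w/v)."""

    concentrations: np.ndarray
    values: np.ndarray
    reference_concentration: float | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.concentrations.shape != self.values.shape:
            raise ValueError("concentrations and values must have equal length")


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def com_positions(trajectory: Trajectory,
                  selection: MoleculeClass | str | Sequence[np.ndarray] | None
                  ) -> np.ndarray:
    """(n_frames, n_molecules, 3) mass-weighted center-of-mass positions.

    ``selection`` is a molecule class (atoms grouped into molecules by
    residue), an explicit list of atom-index arrays (one per molecule), or
    None for every atom as an independent particle.
    """
    pos = trajectory.positions_array()
    if selection is None:
        return pos
    if isinstance(selection, (MoleculeClass, str)):
        groups = molecules_of(trajectory.topology, selection)
    else:
        groups = [np.asarray(g, dtype=int) for g in selection]
    if not groups:
        raise ValueError("selection is empty")
    masses = masses_of(trajectory.topology)
    out = np.empty((pos.shape[0], len(groups), 3))
    for j, g in enumerate(groups):
        w = masses[g]
        out[:, j, :] = np.einsum("fij,i->fj", pos[:, g, :], w) / w.sum()
    return out


def _msd_fft_single(r: np.ndarray) -> np.ndarray:
    """All-origin MSD of one particle path r (n, 3) via the FFT identity."""
    n = r.shape[0]
    r = r - r.mean(axis=0)  # shift-invariant; limits FFT cancellation error
    # S2: autocorrelation of each coordinate, summed over axes
    nfft = 1 << (2 * n - 1).bit_length()
    fts = np.fft.rfft(r, n=nfft, axis=0)
    acf = np.fft.irfft(fts * np.conj(fts), n=nfft, axis=0)[:n].sum(axis=1)
    # S1 via the recursive sum of squared displacements
    sq = (r ** 2).sum(axis=1)
    ssum = 2.0 * sq.sum()
    s1 = np.empty(n)
    for m in range(n):
        if m > 0:
            ssum -= sq[m - 1] + sq[n - m]
        s1[m] = ssum
    counts = n - np.arange(n)
    return s1 / counts - 2.0 * acf / counts


def msd(trajectory: Trajectory,
        selection: MoleculeClass | str | Sequence[np.ndarray] | None = None,
        lags: Sequence[int] | None = None) -> MSDSeries:
    """Mean squared displacement over all sliding time origins.

    The trajectory must be unwrapped; a jump larger than half a box length
    between consecutive frames trips a heuristic error.  ``lags`` selects
    frame-count lags (default: every lag up to n_frames − 1).
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames for an MSD")
    com = com_positions(trajectory, selection)
    L = min(min(fr.box.lengths) for fr in trajectory.frames)
    step = np.abs(np.diff(com, axis=0))
    if step.size and step.max() > L / 2:
        raise ValueError(
            "single-step displacement exceeds half the box length: the "
            "trajectory looks wrapped; unwrap() it before computing an MSD")
    n_frames, n_particles, _ = com.shape
    msd_all = np.zeros(n_frames)
    for j in range(n_particles):
        msd_all += _msd_fft_single(com[:, j, :])
    msd_all /= n_particles
    msd_all[0] = 0.0
    times = trajectory.times
    lag_times_all = times - times[0]
    if lags is None:
        lag_idx = np.arange(n_frames)
    else:
        lag_idx = np.asarray(sorted(set(int(l) for l in lags)), dtype=int)
        if lag_idx.max() >= n_frames:
            raise ValueError("requested lag exceeds trajectory span")
    return MSDSeries(lag_times=lag_times_all[lag_idx],
                     msd=np.maximum(msd_all[lag_idx], 0.0),
                     n_particles=n_particles,
                     n_origins=n_frames - lag_idx)


def msd_brute_force(trajectory: Trajectory,
                    selection=None) -> MSDSeries:
    """O(n²) all-origins MSD; independent reference for the FFT path."""
    com = com_positions(trajectory, selection)
    n_frames, n_particles, _ = com.shape
    out = np.zeros(n_frames)
    for lag in range(1, n_frames):
        d = com[lag:] - com[:-lag]
        out[lag] = (d ** 2).sum(axis=2).mean()
    times = trajectory.times
    return MSDSeries(lag_times=times - times[0], msd=out,
                     n_particles=n_particles,
                     n_origins=n_frames - np.arange(n_frames))


# ---------------------------------------------------------------------------
# diffusion constants
# ---------------------------------------------------------------------------

def diffusion_pbc(msd_series: MSDSeries,
                  fit_window: tuple[float, float] = (0.1, 0.5)) -> DiffusionEstimate:
    """D_PBC (1e-5 cm²/s) from the OLS slope of the MSD over a lag window.

    ``fit_window`` is a fraction pair of the maximum lag; the short-time
    regime is excluded by default.  A negative fitted slope is clamped to
    zero with a flag rather than raising.
    """
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"fit window must satisfy 0 <= lo < hi <= 1, got {fit_window}")
    tmax = msd_series.lag_times[-1]
    mask = (msd_series.lag_times >= lo * tmax) & (msd_series.lag_times <= hi * tmax)
    if mask.sum() < 5:
        raise ValueError(f"fit window contains {int(mask.sum())} lag points; need >= 5")
    t = msd_series.lag_times[mask]
    y = msd_series.msd[mask]
    res = stats.linregress(t, y)
    D = res.slope / 6.0 * D_NM2_PS_TO_1E5_CM2_S
    err = res.stderr / 6.0 * D_NM2_PS_TO_1E5_CM2_S if np.isfinite(res.stderr) else 0.0
    flagged = False
    if D < 0:
        warnings.warn("negative MSD slope fitted; clamping D_PBC to 0", stacklevel=2)
        D, flagged = 0.0, True
    return DiffusionEstimate(D_pbc=float(D), uncertainty=float(err),
                             fit_window=(float(t[0]), float(t[-1])), flagged=flagged)


def _yh_correction_term(T: float, eta: float, L: float, bracket: float) -> float:
    """Finite-size correction k_B·T·bracket/(6π η L) in 1e-5 cm²/s."""
    # SI evaluation: J/K * K / (Pa·s * m) = m²/s, then to 1e-5 cm²/s
    d_m2_s = K_B * T * bracket / (6.0 * np.pi * (eta * PAS_PER_MPAS) * (L * M_PER_NM))
    return d_m2_s * 1e4 / 1e-5  # m²/s -> cm²/s (×1e4) -> units of 1e-5 cm²/s


def yeh_hummer_correction(D_pbc: float, T: float, eta: float, L: float) -> float:
    """D_0 = D_PBC + k_B·T·ξ/(6π η L) with ξ = 2.837297 (cubic box).

    T in K, η in mPa·s, L in nm; D in 1e-5 cm²/s.
    """
    if T <= 0 or eta <= 0 or L <= 0:
        raise ValueError("T, eta, L must all be positive")
    return D_pbc + _yh_correction_term(T, eta, L, XI_CUBIC)


def solute_size_correction(D_pbc: float, T: float, eta: float, L: float,
                           R: float) -> float:
    """Finite-size correction for a solute of hydrodynamic radius R (nm):

    D_0 = D_PBC + k_B·T/(6π η L) · (ξ − 4πR²/(3L²)).

    Valid for R < L/2; recovers the point-particle correction as R → 0.
    """
    if T <= 0 or eta <= 0 or L <= 0:
        raise ValueError("T, eta, L must all be positive")
    if not 0.0 <= R < L / 2:
        raise ValueError(f"hydrodynamic radius R = {R} nm must satisfy 0 <= R < L/2 "
                         f"= {L / 2} nm")
    bracket = XI_CUBIC - 4.0 * np.pi * R ** 2 / (3.0 * L ** 2)
    return D_pbc + _yh_correction_term(T, eta, L, bracket)


# ---------------------------------------------------------------------------
# hard-sphere reference and series arithmetic
# ---------------------------------------------------------------------------

def enskog_ratio(phi) -> float | np.ndarray:
    """Enskog hard-sphere self-diffusion decline D_HS/D_HS0 = (1−φ)³/(1−φ/2)."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any((phi_arr < 0) | (phi_arr >= 1)):
        raise ValueError(f"volume fraction must lie in [0, 1), got {phi}")
    out = (1.0 - phi_arr) ** 3 / (1.0 - 0.5 * phi_arr)
    return float(out) if np.isscalar(phi) or phi_arr.ndim == 0 else out


def normalize_series(series: ConcentrationSeries,
                     reference: float) -> ConcentrationSeries:
    """Divide every value by the value at the reference concentration.

    The reference point maps to exactly 1.
    """
    match = np.isclose(series.concentrations, reference)
    if not match.any():
        raise ValueError(f"reference concentration {reference} not present in series")
    ref_value = float(series.values[match][0])
    if ref_value == 0:
        raise ValueError("reference value is zero; cannot normalize")
    normalized = series.values / ref_value
    normalized[match] = 1.0
    return ConcentrationSeries(concentrations=series.concentrations,
                               values=series.values,
                               reference_concentration=reference,
                               normalized=normalized)


def exponential_decline_fit(concentrations, normalized_values) -> tuple[float, float]:
    """Fit y = exp(−k·c) through the normalized decline; returns (k, R²).

    The curve is constrained through (0, 1) by construction.  R² is computed
    on the linear scale; a zero total sum of squares (constant data) reports
    R² = 0 with a warning.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(normalized_values, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 points for the exponential fit")
    if np.any(y <= 0):
        raise ValueError("normalized values must be positive")

    def model(cc, k):
        return np.exp(-k * cc)

    try:
        with warnings.catch_warnings():
            # constant data makes the parameter covariance inestimable;
            # that degenerate case is reported via the R² convention below
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(model, c, y, p0=[0.01], maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    k = float(popt[0])
    resid = y - model(c, k)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant data: R² reported as 0 by convention", stacklevel=2)
        return k, 0.0
    return k, 1.0 - ss_res / ss_tot


def block_statistics(values, n_blocks: int = 5) -> tuple[float, float]:
    """Mean of block means and their sample standard deviation.

    The series is split into ``n_blocks`` contiguous equal blocks; remainder
    values at the end are dropped.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < n_blocks:
        raise ValueError(f"series of length {len(v)} cannot form {n_blocks} blocks")
    block_len = len(v) // n_blocks
    trimmed = v[: block_len * n_blocks].reshape(n_blocks, block_len)
    means = trimmed.mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1))
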