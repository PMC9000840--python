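"""Two shear-viscosity estimators for solution boxes.

* **Periodic perturbation** (non-equilibrium): a cosine acceleration
  ``a_x(z) = A cos(2πz/l_z)`` drives a steady cosine velocity profile whose
  amplitude v gives ``η = ρ A (l_z/2π)² / v``.
* **Einstein–Helfand** (equilibrium): η from the long-time growth rate of
  the squared running integral of the six off-diagonal pressure-tensor
  components, ``η = V/(2 k_B T) · d/dt (1/6) Σ_ij ⟨[∫ P_ij]²⟩``,
  equivalent to the Green–Kubo integral of the stress autocorrelation.

Internal units: nm, ps, bar, K; viscosities are reported in mPa·s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import (
    K_B,
    M3_PER_NM3,
    MPAS_PER_PAS,
    PA_PER_BAR,
    S_PER_PS,
)
from .model import PressureTensorSeries, Trajectory, masses_of


@dataclass(frozen=True)
class PerturbationSpec:
    """Cosine-acceleration forcing: amplitude A (nm/ps²) and box height l_z (nm)."""

    box_height: float
    amplitude: float = 0.05  # default forcing amplitude used throughout

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.box_height <= 0:
            raise ValueError("amplitude and box height must be positive")


@dataclass
class VelocityProfile:
    """Binned x-velocity versus z with the fitted cosine amplitude (nm/ps)."""

    bin_centers: np.ndarray
    mean_velocity: np.ndarray
    counts: np.ndarray
    fitted_amplitude: float
    lsq_amplitude: float
    box_height: float


@dataclass
class ViscosityEstimate:
    """A shear viscosity in mPa·s with method tag and convergence trace."""

    eta: float
    uncertainty: float = 0.0
    method: str = "periodic_perturbation"
    convergence_series: tuple[np.ndarray, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# periodic perturbation method
# ---------------------------------------------------------------------------

def bin_velocity_profile(trajectory: Trajectory, n_bins: int = 20) -> VelocityProfile:
    """Mass-weighted x-velocity profile along z and its cosine amplitude.

    The amplitude is the discrete cosine projection
    ``v = (2/N) Σ_bins v̄_x(z_c) cos(2πz_c/l_z)`` over bin centers, which is
    orthogonal to any uniform drift; a least-squares fit of
    ``v·cos(2πz/l_z)`` is recorded as a cross-check (and used when empty
    bins break the uniform quadrature).
    """
    if n_bins < 4:
        raise ValueError("need at least 4 z-bins")
    if any(fr.velocities is None for fr in trajectory.frames):
        raise ValueError("trajectory has no velocities; the periodic-perturbation "
                         "method needs per-atom velocities")
    lz = trajectory.frames[0].box.lengths[2]
    edges = np.linspace(0.0, lz, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    masses = masses_of(trajectory.topology)
    mom = np.zeros(n_bins)   # mass-weighted velocity sum
    wsum = np.zeros(n_bins)  # mass sum
    counts = np.zeros(n_bins, dtype=int)
    for fr in trajectory.frames:
        z = np.mod(fr.positions[:, 2], lz)
        idx = np.minimum((z / lz * n_bins).astype(int), n_bins - 1)
        vx = fr.velocities[:, 0]
        mom += np.bincount(idx, weights=masses * vx, minlength=n_bins)
        wsum += np.bincount(idx, weights=masses, minlength=n_bins)
        counts += np.bincount(idx, minlength=n_bins)
    occupied = wsum > 0
    mean_v = np.zeros(n_bins)
    mean_v[occupied] = mom[occupied] / wsum[occupied]
    basis = np.cos(2.0 * np.pi * centers / lz)
    if occupied.all():
        amplitude_proj = 2.0 / n_bins * float(mean_v @ basis)
    else:
        warnings.warn(f"{int((~occupied).sum())} empty z-bin(s) excluded from the "
                      "profile fit", stacklevel=2)
        amplitude_proj = np.nan
    b = basis[occupied]
    lsq_amplitude = float((mean_v[occupied] @ b) / (b @ b))
    fitted = amplitude_proj if np.isfinite(amplitude_proj) else lsq_amplitude
    return VelocityProfile(bin_centers=centers, mean_velocity=mean_v,
                           counts=counts, fitted_amplitude=fitted,
                           lsq_amplitude=lsq_amplitude, box_height=lz)


def periodic_perturbation_viscosity(profile: VelocityProfile, density: float,
                                    spec: PerturbationSpec | None = None
                                    ) -> ViscosityEstimate:
    """η = ρ·A·(l_z/2π)²/v in mPa·s from a fitted velocity-profile amplitude.

    ``density`` in g/mL; the forcing amplitude defaults to 0.05 nm/ps².
    """
    if spec is None:
        spec = PerturbationSpec(box_height=profile.box_height)
    if density <= 0:
        raise ValueError("density must be positive")
    v = profile.fitted_amplitude
    if not np.isfinite(v) or v <= 0:
        raise ValueError(
            f"fitted velocity amplitude {v} is not positive: the profile is "
            "inconsistent with the cosine forcing")
    rho_si = density * 1000.0                     # g/mL -> kg/m^3
    a_si = spec.amplitude * 1e-9 / S_PER_PS ** 2  # nm/ps^2 -> m/s^2
    v_si = v * 1e-9 / S_PER_PS                    # nm/ps -> m/s
    lz_si = spec.box_height * 1e-9
    eta_pas = rho_si * a_si / v_si * (lz_si / (2.0 * np.pi)) ** 2
    return ViscosityEstimate(eta=eta_pas * MPAS_PER_PAS,
                             method="periodic_perturbation")


# ---------------------------------------------------------------------------
# Einstein–Helfand method
# ---------------------------------------------------------------------------

def einstein_helfand_viscosity(series: PressureTensorSeries,
                               fit_window: tuple[float, float] = (0.2, 0.8),
                               origin_stride: int = 10,
                               n_lags: int = 200,
                               max_lag_fraction: float = 0.005,
                               min_max_lag: int = 100) -> ViscosityEstimate:
    """Shear viscosity from the Helfand moment of the pressure tensor.

    The running integral ``W_ij(t) = ∫ P_ij dt'`` is accumulated by
    trapezoidal cumulative sum; the mean squared Helfand displacement
    ``G(t) = (1/6) Σ_ij ⟨[W_ij(t0+t) − W_ij(t0)]²⟩`` is averaged over
    non-overlapping time origins (``origin_stride`` samples apart), and
    η = V/(2 k_B T) × the least-squares slope of G over ``fit_window``
    (fractions of the maximum lag).  The convergence trace records the
    running η as the window end grows.

    The lag span is capped at ``max_lag_fraction`` of the series (with a
    floor of ``min_max_lag`` samples): G(t) is linear once t exceeds the
    stress correlation time, while its origin-averaging noise grows with
    the lag, so a short late-time window is both accurate and stable.
    """
    n = len(series)
    if n < 100:
        raise ValueError(f"need >= 100 pressure samples, got {n}")
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"invalid fit window {fit_window}")
    dt_s = series.dt * S_PER_PS
    P = series.stacked() * PA_PER_BAR  # (6, n) in Pa
    # trapezoidal running integral, W[0] = 0
    W = np.concatenate([np.zeros((6, 1)),
                        np.cumsum(0.5 * (P[:, 1:] + P[:, :-1]) * dt_s, axis=1)],
                       axis=1)
    max_lag = min(max(int(n * max_lag_fraction), min_max_lag), n - 1)
    lag_grid = np.unique(np.linspace(1, max_lag, min(n_lags, max_lag)).astype(int))
    origins = np.arange(0, n, max(int(origin_stride), 1))
    G = np.empty(len(lag_grid))
    for i, lag in enumerate(lag_grid):
        o = origins[origins + lag <= n - 1]
        disp = W[:, o + lag] - W[:, o]
        G[i] = (disp ** 2).mean(axis=1).sum() / 6.0
    tau = lag_grid * dt_s  # lag times in s
    prefactor = (series.box_volume * M3_PER_NM3) / (2.0 * K_B * series.temperature)

    def eta_over(end_idx: int) -> float:
        t_end = tau[end_idx]
        mask = (tau >= lo * t_end) & (tau <= t_end)
        if mask.sum() < 5:
            return np.nan
        res = stats.linregress(tau[mask], G[mask])
        return prefactor * res.slope * MPAS_PER_PAS

    mask_final = (tau >= lo * tau[-1]) & (tau <= hi * tau[-1])
    if mask_final.sum() < 5:
        raise ValueError("fit window contains fewer than 5 lag points")
    res = stats.linregress(tau[mask_final], G[mask_final])
    eta = prefactor * res.slope * MPAS_PER_PAS
    err = prefactor * res.stderr * MPAS_PER_PAS if np.isfinite(res.stderr) else 0.0
    running = np.array([eta_over(i) for i in range(len(lag_grid))])
    return ViscosityEstimate(eta=float(eta), uncertainty=float(err),
                             method="einstein_helfand",
                             convergence_series=(tau / S_PER_PS, running))


def green_kubo_viscosity(series: PressureTensorSeries,
                         max_lag: int | None = None) -> float:
    """Brute-force Green–Kubo viscosity V/(k_B T)·Σ_k ⟨P(0)P(kΔt)⟩Δt (mPa·s).

    Direct discrete sum of the stress autocorrelation over the six
    off-diagonal components; serves as the estimator-equivalence reference
    for the Helfand slope on identical samples.
    """
    n = len(series)
    if max_lag is None:
        max_lag = n // 2
    dt_s = series.dt * S_PER_PS
    P = series.stacked() * PA_PER_BAR
    acf = np.zeros(max_lag)
    for lag in range(max_lag):
        prod = P[:, : n - lag] * P[:, lag:]
        acf[lag] = prod.mean()
    integral = (acf.sum() - 0.5 * acf[0]) * dt_s  # trapezoid with ACF(0) half-weighted
    prefactor = (series.box_volume * M3_PER_NM3) / (K_B * series.temperature)
    return float(prefactor * integral * MPAS_PER_PAS)


def viscosity_convergence_report(estimate: ViscosityEstimate,
                                 tail_threshold: float = 0.10):
    """Running-η convergence table and a converged/non-converged flag.

    Returns ``(DataFrame, converged)``; the flag compares the running η at
    the final window end with the value one decade earlier and trips when
    the relative change exceeds ``tail_threshold``.
    """
    import pandas as pd

    if estimate.convergence_series is None:
        raise ValueError("estimate has no convergence series")
    t, running = estimate.convergence_series
    valid = np.isfinite(running)
    rel_change = np.full_like(running, np.nan)
    prev = running[valid]
    tv = t[valid]
    if len(prev) >= 2:
        rc = np.abs(np.diff(prev)) / np.maximum(np.abs(prev[:-1]), 1e-300)
        rel_change[np.nonzero(valid)[0][1:]] = rc
    df = pd.DataFrame({"window_end_ps": t, "eta_mPas": running,
                       "relative_change": rel_change})
    if len(tv) >= 2:
        eta_final = prev[-1]
        decade_idx = int(np.argmin(np.abs(tv - tv[-1] / 10.0)))
        eta_decade = prev[decade_idx]
        if eta_decade == 0 and eta_final == 0:
            converged = True
        elif eta_decade == 0:
            converged = False
        else:
            converged = abs(eta_final - eta_decade) / abs(eta_decade) <= tail_threshold
    else:
        converged = False
    return df, bool(converged)
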