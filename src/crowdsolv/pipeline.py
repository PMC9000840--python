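"""Orchestration: concentration sweeps, comparison arithmetic, and reports.

This module glues the estimator modules into the analysis workflows the
package exists for: sweeping an observable over a crowder-concentration
grid with normalization and the Enskog hard-sphere reference column, the
signed percent-deviation arithmetic used to compare simulated transport
coefficients against experimental references, and machine-readable run
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import composition, transport
from .model import Box, MoleculeClass, Trajectory

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# percent deviation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviationReport:
    """Signed percent deviation of a simulated value from a reference."""

    simulated: float
    reference: float
    signed_percent: float
    magnitude: int
    label: str

    def __str__(self) -> str:
        if self.label == "exact":
            return f"{self.simulated} matches the reference {self.reference} (0%)"
        return (f"{self.simulated} vs {self.reference}: {self.label} by "
                f"{self.magnitude}%")


def percent_deviation(simulated: float, reference: float) -> DeviationReport:
    """Signed deviation (simulated − reference)/reference·100 with an
    over/under label and the nearest-integer magnitude."""
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    signed = (simulated - reference) / reference * 100.0
    magnitude = int(round(abs(signed)))
    if signed > 0:
        label = "overestimation"
    elif signed < 0:
        label = "underestimation"
    else:
        label = "exact"
    return DeviationReport(simulated=simulated, reference=reference,
                           signed_percent=signed, magnitude=magnitude,
                           label=label)


# ---------------------------------------------------------------------------
# concentration sweep
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One concentration point of a sweep: an unwrapped trajectory plus the
    metadata needed to estimate and correct its diffusion constant."""

    concentration_wv: float
    trajectory: Trajectory
    selection: object = None            # molecule class / index groups / None
    temperature: float = 298.15
    viscosity: float | None = None      # mPa·s; enables finite-size correction
    fit_window: tuple[float, float] = (0.1, 0.5)
    n_blocks: int = 5
    seed: int | None = None


def diffusion_with_block_error(config: RunConfig) -> tuple[float, float]:
    """D_PBC (1e-5 cm²/s) and its five-block uncertainty for one config.

    The trajectory is split into ``n_blocks`` contiguous time segments; the
    block spread of per-segment estimates gives the uncertainty.
    """
    series = transport.msd(config.trajectory, config.selection)
    est = transport.diffusion_pbc(series, config.fit_window)
    n_frames = len(config.trajectory)
    block_len = n_frames // config.n_blocks
    block_values = []
    if block_len >= 10:
        for b in range(config.n_blocks):
            sub = Trajectory(config.trajectory.topology,
                             config.trajectory.frames[b * block_len:(b + 1) * block_len])
            sub_series = transport.msd(sub, config.selection)
            block_values.append(
                transport.diffusion_pbc(sub_series, config.fit_window).D_pbc)
        err = float(np.std(block_values, ddof=1))
    else:
        err = est.uncertainty
    return est.D_pbc, err


def concentration_sweep(configs: Sequence[RunConfig],
                        reference_concentration: float | None = None,
                        box: Box | None = None) -> pd.DataFrame:
    """Long-format sweep table over a concentration series.

    One row per (concentration, observable): the PBC diffusion constant
    with block error, optionally the finite-size-corrected value, the
    series normalized to the reference concentration (default: the lowest),
    and the Enskog hard-sphere reference at the composition's crowder
    volume fraction (computed when ``box`` is given).
    """
    if not configs:
        raise ValueError("concentration sweep needs at least one config")
    concentrations = np.array([c.concentration_wv for c in configs])
    if reference_concentration is None:
        reference_concentration = float(concentrations.min())
    rows = []
    d_values, d_errors, d0_values = [], [], []
    for cfg in configs:
        d, err = diffusion_with_block_error(cfg)
        d_values.append(d)
        d_errors.append(err)
        if cfg.viscosity is not None:
            L = cfg.trajectory.frames[0].box.lengths[0]
            d0 = transport.yeh_hummer_correction(d, cfg.temperature,
                                                 cfg.viscosity, L)
        else:
            d0 = d
        d0_values.append(d0)
    series = transport.ConcentrationSeries(concentrations=concentrations,
                                           values=np.array(d0_values))
    normalized = transport.normalize_series(series, reference_concentration)
    for i, cfg in enumerate(configs):
        c = cfg.concentration_wv
        rows.append((c, "D_pbc", d_values[i], d_errors[i]))
        rows.append((c, "D_0", d0_values[i], d_errors[i]))
        rows.append((c, "D_normalized", float(normalized.normalized[i]), np.nan))
        if box is not None:
            phi = composition.volume_fraction(
                composition.solvent_counts(c, box)[0], box)
            rows.append((c, "enskog_reference",
                         float(transport.enskog_ratio(phi)), np.nan))
    return pd.DataFrame(rows, columns=["concentration_wv", "observable",
                                       "value", "error"])


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV emission with fixed 6-significant-digit float formatting, so that
    re-running a sweep with the same seed is byte-identical."""
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def report(run_outputs: dict, path: str | Path | None = None) -> dict:
    """Machine-readable run report (versioned JSON) plus a text summary.

    ``run_outputs`` maps analysis names to JSON-serializable results;
    seeds, block errors, and convergence flags included by the callers are
    passed through untouched.
    """
    if not run_outputs:
        raise ValueError("report needs at least one completed analysis")
    doc = {"schema_version": SCHEMA_VERSION, "analyses": run_outputs}
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")
    return doc


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    raise TypeError(f"cannot serialize {type(obj)}")


def summarize(doc: dict) -> str:
    lines = [f"crowdsolv report (schema v{doc['schema_version']})"]
    for name, payload in doc["analyses"].items():
        lines.append(f"  {name}: {json.dumps(payload, default=_jsonify)[:200]}")
    return "\n".join(lines)
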