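"""End-to-end synthetic study workflows.

These functions wire the generators to the estimators the way the MD
study wires production trajectories to its analysis: a concentration
sweep generates Brownian solvent trajectories whose ground-truth diffusion
constants decline with crowder volume fraction following the Enskog
hard-sphere curve, then recovers, normalizes, and tabulates them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import composition, pipeline, synthetic, transport
from .model import Box


def synthetic_concentration_sweep(concentrations, seed: int = 0,
                                  n_particles: int = 200, n_steps: int = 400,
                                  dt: float = 1.0, box: Box | None = None,
                                  D_dilute: float = 2.30) -> pd.DataFrame:
    """Generate-and-analyze sweep over a crowder concentration grid.

    For each concentration the crowder volume fraction is computed from the
    box composition, the ground-truth diffusion constant is the dilute
    value ``D_dilute`` (1e-5 cm²/s) scaled by the Enskog hard-sphere
    decline, and a Brownian trajectory at that constant is generated and
    re-analyzed.  Output is the long-format sweep table with normalized
    and Enskog reference columns.
    """
    if box is None:
        box = Box.cubic(4.0)
    rng = np.random.default_rng(seed)
    configs = []
    for c in concentrations:
        n_peg, _ = composition.solvent_counts(c, box)
        phi = composition.volume_fraction(n_peg, box)
        d_true = D_dilute * transport.enskog_ratio(min(phi, 0.999))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        res = synthetic.brownian_trajectory(n_particles, n_steps, dt, box,
                                            D_target=d_true, seed=sub_seed)
        configs.append(pipeline.RunConfig(concentration_wv=float(c),
                                          trajectory=res.trajectory,
                                          seed=sub_seed))
    return pipeline.concentration_sweep(configs, box=box)


def diffusion_recovery_grid(d_targets=(0.1, 1.0, 5.0), seed: int = 0,
                            n_particles: int = 1000, n_steps: int = 2000,
                            dt: float = 1.0) -> pd.DataFrame:
    """Recover D_PBC from Brownian trajectories across a target grid.

    Returns a table of target, estimate, and relative error; the box is
    large enough that no finite-size correction applies to the generator
    (free Brownian motion has none).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in d_targets:
        res = synthetic.brownian_trajectory(n_particles, n_steps, dt,
                                            Box.cubic(10.0), D_target=d,
                                            seed=int(rng.integers(0, 2 ** 31 - 1)))
        series = transport.msd(res.trajectory)
        est = transport.diffusion_pbc(series)
        rows.append({"D_target": d, "D_pbc": est.D_pbc,
                     "relative_error": abs(est.D_pbc - d) / d})
    return pd.DataFrame(rows)
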