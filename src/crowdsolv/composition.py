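"""Solution composition for PEG-4/water crowding boxes.

Given a target crowder concentration in % w/v (grams of PEG-4 per 100 mL of
solution), construct molecule counts for a periodic box, convert between
concentration unit systems (% w/v, volume %, weight %), and compute the
crowder volume fraction φ that enters the Enskog hard-sphere reference.

Counts follow the flooring rule of the original composition table: the PEG
count is the floor of c·V·N_A/(100·M), and water fills the volume left by
the realized PEG molecules at its pure-liquid density.  At the pure-crowder
limit (c = 100·ρ_peg, 112 % w/v for PEG-4) the solution contains no water
by definition.

The integer unit columns are computed from the realized counts against the
ideal-mixing solution volume (sum of pure-component molar volumes), then
floored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ML_PER_NM3, N_A
from .model import Box

#: N_A expressed per nm^3·(g/mL) so that (g/mL)·(nm^3)·_NA_NM3 / (g/mol) = count
_NA_NM3 = N_A * ML_PER_NM3  # = 602.214076 molecules per (nm^3 * g/mL / (g/mol))


@dataclass(frozen=True)
class ComponentSpec:
    """A pure liquid component: molar mass (g/mol) and pure-liquid density (g/mL)."""

    name: str
    molar_mass: float
    pure_density: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be > 0")
        if self.pure_density <= 0:
            raise ValueError(f"{self.name}: pure density must be > 0")

    @property
    def molecular_volume(self) -> float:
        """Volume per molecule in the pure liquid, nm^3."""
        return self.molar_mass / (self.pure_density * _NA_NM3)


#: Tetraethylene glycol, C8H18O5.
PEG4 = ComponentSpec("PEG-4", molar_mass=194.23, pure_density=1.12)
#: Water at ambient conditions.
WATER = ComponentSpec("water", molar_mass=18.015, pure_density=1.00)


@dataclass(frozen=True)
class SolutionSpec:
    """A realized box composition with its derived concentration measures."""

    box: Box
    n_peg: int
    n_water: int
    concentration_wv: float
    volume_percent: float
    weight_percent: float
    volume_fraction: float

    def __post_init__(self) -> None:
        if self.n_peg < 0 or self.n_water < 0:
            raise ValueError("molecule counts must be non-negative")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")
        if not 0.0 <= self.weight_percent <= 100.0:
            raise ValueError("weight percent must lie in [0, 100]")


def solvent_counts(concentration_wv: float, box: Box,
                   peg: ComponentSpec = PEG4,
                   water: ComponentSpec = WATER) -> tuple[int, int]:
    """Molecule counts realizing a target crowder concentration in a box.

    ``concentration_wv`` is % w/v (g crowder / 100 mL solution); the upper
    limit 100·ρ_peg (112 for PEG-4) is the pure crowder liquid.
    """
    c_max = 100.0 * peg.pure_density
    if not 0.0 <= concentration_wv <= c_max:
        raise ValueError(
            f"concentration {concentration_wv} % w/v outside [0, {c_max}] "
            f"(pure-{peg.name} limit)")
    V = box.volume  # nm^3
    # c in g/mL is concentration_wv / 100
    n_peg = math.floor(concentration_wv / 100.0 * V * _NA_NM3 / peg.molar_mass)
    if concentration_wv >= c_max * (1.0 - 1e-12):
        n_water = 0
    else:
        v_water = V - n_peg * peg.molecular_volume  # nm^3 left for water
        n_water = math.floor(water.pure_density * max(v_water, 0.0)
                             * _NA_NM3 / water.molar_mass)
    return n_peg, max(n_water, 0)


def concentration_units(n_peg: int, n_water: int, box: Box,
                        peg: ComponentSpec = PEG4,
                        water: ComponentSpec = WATER,
                        floored: bool = True) -> tuple[float, float, float]:
    """(% w/v, volume %, weight %) of a realized composition.

    Volumes use ideal mixing (pure-component molar volumes); the solution
    volume is their sum.  With ``floored`` (default) the three values are
    floored to integers, matching the composition table convention; the
    exact floats are returned otherwise.
    """
    if n_peg == 0 and n_water == 0:
        raise ValueError("composition is empty: both counts are zero")
    if box.volume <= 0:
        raise ValueError("box volume must be positive")
    m_peg = n_peg * peg.molar_mass      # g/mol-scaled masses; ratios are unit-free
    m_water = n_water * water.molar_mass
    v_peg = n_peg * peg.molecular_volume      # nm^3
    v_water = n_water * water.molecular_volume
    v_solution = v_peg + v_water
    wv = 100.0 * n_peg * peg.molar_mass / (_NA_NM3 * v_solution)
    volume_percent = 100.0 * v_peg / v_solution
    weight_percent = 100.0 * m_peg / (m_peg + m_water)
    if floored:
        return (math.floor(wv), math.floor(volume_percent), math.floor(weight_percent))
    return (wv, volume_percent, weight_percent)


def volume_fraction(n_peg: int, box: Box, peg: ComponentSpec = PEG4) -> float:
    """Crowder volume fraction φ from the pure-component molar volume."""
    if n_peg < 0:
        raise ValueError("n_peg must be non-negative")
    phi = n_peg * peg.molecular_volume / box.volume
    return min(max(phi, 0.0), 1.0)


def solution_spec(concentration_wv: float, box: Box,
                  peg: ComponentSpec = PEG4,
                  water: ComponentSpec = WATER) -> SolutionSpec:
    """Full realized composition record for a target concentration."""
    n_peg, n_water = solvent_counts(concentration_wv, box, peg, water)
    if n_peg == 0 and n_water == 0:
        wv, v_pct, wt_pct = 0.0, 0.0, 0.0
    else:
        wv, v_pct, wt_pct = concentration_units(n_peg, n_water, box, peg, water,
                                                floored=False)
    return SolutionSpec(box=box, n_peg=n_peg, n_water=n_water,
                        concentration_wv=concentration_wv,
                        volume_percent=v_pct, weight_percent=wt_pct,
                        volume_fraction=volume_fraction(n_peg, box, peg))


def composition_table(concentrations, box: Box,
                      peg: ComponentSpec = PEG4,
                      water: ComponentSpec = WATER):
    """Composition table over a concentration grid as a pandas DataFrame.

    Columns: w_over_v, v_percent, wt_percent (floored integers), n_peg,
    n_water, volume_fraction.
    """
    import pandas as pd

    rows = []
    for c in concentrations:
        n_peg, n_water = solvent_counts(c, box, peg, water)
        if n_peg == 0 and n_water == 0:
            units = (0, 0, 0)
        else:
            units = concentration_units(n_peg, n_water, box, peg, water)
        rows.append({
            "w_over_v": int(round(c)) if float(c).is_integer() else c,
            "v_percent": units[1],
            "wt_percent": units[2],
            "n_peg": n_peg,
            "n_water": n_water,
            "volume_fraction": volume_fraction(n_peg, box, peg),
        })
    return pd.DataFrame(rows)
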