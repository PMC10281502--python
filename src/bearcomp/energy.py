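"""Storage-energy surfaces and the single-storage comparator.

The single-storage model assumes isomorphic structure (``K = c * L**3``)
and strong homeostasis of storage (fixed lipid/protein fractions), so its
energy is affine in mass above the structural boundary. The multi-storage
model lets storage composition vary with condition, which makes energy
convex in mass along a fixed-length column when the storage-muscle share
declines and the adipose lipid share rises with condition. Surfaces mask
the infeasible region (mass below structural mass) and can carry the
conventional bound curves: minimum mass = structural mass, maximum mass =
four times the single-storage structural mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .composition import (CompositionParams, EnergyDensities,
                          InvalidInputError, composition_arrays,
                          structural_mass, StructuralParams)


@dataclass(frozen=True)
class SingleStorageParams:
    """Comparator model parameters (externally supplied).

    ``structural_coefficient`` is kg per m**exponent; storage fractions
    are the fixed lipid/protein shares of storage mass.
    """

    structural_coefficient: float
    storage_lipid_fraction: float
    storage_protein_fraction: float
    structural_exponent: float = 3.0
    energy: EnergyDensities = field(default_factory=EnergyDensities)

    def __post_init__(self) -> None:
        if self.structural_coefficient <= 0:
            raise InvalidInputError("structural coefficient must be positive")
        for f in (self.storage_lipid_fraction, self.storage_protein_fraction):
            if not 0 <= f <= 1:
                raise InvalidInputError("storage fractions must be in [0,1]")
        if self.storage_lipid_fraction + self.storage_protein_fraction > 1:
            raise InvalidInputError("storage fractions must sum to <= 1")

    @property
    def storage_energy_density(self) -> float:
        return (self.energy.lipid * self.storage_lipid_fraction
                + self.energy.protein * self.storage_protein_fraction)


@dataclass
class EnergySurface:
    """Energy over a (length x mass) grid with feasibility mask.

    ``energy[i, j]`` corresponds to ``mass_grid[i]`` and
    ``length_grid[j]``; infeasible cells are NaN. ``min_mass_curve`` is
    the structural-mass boundary over the length grid; ``max_mass_curve``
    (optional) is four times the single-storage structural mass.
    """

    length_grid: np.ndarray
    mass_grid: np.ndarray
    energy: np.ndarray
    feasible: np.ndarray
    min_mass_curve: np.ndarray
    max_mass_curve: Optional[np.ndarray] = None
    model: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long format for external contour plotting."""
        LL, MM = np.meshgrid(self.length_grid, self.mass_grid)
        return pd.DataFrame({
            "length_m": LL.ravel(), "mass_kg": MM.ravel(),
            "energy_MJ": self.energy.ravel(),
            "feasible": self.feasible.ravel(),
        })


def single_storage_structural_mass(length, p: SingleStorageParams):
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise InvalidInputError("length must be positive")
    out = p.structural_coefficient * length ** p.structural_exponent
    return out if out.ndim else float(out)


def single_storage_energy(length, mass, p: SingleStorageParams):
    """Single-storage energy (MJ) and feasibility.

    ``E = (M - cL**3) * (f_L*eps_L + f_P*eps_P)`` above the structural
    boundary; returns ``(energy, feasible)`` with NaN where infeasible.
    """
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise InvalidInputError("mass must be positive")
    K = np.asarray(single_storage_structural_mass(length, p))
    feasible = mass >= K
    E = np.where(feasible, (mass - K) * p.storage_energy_density, np.nan)
    if E.ndim == 0:
        return float(E), bool(feasible)
    return E, feasible


def _check_grids(length_grid, mass_grid):
    length_grid = np.asarray(length_grid, dtype=float)
    mass_grid = np.asarray(mass_grid, dtype=float)
    for g, name in ((length_grid, "length"), (mass_grid, "mass")):
        if g.ndim != 1 or np.any(np.diff(g) <= 0):
            raise InvalidInputError(f"{name} grid must be 1-D strictly ascending")
        if np.any(g <= 0):
            raise InvalidInputError(f"{name} grid must be positive")
    return length_grid, mass_grid


def multi_storage_surface(length_grid, mass_grid, sex: str,
                          p: CompositionParams, muscle_level: str = "avg",
                          single: Optional[SingleStorageParams] = None
                          ) -> EnergySurface:
    """Multi-storage energy over the grid for one sex."""
    length_grid, mass_grid = _check_grids(length_grid, mass_grid)
    LL, MM = np.meshgrid(length_grid, mass_grid)
    r = composition_arrays(LL, MM, sex, p, muscle_level)
    max_curve = (4.0 * np.asarray(
        single_storage_structural_mass(length_grid, single))
        if single is not None else None)
    return EnergySurface(
        length_grid=length_grid, mass_grid=mass_grid,
        energy=r["E_O"], feasible=r["feasible"],
        min_mass_curve=np.asarray(structural_mass(length_grid, p.structural)),
        max_mass_curve=max_curve, model="multi_storage")


def single_storage_surface(length_grid, mass_grid, p: SingleStorageParams
                           ) -> EnergySurface:
    """Single-storage comparator energy over the grid."""
    length_grid, mass_grid = _check_grids(length_grid, mass_grid)
    LL, MM = np.meshgrid(length_grid, mass_grid)
    E, feasible = single_storage_energy(LL, MM, p)
    K = np.asarray(single_storage_structural_mass(length_grid, p))
    return EnergySurface(
        length_grid=length_grid, mass_grid=mass_grid, energy=E,
        feasible=feasible, min_mass_curve=K, max_mass_curve=4.0 * K,
        model="single_storage")


@dataclass
class DifferenceSurface:
    """Cell-wise (multi − single) energy difference.

    ``multi_only`` marks cells feasible under the multi-storage model but
    below the single-storage structural boundary — the region the
    comparator deems impossible.
    """

    length_grid: np.ndarray
    mass_grid: np.ndarray
    difference: np.ndarray
    both_feasible: np.ndarray
    multi_only: np.ndarray


def surface_difference(multi: EnergySurface, single: EnergySurface
                       ) -> DifferenceSurface:
    if (multi.length_grid.shape != single.length_grid.shape
            or multi.mass_grid.shape != single.mass_grid.shape
            or not np.allclose(multi.length_grid, single.length_grid)
            or not np.allclose(multi.mass_grid, single.mass_grid)):
        raise InvalidInputError("surfaces are on different grids")
    both = multi.feasible & single.feasible
    diff = np.where(both, multi.energy - single.energy, np.nan)
    return DifferenceSurface(
        length_grid=multi.length_grid, mass_grid=multi.mass_grid,
        difference=diff, both_feasible=both,
        multi_only=multi.feasible & ~single.feasible)


def shape_density(length, p: StructuralParams):
    """Structural mass over length cubed (kg/m^3).

    Constant under isomorphy (both allometric exponents exactly 3);
    decreasing in length when the exponents fall below 3.
    """
    length = np.asarray(length, dtype=float)
    out = np.asarray(structural_mass(length, p)) / length ** 3
    return out if out.ndim else float(out)
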