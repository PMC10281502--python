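"""Deterministic multi-storage body composition equations.

Partitions a polar bear's total body mass ``M`` into structural mass ``K``
(structural muscle ``K_U`` plus structure non-muscle ``K_nU``: bones, hide,
viscera) and storage mass ``O = M - K``, then splits storage into storage
muscle ``O_U`` and storage adipose ``A`` using a body-condition-dependent
allocation, and finally converts the lipid and protein content of both
storage compartments into total metabolizable storage energy ``E_O`` (MJ).

All lengths are straight-line body lengths in meters, masses in kg.
Functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .smi import SMIParams, scaled_mass_index

SEXES = ("F", "M")
AGE_CLASSES = ("coy", "yearling", "subadult", "adult")
MUSCLE_LEVELS = ("min", "avg", "max")

#: Metabolizable energy density of lipid, MJ/kg.
LIPID_ENERGY_DENSITY = 39.3
#: Metabolizable energy density of protein, MJ/kg.
PROTEIN_ENERGY_DENSITY = 18.4


class InvalidInputError(ValueError):
    """Raised when an input violates a model precondition."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidInputError(msg)


def classify_age_class(sex: str, age_years: float) -> str:
    """Age class from sex and age.

    Cubs-of-the-year are under 1 year, yearlings under 2; females are adult
    from 4 years, males from 6 (the ages at which ~97% of asymptotic body
    length is reached); everything between is subadult.
    """
    _require(sex in SEXES, f"unknown sex code {sex!r}")
    _require(age_years >= 0, "age_years must be non-negative")
    if age_years < 1:
        return "coy"
    if age_years < 2:
        return "yearling"
    if (sex == "F" and age_years >= 4) or (sex == "M" and age_years >= 6):
        return "adult"
    return "subadult"


@dataclass(frozen=True)
class Morphometrics:
    """One bear's field measurements."""

    id: str
    sex: str
    length: float  # straight-line body length, m
    mass: float  # total body mass, kg
    age_years: Optional[float] = None
    age_class: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.sex in SEXES, f"unknown sex code {self.sex!r}")
        _require(self.length > 0, "length must be positive")
        _require(self.mass > 0, "mass must be positive")
        if self.age_class is not None:
            _require(self.age_class in AGE_CLASSES,
                     f"unknown age class {self.age_class!r}")
        if self.age_years is not None:
            derived = classify_age_class(self.sex, self.age_years)
            if self.age_class is None:
                object.__setattr__(self, "age_class", derived)
            else:
                _require(self.age_class == derived,
                         f"age_class {self.age_class!r} inconsistent with "
                         f"age {self.age_years} ({derived!r})")


@dataclass(frozen=True)
class EnergyDensities:
    """Metabolizable energy content of storage molecules, MJ/kg."""

    lipid: float = LIPID_ENERGY_DENSITY
    protein: float = PROTEIN_ENERGY_DENSITY

    def __post_init__(self) -> None:
        _require(self.lipid > 0 and self.protein > 0,
                 "energy densities must be positive")


@dataclass(frozen=True)
class MuscleCompositionBounds:
    """Observed bounds on lipid/protein proportions of storage muscle.

    From chemical analyses of polar bear biceps femoris. The caller picks a
    level ("min" | "avg" | "max"); downstream predictions use the chosen
    level for both proportions.
    """

    lipid_min: float = 0.0030
    lipid_avg: float = 0.0218
    lipid_max: float = 0.0680
    protein_min: float = 0.2050
    protein_avg: float = 0.3738
    protein_max: float = 0.6200

    def __post_init__(self) -> None:
        _require(0 <= self.lipid_min <= self.lipid_avg <= self.lipid_max <= 1,
                 "lipid bounds must satisfy 0 <= min <= avg <= max <= 1")
        _require(
            0 <= self.protein_min <= self.protein_avg <= self.protein_max <= 1,
            "protein bounds must satisfy 0 <= min <= avg <= max <= 1")
        _require(self.lipid_max + self.protein_max <= 1,
                 "lipid_max + protein_max must not exceed 1")

    def lipid(self, level: str = "avg") -> float:
        _require(level in MUSCLE_LEVELS, f"unknown muscle level {level!r}")
        return {"min": self.lipid_min, "avg": self.lipid_avg,
                "max": self.lipid_max}[level]

    def protein(self, level: str = "avg") -> float:
        _require(level in MUSCLE_LEVELS, f"unknown muscle level {level!r}")
        return {"min": self.protein_min, "avg": self.protein_avg,
                "max": self.protein_max}[level]


@dataclass(frozen=True)
class StructuralParams:
    """Log-log allometries for structural muscle and structure non-muscle.

    ``K_U = exp(alpha_lU0 + beta_lU1 * ln L)`` and
    ``K_nU = exp(alpha_lKnU0 + beta_lKnU1 * ln L)``; ``beta_lU2`` is the
    adipose exponent of the total-muscle regression (used in fitting only —
    prediction of structural muscle sets the adipose term to zero).
    Coefficients are unit-dependent; ``length_unit`` records the unit the
    parameters were fitted in and is checked at load.
    """

    alpha_lU0: float
    beta_lU1: float
    beta_lU2: float
    sd_lU: float
    alpha_lKnU0: float
    beta_lKnU1: float
    sd_lKnU: float
    length_unit: str = "m"

    def __post_init__(self) -> None:
        _require(self.sd_lU > 0 and self.sd_lKnU > 0,
                 "residual sds must be positive")
        _require(self.length_unit == "m",
                 "structural coefficients are defined for lengths in meters")


@dataclass(frozen=True)
class StorageAllocationParams:
    """Beta regression (logit link) of storage-muscle proportion on SMI."""

    alpha_POu: float
    beta_POu: float
    phi1: float  # beta precision

    def __post_init__(self) -> None:
        _require(self.phi1 > 0, "phi1 must be positive")


@dataclass(frozen=True)
class AdiposeLipidParams:
    """Beta regression of adipose lipid proportion on SMI, sex intercepts."""

    alpha_F: float
    alpha_M: float
    beta: float
    phi2: float

    def __post_init__(self) -> None:
        _require(self.phi2 > 0, "phi2 must be positive")


@dataclass(frozen=True)
class AdiposeProteinParams:
    """Beta regression of adipose protein proportion on lipid proportion."""

    alpha: float
    beta: float
    phi3: float

    def __post_init__(self) -> None:
        _require(self.phi3 > 0, "phi3 must be positive")


@dataclass(frozen=True)
class CompositionParams:
    """Full fitted/constant parameter bundle for the multi-storage model."""

    structural: StructuralParams
    allocation: StorageAllocationParams
    adipose_lipid: AdiposeLipidParams
    adipose_protein: AdiposeProteinParams
    smi: SMIParams
    muscle: MuscleCompositionBounds = field(default_factory=MuscleCompositionBounds)
    energy: EnergyDensities = field(default_factory=EnergyDensities)

    def replace(self, **kwargs) -> "CompositionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BodyCompositionEstimate:
    """Derived compartment masses and storage energy for one bear.

    When ``feasible`` is False (total mass below predicted structural mass)
    the storage fields are NaN.
    """

    id: str
    sex: str
    length: float
    mass: float
    smi: float
    K_U: float
    K_nU: float
    K: float
    feasible: bool
    O: float = np.nan
    P_OU: float = np.nan
    O_U: float = np.nan
    A: float = np.nan
    P_AL: float = np.nan
    P_AP: float = np.nan
    O_L: float = np.nan
    O_P: float = np.nan
    E_O: float = np.nan


# ---------------------------------------------------------------------------
# Elemental operations, in pipeline order
# ---------------------------------------------------------------------------

def structural_muscle_mass(length, p: StructuralParams):
    """Structural muscle K_U (kg) from length via the fitted allometry."""
    length = np.asarray(length, dtype=float)
    _require(bool(np.all(length > 0)), "length must be positive")
    out = np.exp(p.alpha_lU0 + p.beta_lU1 * np.log(length))
    return out if out.ndim else float(out)


def structure_nonmuscle_mass(length, p: StructuralParams):
    """Structure non-muscle K_nU (kg): bones + hide + viscera allometry."""
    length = np.asarray(length, dtype=float)
    _require(bool(np.all(length > 0)), "length must be positive")
    out = np.exp(p.alpha_lKnU0 + p.beta_lKnU1 * np.log(length))
    return out if out.ndim else float(out)


def structural_mass(length, p: StructuralParams):
    """Total structural mass K = K_U + K_nU (kg)."""
    return structural_muscle_mass(length, p) + structure_nonmuscle_mass(length, p)


def storage_mass(mass, structural):
    """Storage mass O = M - K (kg) and feasibility.

    Returns ``(O, feasible)``. Mass equal to structural mass is the feasible
    boundary (O = 0); mass below it is flagged infeasible (data, not an
    error — the energy surfaces mask this region) and O is NaN there.
    """
    mass = np.asarray(mass, dtype=float)
    structural = np.asarray(structural, dtype=float)
    _require(bool(np.all(mass > 0)), "mass must be positive")
    _require(bool(np.all(structural > 0)), "structural mass must be positive")
    feasible = mass >= structural
    O = np.where(feasible, mass - structural, np.nan)
    if O.ndim == 0:
        return float(O), bool(feasible)
    return O, feasible


def proportion_storage_muscle(smi_value, p: StorageAllocationParams):
    """Proportion of storage that is muscle, inverse-logit linear in SMI."""
    smi_value = np.asarray(smi_value, dtype=float)
    out = expit(p.alpha_POu + p.beta_POu * smi_value)
    return out if out.ndim else float(out)


def partition_storage(O, P_OU):
    """Split storage O into (storage muscle O_U, storage adipose A)."""
    O = np.asarray(O, dtype=float)
    P_OU = np.asarray(P_OU, dtype=float)
    _require(bool(np.all(O >= 0)), "storage mass must be non-negative")
    _require(bool(np.all((P_OU >= 0) & (P_OU <= 1))),
             "P_OU must lie in [0, 1]")
    O_U = O * P_OU
    A = O - O_U  # complement: O_U + A reconstitutes O to within one ulp
    if O.ndim == 0 and P_OU.ndim == 0:
        return float(O_U), float(A)
    return O_U, A


def adipose_lipid_proportion(smi_value, sex, p: AdiposeLipidParams):
    """Lipid proportion of adipose from SMI, with sex-specific intercept."""
    if isinstance(sex, str):
        _require(sex in SEXES, f"unknown sex code {sex!r}")
        alpha = p.alpha_F if sex == "F" else p.alpha_M
    else:
        sex = np.asarray(sex)
        bad = set(np.unique(sex)) - set(SEXES)
        _require(not bad, f"unknown sex codes {sorted(bad)!r}")
        alpha = np.where(sex == "F", p.alpha_F, p.alpha_M)
    smi_value = np.asarray(smi_value, dtype=float)
    out = expit(alpha + p.beta * smi_value)
    return out if np.ndim(out) else float(out)


def adipose_protein_proportion(P_AL, p: AdiposeProteinParams):
    """Protein proportion of adipose from its lipid proportion."""
    P_AL = np.asarray(P_AL, dtype=float)
    _require(bool(np.all((P_AL >= 0) & (P_AL <= 1))),
             "P_AL must lie in [0, 1]")
    out = expit(p.alpha + p.beta * P_AL)
    return out if out.ndim else float(out)


def storage_lipid_mass(P_AL, A, P_UL, O_U):
    """Total storage lipid O_L = P_AL*A + P_UL*O_U (kg)."""
    A = np.asarray(A, dtype=float)
    O_U = np.asarray(O_U, dtype=float)
    _require(bool(np.all(A >= 0) and np.all(O_U >= 0)),
             "masses must be non-negative")
    for prop in (P_AL, P_UL):
        _require(bool(np.all((np.asarray(prop) >= 0)
                             & (np.asarray(prop) <= 1))),
                 "proportions must lie in [0, 1]")
    out = np.asarray(P_AL) * A + np.asarray(P_UL) * O_U
    return out if out.ndim else float(out)


def storage_protein_mass(P_AP, A, P_UP, O_U):
    """Total storage protein O_P = P_AP*A + P_UP*O_U (kg)."""
    return storage_lipid_mass(P_AP, A, P_UP, O_U)


def total_storage_energy(O_L, O_P, e: EnergyDensities = EnergyDensities()):
    """Storage energy E_O = eps_L*O_L + eps_P*O_P (MJ)."""
    O_L = np.asarray(O_L, dtype=float)
    O_P = np.asarray(O_P, dtype=float)
    _require(bool(np.all(O_L >= 0) and np.all(O_P >= 0)),
             "masses must be non-negative")
    out = e.lipid * O_L + e.protein * O_P
    return out if out.ndim else float(out)


def muscle_energy_density(P_UL, P_UP, e: EnergyDensities = EnergyDensities()):
    """Energy per kg of storage muscle at given lipid/protein proportions."""
    for prop in (P_UL, P_UP):
        _require(bool(np.all((np.asarray(prop) >= 0)
                             & (np.asarray(prop) <= 1))),
                 "proportions must lie in [0, 1]")
    out = e.lipid * np.asarray(P_UL, dtype=float) + e.protein * np.asarray(
        P_UP, dtype=float)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def composition_arrays(length, mass, sex, p: CompositionParams,
                       muscle_level: str = "avg") -> dict:
    """Vectorized composition chain; returns a dict of arrays.

    ``sex`` is a single code or an array matching the broadcast shape.
    Infeasible entries (mass below structural mass) carry NaN storage
    fields and ``feasible`` False.
    """
    length = np.asarray(length, dtype=float)
    mass = np.asarray(mass, dtype=float)
    smi = scaled_mass_index(mass, length, p.smi)
    K_U = structural_muscle_mass(length, p.structural)
    K_nU = structure_nonmuscle_mass(length, p.structural)
    K = np.asarray(K_U + K_nU)
    feasible = np.asarray(mass >= K)
    with np.errstate(invalid="ignore"):
        O = np.where(feasible, mass - K, np.nan)
        P_OU = proportion_storage_muscle(smi, p.allocation)
        O_U = O * P_OU
        A = O - O_U
        P_AL = adipose_lipid_proportion(smi, sex, p.adipose_lipid)
        P_AP = adipose_protein_proportion(P_AL, p.adipose_protein)
        P_UL = p.muscle.lipid(muscle_level)
        P_UP = p.muscle.protein(muscle_level)
        O_L = P_AL * A + P_UL * O_U
        O_P = P_AP * A + P_UP * O_U
        E_O = p.energy.lipid * O_L + p.energy.protein * O_P
    return {"smi": smi, "K_U": np.asarray(K_U), "K_nU": np.asarray(K_nU),
            "K": K, "feasible": feasible, "O": O, "P_OU": np.asarray(P_OU),
            "O_U": O_U, "A": A, "P_AL": np.asarray(P_AL),
            "P_AP": np.asarray(P_AP), "O_L": O_L, "O_P": O_P, "E_O": E_O}


def full_composition(m: Morphometrics, p: CompositionParams,
                     muscle_level: str = "avg") -> BodyCompositionEstimate:
    """Run the full chain for one bear.

    SMI -> K_U, K_nU -> K -> O -> P_OU -> (O_U, A) -> P_AL, P_AP ->
    (O_L, O_P) -> E_O. ``muscle_level`` selects the lipid/protein
    proportions used for storage muscle.
    """
    r = composition_arrays(m.length, m.mass, m.sex, p, muscle_level)
    scal = {k: (bool(v) if k == "feasible" else float(v))
            for k, v in r.items()}
    return BodyCompositionEstimate(
        id=m.id, sex=m.sex, length=m.length, mass=m.mass,
        smi=scal["smi"], K_U=scal["K_U"], K_nU=scal["K_nU"], K=scal["K"],
        feasible=scal["feasible"], O=scal["O"], P_OU=scal["P_OU"],
        O_U=scal["O_U"], A=scal["A"], P_AL=scal["P_AL"], P_AP=scal["P_AP"],
        O_L=scal["O_L"], O_P=scal["O_P"], E_O=scal["E_O"])
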