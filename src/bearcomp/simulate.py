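"""Synthetic dissection, biopsy, adipose-chemistry and recapture data.

The generators emulate the four field datasets the model is trained and
tested on, with known ground-truth parameters for recovery testing:

* dissection records (default n=31): per bear, a length and a target
  scaled mass index are drawn; structural muscle and structure non-muscle
  come from the log-log allometries with lognormal noise; the
  storage-muscle share is beta-distributed around the condition-dependent
  allocation curve; tissue masses close exactly (total mass equals the sum
  of parts), and the realized SMI equals its target by construction.
* adipose biopsies (default n=140): lipid proportion of adipose is
  beta-distributed around the sex-specific condition curve.
* adipose chemistry (default n=25): lipid proportion spans its observed
  range (0.45-0.75); protein proportion is beta-distributed around the
  decay curve in lipid; pairs with sum > 1 are rejected and redrawn.
* recaptures (default n=36): adult bears measured twice at the same true
  length; mass changes by a drawn daily rate over a drawn interval; true
  storage lipid at each timepoint comes from the full composition chain
  and the isotopic observation adds proportional noise (default 2.7%).

All outputs are pandas DataFrames with the CSV schemas the consuming
modules read. Generation is deterministic under ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .composition import (AdiposeLipidParams, AdiposeProteinParams,
                          CompositionParams, EnergyDensities,
                          MuscleCompositionBounds, StorageAllocationParams,
                          StructuralParams, composition_arrays)
from .smi import SMIParams


class GenerationError(RuntimeError):
    """Raised when a config cannot produce a feasible record."""


def default_truth() -> CompositionParams:
    """Default ground-truth parameter bundle.

    Chosen so derived quantities land in published descriptive ranges for
    polar bears: adipose lipid proportions within 0.45-0.75, the
    storage-muscle proportion declining with condition, structural length
    exponents slightly below three, and total masses of adult bears in the
    hundreds of kg. The allocation precision is small (phi1 = 2.5),
    reflecting the wide scatter of storage-muscle proportions derived from
    dissections.
    """
    return CompositionParams(
        structural=StructuralParams(
            alpha_lU0=2.08, beta_lU1=2.90, beta_lU2=0.30, sd_lU=0.06,
            alpha_lKnU0=2.52, beta_lKnU1=2.85, sd_lKnU=0.08),
        allocation=StorageAllocationParams(
            alpha_POu=1.5, beta_POu=-0.015, phi1=2.5),
        adipose_lipid=AdiposeLipidParams(
            alpha_F=-0.25, alpha_M=-0.45, beta=0.0055, phi2=40.0),
        adipose_protein=AdiposeProteinParams(
            alpha=-0.145, beta=-2.5, phi3=35.0),
        smi=SMIParams(b_sma=2.9, L0=1.8),
        muscle=MuscleCompositionBounds(),
        energy=EnergyDensities(),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition settings for the synthetic datasets."""

    truth: CompositionParams = field(default_factory=default_truth)
    seed: int = 0
    n_dissection: int = 31
    n_biopsy: int = 140
    n_chem: int = 25
    n_recapture: int = 36
    length_range: Tuple[float, float] = (0.9, 2.6)
    adult_length_range: Tuple[float, float] = (1.75, 2.35)
    smi_range: Tuple[float, float] = (130.0, 240.0)  # condition span, kg
    chem_lipid_range: Tuple[float, float] = (0.45, 0.75)
    interval_range: Tuple[float, float] = (8.0, 200.0)  # days
    daily_change_range: Tuple[float, float] = (0.2, 0.8)  # kg/day
    gain_fraction: float = 2.0 / 36.0  # share of recaptures gaining mass
    isotopic_error_fraction: float = 0.027
    length_jitter_sd: float = 0.0  # field measurement error, m
    knu_split: Tuple[float, float, float] = (0.35, 0.30, 0.35)  # hide/viscera/bones
    n_biopsy_outliers: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.smi_range,
                       self.chem_lipid_range, self.interval_range,
                       self.daily_change_range, self.adult_length_range):
            if not (0 < lo < hi):
                raise GenerationError("ranges must be positive and ordered")
        for n in (self.n_dissection, self.n_biopsy, self.n_chem,
                  self.n_recapture):
            if n < 1:
                raise GenerationError("dataset sizes must be >= 1")
        if abs(sum(self.knu_split) - 1.0) > 1e-12:
            raise GenerationError("knu_split fractions must sum to 1")


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _beta_open(rng, a, b):
    """Beta draw guaranteed strictly inside (0, 1)."""
    x = rng.beta(a, b)
    while np.any((x <= 0.0) | (x >= 1.0)):
        bad = (x <= 0.0) | (x >= 1.0)
        x = np.where(bad, rng.beta(a, b), x)
    return x


def _draw_sex(rng, n):
    return np.where(rng.random(n) < 0.5, "F", "M")


def _draw_age(rng, sex):
    # Ages spanning all classes; not used by the fitting stages.
    return np.round(rng.uniform(0.5, 20.0, size=len(sex)), 1)


def gen_dissection(cfg: GeneratorConfig) -> pd.DataFrame:
    """Dissection records with exact mass closure and SMI targeting.

    Structural muscle is the deterministic allometry prediction, so the
    latent storage-muscle proportion recovered by the combined fit at the
    truth parameters equals the beta-distributed proportion drawn here and
    lies strictly inside (0, 1) — the generated data are always valid
    inputs for the fitting stage. All muscle-mass scatter therefore comes
    from the storage-allocation beta law; structure non-muscle keeps its
    lognormal regression noise. Storage mass is set so the realized SMI
    equals its target: O = M_target - K_U - K_nU, where M_target is the
    mass implied by the target SMI at the drawn length. Targets implying
    non-positive storage are redrawn (up to a retry cap).
    """
    t = cfg.truth
    s, a = t.structural, t.allocation
    rng = _rng(cfg, 1)
    rows = []
    for i in range(cfg.n_dissection):
        for attempt in range(cfg.max_retries):
            L = rng.uniform(*cfg.length_range)
            smi_target = rng.uniform(*cfg.smi_range)
            K_U = np.exp(s.alpha_lU0 + s.beta_lU1 * np.log(L))
            K_nU = np.exp(s.alpha_lKnU0 + s.beta_lKnU1 * np.log(L)
                          + s.sd_lKnU * rng.standard_normal())
            M = smi_target * (L / t.smi.L0) ** t.smi.b_sma
            O = M - K_U - K_nU
            if O > 0.05:
                break
        else:
            raise GenerationError(
                f"could not draw feasible storage for record {i}: "
                f"condition range too low for the structural allometry")
        mu = expit(a.alpha_POu + a.beta_POu * smi_target)
        p = float(_beta_open(rng, mu * a.phi1, (1 - mu) * a.phi1))
        O_U = O * p
        A = O - O_U
        U = K_U + O_U
        hide, viscera, bones = (f * K_nU for f in cfg.knu_split)
        sex = str(_draw_sex(rng, 1)[0])
        rows.append({
            "id": f"D{i:03d}", "sex": sex,
            "age_years": float(_draw_age(rng, [sex])[0]),
            "length_m": L, "mass_kg": U + A + hide + viscera + bones,
            "muscle_kg": U, "adipose_kg": A, "hide_kg": hide,
            "viscera_kg": viscera, "bones_kg": bones,
        })
    return pd.DataFrame(rows)


def gen_biopsy(cfg: GeneratorConfig) -> pd.DataFrame:
    """Adipose biopsy records: sex, morphometrics and lipid proportion."""
    t = cfg.truth
    al = t.adipose_lipid
    rng = _rng(cfg, 2)
    n = cfg.n_biopsy
    L = rng.uniform(*cfg.length_range, size=n)
    smi = rng.uniform(*cfg.smi_range, size=n)
    M = smi * (L / t.smi.L0) ** t.smi.b_sma
    sex = _draw_sex(rng, n)
    alpha = np.where(sex == "F", al.alpha_F, al.alpha_M)
    mu = expit(alpha + al.beta * smi)
    P_AL = _beta_open(rng, mu * al.phi2, (1 - mu) * al.phi2)
    out = np.zeros(n, dtype=bool)
    df = pd.DataFrame({
        "id": [f"B{i:03d}" for i in range(n)], "sex": sex,
        "age_years": _draw_age(rng, sex), "length_m": L, "mass_kg": M,
        "lipid_proportion": P_AL, "outlier": out,
    })
    if cfg.n_biopsy_outliers:
        # Extreme-condition young males with anomalously low lipid content,
        # mirroring records an analyst would flag and exclude.
        k = cfg.n_biopsy_outliers
        Lo = rng.uniform(0.9, 1.2, size=k)
        Mo = rng.uniform(0.6, 0.9, size=k) * (
            np.exp(t.structural.alpha_lU0 + t.structural.beta_lU1 * np.log(Lo))
            + np.exp(t.structural.alpha_lKnU0
                     + t.structural.beta_lKnU1 * np.log(Lo))) * 2.0
        extra = pd.DataFrame({
            "id": [f"BX{i:03d}" for i in range(k)],
            "sex": ["M"] * k, "age_years": [0.8] * k,
            "length_m": Lo, "mass_kg": Mo,
            "lipid_proportion": _beta_open(rng, 0.3 * 20, 0.7 * 20),
            "outlier": [True] * k,
        })
        df = pd.concat([df, extra], ignore_index=True)
    return df


def gen_adipose_chem(cfg: GeneratorConfig) -> pd.DataFrame:
    """Adipose chemistry pairs (lipid, protein proportions), sum <= 1."""
    t = cfg.truth
    ap = t.adipose_protein
    rng = _rng(cfg, 3)
    n = cfg.n_chem
    P_AL = rng.uniform(*cfg.chem_lipid_range, size=n)
    mu = expit(ap.alpha + ap.beta * P_AL)
    P_AP = _beta_open(rng, mu * ap.phi3, (1 - mu) * ap.phi3)
    for _ in range(cfg.max_retries):
        bad = P_AL + P_AP > 1.0
        if not bad.any():
            break
        P_AP = np.where(bad, _beta_open(rng, mu * ap.phi3, (1 - mu) * ap.phi3),
                        P_AP)
    else:
        raise GenerationError("could not satisfy lipid+protein <= 1")
    return pd.DataFrame({
        "id": [f"C{i:03d}" for i in range(n)],
        "lipid_proportion": P_AL, "protein_proportion": P_AP,
    })


def _structural_mass_point(L: float, t: CompositionParams) -> float:
    s = t.structural
    return (np.exp(s.alpha_lU0 + s.beta_lU1 * np.log(L))
            + np.exp(s.alpha_lKnU0 + s.beta_lKnU1 * np.log(L)))


def gen_recapture(cfg: GeneratorConfig,
                  muscle_level: str = "avg") -> pd.DataFrame:
    """Paired-capture records with isotopic storage-lipid observations.

    True lipid at each timepoint is computed through the full composition
    chain at the truth parameters; the isotopic observation multiplies the
    truth by ``1 + Normal(0, isotopic_error_fraction)``. Most bears lose
    mass; a configurable fraction gains, mirroring the study.
    """
    t = cfg.truth
    rng = _rng(cfg, 4)
    n = cfg.n_recapture
    n_sb = max(1, round(n / 9)) if n >= 9 else 0
    rows = []
    for i in range(n):
        # Southern Beaufort records are adult females, as in the study;
        # Western Hudson Bay mixes adult males and females.
        sex = "F" if i < n_sb or (i % 3 != 0) else "M"
        for _ in range(cfg.max_retries):
            L = rng.uniform(*cfg.adult_length_range)
            K = _structural_mass_point(L, t)
            smi1 = rng.uniform(*cfg.smi_range)
            M1 = smi1 * (L / t.smi.L0) ** t.smi.b_sma
            interval = float(np.round(rng.uniform(*cfg.interval_range)))
            daily = rng.uniform(*cfg.daily_change_range)
            gain = rng.random() < cfg.gain_fraction
            M2 = M1 + (daily if gain else -daily) * interval
            if M1 > K + 1.0 and M2 > K + 1.0:
                break
        else:
            raise GenerationError(
                "could not draw a feasible recapture mass trajectory")
        lip = [float(composition_arrays(L, M, sex, t, muscle_level)["O_L"])
               for M in (M1, M2)]
        err = cfg.isotopic_error_fraction
        obs = [v * (1.0 + err * rng.standard_normal()) for v in lip]
        jit = cfg.length_jitter_sd
        l1 = L + (jit * rng.standard_normal() if jit else 0.0)
        l2 = L + (jit * rng.standard_normal() if jit else 0.0)
        rows.append({
            "id": f"R{i:03d}",
            "subpop": "SB" if i < n_sb else "WH",
            "sex": sex, "class": "adult",
            "interval_days": interval,
            "len1_m": l1, "mass1_kg": M1, "lipid1_kg": obs[0],
            "len2_m": l2, "mass2_kg": M2, "lipid2_kg": obs[1],
        })
    return pd.DataFrame(rows)


def manifest(cfg: GeneratorConfig) -> dict:
    """JSON-serializable record of the generator configuration and truth."""
    d = asdict(cfg)
    d["truth"] = {
        "structural": asdict(cfg.truth.structural),
        "allocation": asdict(cfg.truth.allocation),
        "adipose_lipid": asdict(cfg.truth.adipose_lipid),
        "adipose_protein": asdict(cfg.truth.adipose_protein),
        "smi": asdict(cfg.truth.smi),
        "muscle": asdict(cfg.truth.muscle),
        "energy": asdict(cfg.truth.energy),
    }
    return d
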