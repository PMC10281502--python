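"""Bayesian fitting processes for the multi-storage model.

Four fits parameterize the model:

* the combined fit — a log-log regression of total muscle mass on length
  and adipose mass, jointly with a beta regression (logit link,
  mean-precision parameterization) of the latent storage-muscle proportion
  on the scaled mass index; within each draw the latent structural muscle
  ``K_U = exp(alpha_lU0 + beta_lU1 ln L)`` converts observed total muscle
  into a storage-muscle proportion, so the allocation curve and the
  muscle allometry are estimated in one posterior;
* the structure non-muscle regression (log-log on length);
* the adipose-lipid beta regression on SMI with sex-specific intercepts;
* the adipose-protein beta regression on the adipose lipid proportion.

Two prior sets are provided: "unrestricted" (improper flat priors; scale
parameters flat on (0, inf)) and "weakly_informative" (Normal(0,2) on
coefficients; Uniform(0,1) on the log-scale residual sds; Normal(0,2),
effectively half-normal, on the allocation precision; Uniform(0,100) on
the adipose precisions). Positive parameters are sampled on the log scale
with the Jacobian correction, priors evaluated on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .composition import InvalidInputError
from .mcmc import PosteriorFit, SamplerConfig, make_fit, run_mcmc
from .smi import SMIParams, scaled_mass_index

PRIOR_SET_NAMES = ("unrestricted", "weakly_informative")


class IdentifiabilityError(ValueError):
    """Raised when the data cannot identify the model (e.g. n < 3)."""


@dataclass(frozen=True)
class PriorSet:
    """Named per-parameter prior specifications.

    Each entry is one of ``("flat",)`` (improper, density 1 on the whole
    support), ``("normal", mu, sd)`` or ``("uniform", lo, hi)``, evaluated
    on the natural scale; the positivity constraint of scale parameters is
    enforced by the log-scale parameterization.
    """

    name: str
    entries: dict

    def for_params(self, names) -> "PriorSet":
        missing = [n for n in names if n not in self.entries]
        if missing:
            raise KeyError(f"prior set {self.name!r} missing entries for {missing}")
        return PriorSet(self.name, {n: self.entries[n] for n in names})


_COEFF = ("alpha_lU0", "beta_lU1", "beta_lU2", "alpha_lKnU0", "beta_lKnU1",
          "alpha_POu", "beta_POu", "alpha_F", "alpha_M", "beta_PAL",
          "alpha_PAP", "beta_PAP",
          "alpha_POu_F", "alpha_POu_M", "beta_POu_F", "beta_POu_M")
_SDS = ("sd_lU", "sd_lKnU")


def prior_sets() -> dict:
    """The two prior sets used throughout."""
    unrestricted = {n: ("flat",) for n in _COEFF}
    unrestricted.update({n: ("flat",) for n in _SDS})
    unrestricted.update({"phi1": ("flat",), "phi2": ("flat",),
                         "phi3": ("flat",)})
    weakly = {n: ("normal", 0.0, 2.0) for n in _COEFF}
    weakly.update({n: ("uniform", 0.0, 1.0) for n in _SDS})
    weakly.update({"phi1": ("normal", 0.0, 2.0),
                   "phi2": ("uniform", 0.0, 100.0),
                   "phi3": ("uniform", 0.0, 100.0)})
    return {"unrestricted": PriorSet("unrestricted", unrestricted),
            "weakly_informative": PriorSet("weakly_informative", weakly)}


def get_prior_set(name: str) -> PriorSet:
    if name not in PRIOR_SET_NAMES:
        raise InvalidInputError(f"unknown prior set {name!r}")
    return prior_sets()[name]


# ---------------------------------------------------------------------------
# Log densities (vectorized over chains)
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def normal_logpdf(x, mu, sd):
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def beta_logpdf_mean_precision(x, mu, phi):
    """log Beta(x; a=mu*phi, b=(1-mu)*phi)."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (gammaln(a + b) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x))


def _log_prior(values: dict, priors: PriorSet) -> np.ndarray:
    """Sum of per-parameter prior log densities; values are (chains,)."""
    total = 0.0
    for name, v in values.items():
        spec = priors.entries[name]
        if spec[0] == "flat":
            continue
        if spec[0] == "normal":
            total = total + normal_logpdf(v, spec[1], spec[2])
        elif spec[0] == "uniform":
            lo, hi = spec[1], spec[2]
            total = total + np.where((v >= lo) & (v <= hi),
                                     -np.log(hi - lo), -np.inf)
        else:  # pragma: no cover - construction guards this
            raise ValueError(f"unknown prior family {spec[0]!r}")
    return np.asarray(total) + np.zeros(len(next(iter(values.values()))))


def _finite_or_neginf(lp: np.ndarray) -> np.ndarray:
    return np.where(np.isfinite(lp) | np.isneginf(lp), lp, np.nan)


# ---------------------------------------------------------------------------
# Shared fit plumbing
# ---------------------------------------------------------------------------

def _check_n(n: int, minimum: int = 3) -> None:
    if n < minimum:
        raise IdentifiabilityError(
            f"at least {minimum} records required, got {n}")


def _check_variance(x: np.ndarray, what: str) -> None:
    if np.std(x) == 0:
        raise IdentifiabilityError(f"no variance in {what}")


def _jittered(center: np.ndarray, cfg: SamplerConfig, scale: float = 0.05):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    return center[None, :] + scale * rng.standard_normal(
        (cfg.chains, center.size))


def _run(model_name, names, positive, log_post_natural, init_natural, cfg,
         flags=None, transform=None, blocks=None):
    """Sample a model whose positive params are handled on the log scale.

    ``log_post_natural`` and ``init_natural`` work in the sampling
    parameterization (predictors centered for mixing); ``transform`` maps
    sampled natural draws back to the reported parameterization (a linear
    shear, so no Jacobian contribution).
    """
    positive = np.asarray(positive, dtype=bool)

    def to_natural(theta):
        nat = theta.copy()
        nat[:, positive] = np.exp(theta[:, positive])
        return nat

    def log_post(theta):
        nat = to_natural(theta)
        lp = log_post_natural(nat)
        # Jacobian of the log transform for positive parameters.
        lp = lp + theta[:, positive].sum(axis=1)
        return _finite_or_neginf(lp)

    center = init_natural.copy()
    center[positive] = np.log(center[positive])
    x0 = _jittered(center, cfg)
    # Shrink jitter until all chains start inside the support.
    for _ in range(30):
        if np.all(np.isfinite(log_post(x0))):
            break
        x0 = center[None, :] + 0.5 * (x0 - center[None, :])
    else:
        raise IdentifiabilityError(
            f"could not find a valid starting point for {model_name}")
    draws, info = run_mcmc(log_post, x0, cfg, blocks=blocks)
    nat = draws.copy()
    nat[:, :, positive] = np.exp(draws[:, :, positive])
    if transform is not None:
        nat = transform(nat)
    return make_fit(model_name, names, nat, info, flags)


# ---------------------------------------------------------------------------
# Data validation
# ---------------------------------------------------------------------------

def validate_dissection(df: pd.DataFrame, mass_tolerance: float = 0.01
                        ) -> pd.DataFrame:
    """Check dissection records: positive tissue masses, mass closure."""
    needed = ["length_m", "mass_kg", "muscle_kg", "adipose_kg", "hide_kg",
              "viscera_kg", "bones_kg"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidInputError(f"dissection data missing columns {missing}")
    if (df[needed] <= 0).any().any():
        raise InvalidInputError("dissection masses/lengths must be positive")
    parts = df[["muscle_kg", "adipose_kg", "hide_kg", "viscera_kg",
                "bones_kg"]].sum(axis=1)
    rel = (parts - df["mass_kg"]).abs() / df["mass_kg"]
    if (rel > mass_tolerance).any():
        bad = df.index[rel > mass_tolerance].tolist()
        raise InvalidInputError(
            f"tissue masses do not sum to total mass within "
            f"{mass_tolerance:.0%} for rows {bad}")
    return df


def validate_proportions(x: np.ndarray, what: str) -> None:
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise InvalidInputError(
            f"{what} must lie strictly inside (0, 1): the beta likelihood "
            "has open support")


# ---------------------------------------------------------------------------
# Fitting processes
# ---------------------------------------------------------------------------

def _combined_data(df, smi_params):
    validate_dissection(df)
    _check_n(len(df))
    L = df["length_m"].to_numpy(float)
    A = df["adipose_kg"].to_numpy(float)
    U = df["muscle_kg"].to_numpy(float)
    M = df["mass_kg"].to_numpy(float)
    _check_variance(np.log(L), "ln(length)")
    _check_variance(np.log(A), "ln(adipose)")
    smi = scaled_mass_index(M, L, smi_params)
    return np.log(L), np.log(A), A, U, np.log(U), smi


def _combined_init(lnL, lnA, lnU, U, smi):
    X = np.column_stack([np.ones_like(lnL), lnL, lnA])
    coef, *_ = np.linalg.lstsq(X, lnU, rcond=None)
    resid = lnU - X @ coef
    sd = float(np.clip(np.std(resid), 0.02, 0.9))
    a0, b1, b2 = coef
    # Structural muscle must sit below every observed total muscle mass.
    while np.any(U - np.exp(a0 + b1 * lnL) <= 0):
        a0 -= 0.05
    p = (U - np.exp(a0 + b1 * lnL))
    p = p / (np.exp(lnA) + p)
    lo = logit(np.clip(p, 1e-3, 1 - 1e-3))
    Z = np.column_stack([np.ones_like(smi), smi])
    aP, bP = np.linalg.lstsq(Z, lo, rcond=None)[0]
    mu = expit(aP + bP * smi)
    v = max(np.var(p - mu), 1e-4)
    phi = float(np.clip(np.mean(mu * (1 - mu)) / v - 1, 0.5, 50.0))
    return a0, b1, b2, sd, aP, bP, phi


def fit_combined(df: pd.DataFrame, smi: SMIParams, priors: PriorSet,
                 cfg: SamplerConfig) -> PosteriorFit:
    """Joint fit of the total-muscle regression and the allocation curve.

    Draws where any latent storage muscle ``U_i - K_U_i`` is non-positive
    are outside the support (log density −inf); the sampler rejects such
    proposals and reports their count.
    """
    lnL, lnA, A, U, lnU, smi_v = _combined_data(df, smi)
    names = ["alpha_lU0", "beta_lU1", "beta_lU2", "sd_lU",
             "alpha_POu", "beta_POu", "phi1"]
    positive = [False, False, False, True, False, False, True]
    pri = priors.for_params(names)
    mL, mA, mS = lnL.mean(), lnA.mean(), smi_v.mean()
    lnLc, lnAc, smic = lnL - mL, lnA - mA, smi_v - mS

    def log_post(nat):
        # Intercepts are sampled at the predictor means for mixing.
        a0c, b1, b2, sd, aPc, bP, phi = (nat[:, i] for i in range(7))
        mu_reg = a0c[:, None] + b1[:, None] * lnLc + b2[:, None] * lnAc
        ll = normal_logpdf(lnU, mu_reg, sd[:, None]).sum(axis=1)
        K_U = np.exp(a0c[:, None] + b1[:, None] * lnLc - b2[:, None] * mA)
        O_U = U - K_U
        ok = np.all(O_U > 0, axis=1)
        P_OU = np.where(O_U > 0, O_U / (A + O_U), 0.5)
        mu = expit(aPc[:, None] + bP[:, None] * smic)
        ll2 = beta_logpdf_mean_precision(P_OU, mu, phi[:, None]).sum(axis=1)
        lp = ll + np.where(ok, ll2, -np.inf)
        vals = {"alpha_lU0": a0c - b1 * mL - b2 * mA, "beta_lU1": b1,
                "beta_lU2": b2, "sd_lU": sd,
                "alpha_POu": aPc - bP * mS, "beta_POu": bP, "phi1": phi}
        return lp + _log_prior(vals, pri)

    def transform(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 1] * mL - nat[..., 2] * mA
        out[..., 4] = nat[..., 4] - nat[..., 5] * mS
        return out

    a0, b1, b2, sd, aP, bP, phi = _combined_init(lnL, lnA, lnU, U, smi_v)
    init = np.array([a0 + b1 * mL + b2 * mA, b1, b2, sd,
                     aP + bP * mS, bP, phi])
    return _run("combined", names, positive, log_post, init, cfg,
                transform=transform, blocks=[[0, 1, 2, 3], [4, 5, 6]])


def fit_combined_sex_varying(df: pd.DataFrame, smi: SMIParams,
                             priors: PriorSet, cfg: SamplerConfig
                             ) -> PosteriorFit:
    """Combined fit with sex-specific allocation intercept and slope.

    Reported diagnostics make any degradation relative to the pooled model
    visible (the dissection sample is small for a sex split).
    """
    if not {"F", "M"} <= set(df["sex"]):
        raise IdentifiabilityError("both sexes required for the sex-varying fit")
    lnL, lnA, A, U, lnU, smi_v = _combined_data(df, smi)
    is_f = (df["sex"] == "F").to_numpy()
    names = ["alpha_lU0", "beta_lU1", "beta_lU2", "sd_lU",
             "alpha_POu_F", "alpha_POu_M", "beta_POu_F", "beta_POu_M",
             "phi1"]
    positive = [False, False, False, True,
                False, False, False, False, True]
    pri = priors.for_params(names)

    mL, mA, mS = lnL.mean(), lnA.mean(), smi_v.mean()
    lnLc, lnAc, smic = lnL - mL, lnA - mA, smi_v - mS

    def log_post(nat):
        a0c, b1, b2, sd, aFc, aMc, bF, bM, phi = (nat[:, i] for i in range(9))
        mu_reg = a0c[:, None] + b1[:, None] * lnLc + b2[:, None] * lnAc
        ll = normal_logpdf(lnU, mu_reg, sd[:, None]).sum(axis=1)
        K_U = np.exp(a0c[:, None] + b1[:, None] * lnLc - b2[:, None] * mA)
        O_U = U - K_U
        ok = np.all(O_U > 0, axis=1)
        P_OU = np.where(O_U > 0, O_U / (A + O_U), 0.5)
        aP = np.where(is_f, aFc[:, None], aMc[:, None])
        bP = np.where(is_f, bF[:, None], bM[:, None])
        mu = expit(aP + bP * smic)
        ll2 = beta_logpdf_mean_precision(P_OU, mu, phi[:, None]).sum(axis=1)
        lp = ll + np.where(ok, ll2, -np.inf)
        vals = {"alpha_lU0": a0c - b1 * mL - b2 * mA, "beta_lU1": b1,
                "beta_lU2": b2, "sd_lU": sd,
                "alpha_POu_F": aFc - bF * mS, "alpha_POu_M": aMc - bM * mS,
                "beta_POu_F": bF, "beta_POu_M": bM, "phi1": phi}
        return lp + _log_prior(vals, pri)

    def transform(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 1] * mL - nat[..., 2] * mA
        out[..., 4] = nat[..., 4] - nat[..., 6] * mS
        out[..., 5] = nat[..., 5] - nat[..., 7] * mS
        return out

    a0, b1, b2, sd, aP, bP, phi = _combined_init(lnL, lnA, lnU, U, smi_v)
    aPc = aP + bP * mS
    init = np.array([a0 + b1 * mL + b2 * mA, b1, b2, sd, aPc, aPc, bP, bP,
                     phi])
    return _run("combined_sex_varying", names, positive, log_post, init, cfg,
                transform=transform, blocks=[[0, 1, 2, 3], [4, 5, 6, 7, 8]])


def fit_structure_nonmuscle(df: pd.DataFrame, priors: PriorSet,
                            cfg: SamplerConfig) -> PosteriorFit:
    """Log-log regression of structure non-muscle (hide+viscera+bones)."""
    validate_dissection(df)
    _check_n(len(df))
    L = df["length_m"].to_numpy(float)
    KnU = (df["hide_kg"] + df["viscera_kg"] + df["bones_kg"]).to_numpy(float)
    lnL, lnK = np.log(L), np.log(KnU)
    _check_variance(lnL, "ln(length)")
    names = ["alpha_lKnU0", "beta_lKnU1", "sd_lKnU"]
    positive = [False, False, True]
    pri = priors.for_params(names)

    mL = lnL.mean()
    lnLc = lnL - mL

    def log_post(nat):
        ac, b, sd = nat[:, 0], nat[:, 1], nat[:, 2]
        mu = ac[:, None] + b[:, None] * lnLc
        ll = normal_logpdf(lnK, mu, sd[:, None]).sum(axis=1)
        vals = {"alpha_lKnU0": ac - b * mL, "beta_lKnU1": b, "sd_lKnU": sd}
        return ll + _log_prior(vals, pri)

    def transform(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 1] * mL
        return out

    X = np.column_stack([np.ones_like(lnL), lnL])
    coef, *_ = np.linalg.lstsq(X, lnK, rcond=None)
    sd0 = float(np.clip(np.std(lnK - X @ coef), 0.02, 0.9))
    init = np.array([coef[0] + coef[1] * mL, coef[1], sd0])
    return _run("structure_nonmuscle", names, positive, log_post, init, cfg,
                transform=transform)


def fit_adipose_lipid(df: pd.DataFrame, smi: SMIParams, priors: PriorSet,
                      cfg: SamplerConfig) -> PosteriorFit:
    """Beta regression of adipose lipid proportion on SMI, by sex.

    With a single-sex input the missing intercept is estimated under the
    weakly informative Normal(0, 2) prior only (there is no likelihood
    contribution) and the fit carries a ``missing_sex`` flag.
    """
    _check_n(len(df))
    P = df["lipid_proportion"].to_numpy(float)
    validate_proportions(P, "adipose lipid proportions")
    smi_v = scaled_mass_index(df["mass_kg"].to_numpy(float),
                              df["length_m"].to_numpy(float), smi)
    is_f = (df["sex"] == "F").to_numpy()
    flags = {}
    present = set(df["sex"])
    missing = sorted({"F", "M"} - present)
    if missing:
        flags["missing_sex"] = missing
    names = ["alpha_F", "alpha_M", "beta_PAL", "phi2"]
    positive = [False, False, False, True]
    pri = priors.for_params(names)
    entries = dict(pri.entries)
    for sex, pname in (("F", "alpha_F"), ("M", "alpha_M")):
        if sex in missing and entries[pname] == ("flat",):
            entries[pname] = ("normal", 0.0, 2.0)  # keep posterior proper
    pri = PriorSet(pri.name, entries)

    mS = smi_v.mean()
    smic = smi_v - mS

    def log_post(nat):
        aFc, aMc, b, phi = (nat[:, i] for i in range(4))
        alpha = np.where(is_f, aFc[:, None], aMc[:, None])
        mu = expit(alpha + b[:, None] * smic)
        ll = beta_logpdf_mean_precision(P, mu, phi[:, None]).sum(axis=1)
        vals = {"alpha_F": aFc - b * mS, "alpha_M": aMc - b * mS,
                "beta_PAL": b, "phi2": phi}
        return ll + _log_prior(vals, pri)

    def transform(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 2] * mS
        out[..., 1] = nat[..., 1] - nat[..., 2] * mS
        return out

    lo = logit(P)
    Z = np.column_stack([np.ones_like(smic), smic])
    a0, b0 = np.linalg.lstsq(Z, lo, rcond=None)[0]
    mu0 = expit(a0 + b0 * smic)
    v = max(np.var(P - mu0), 1e-5)
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / v - 1, 1.0, 90.0))
    init = np.array([a0, a0, b0, phi0])
    return _run("adipose_lipid", names, positive, log_post, init, cfg,
                flags=flags, transform=transform)


def fit_adipose_protein(df: pd.DataFrame, priors: PriorSet,
                        cfg: SamplerConfig) -> PosteriorFit:
    """Beta regression of adipose protein proportion on lipid proportion."""
    _check_n(len(df))
    PAL = df["lipid_proportion"].to_numpy(float)
    PAP = df["protein_proportion"].to_numpy(float)
    validate_proportions(PAL, "adipose lipid proportions")
    validate_proportions(PAP, "adipose protein proportions")
    names = ["alpha_PAP", "beta_PAP", "phi3"]
    positive = [False, False, True]
    pri = priors.for_params(names)

    mP = PAL.mean()
    PALc = PAL - mP

    def log_post(nat):
        ac, b, phi = nat[:, 0], nat[:, 1], nat[:, 2]
        mu = expit(ac[:, None] + b[:, None] * PALc)
        ll = beta_logpdf_mean_precision(PAP, mu, phi[:, None]).sum(axis=1)
        vals = {"alpha_PAP": ac - b * mP, "beta_PAP": b, "phi3": phi}
        return ll + _log_prior(vals, pri)

    def transform(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 1] * mP
        return out

    lo = logit(PAP)
    Z = np.column_stack([np.ones_like(PALc), PALc])
    a0, b0 = np.linalg.lstsq(Z, lo, rcond=None)[0]
    mu0 = expit(a0 + b0 * PALc)
    v = max(np.var(PAP - mu0), 1e-5)
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / v - 1, 1.0, 90.0))
    init = np.array([a0, b0, phi0])
    return _run("adipose_protein", names, positive, log_post, init, cfg,
                transform=transform)


def fit_combined_two_stage(df: pd.DataFrame, smi: SMIParams,
                           priors: PriorSet, cfg: SamplerConfig) -> dict:
    """Non-joint fallback: regression first, then beta on plug-in P_OU.

    Intended for testing/debugging; the joint ``fit_combined`` is the
    canonical procedure.
    """
    lnL, lnA, A, U, lnU, smi_v = _combined_data(df, smi)
    reg_names = ["alpha_lU0", "beta_lU1", "beta_lU2", "sd_lU"]
    positive = [False, False, False, True]
    pri = priors.for_params(reg_names)

    mL, mA, mS = lnL.mean(), lnA.mean(), smi_v.mean()
    lnLc, lnAc = lnL - mL, lnA - mA

    def log_post_reg(nat):
        a0c, b1, b2, sd = (nat[:, i] for i in range(4))
        mu = a0c[:, None] + b1[:, None] * lnLc + b2[:, None] * lnAc
        ll = normal_logpdf(lnU, mu, sd[:, None]).sum(axis=1)
        vals = {"alpha_lU0": a0c - b1 * mL - b2 * mA, "beta_lU1": b1,
                "beta_lU2": b2, "sd_lU": sd}
        return ll + _log_prior(vals, pri)

    def transform_reg(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 1] * mL - nat[..., 2] * mA
        return out

    a0, b1, b2, sd, aP, bP, phi = _combined_init(lnL, lnA, lnU, U, smi_v)
    stage1 = _run("total_muscle_regression", reg_names, positive,
                  log_post_reg, np.array([a0 + b1 * mL + b2 * mA, b1, b2,
                                          sd]), cfg, transform=transform_reg)

    m = stage1.posterior_means
    a0_hat, b1_hat = m["alpha_lU0"], m["beta_lU1"]
    O_U = U - np.exp(a0_hat + b1_hat * lnL)
    keep = O_U > 0
    P_OU = O_U[keep] / (A[keep] + O_U[keep])
    smi_k = smi_v[keep]
    alloc_names = ["alpha_POu", "beta_POu", "phi1"]
    pri2 = priors.for_params(alloc_names)

    mSk = smi_k.mean()
    smikc = smi_k - mSk

    def log_post_alloc(nat):
        aPc, bPc, phic = nat[:, 0], nat[:, 1], nat[:, 2]
        mu = expit(aPc[:, None] + bPc[:, None] * smikc)
        ll = beta_logpdf_mean_precision(P_OU, mu, phic[:, None]).sum(axis=1)
        vals = {"alpha_POu": aPc - bPc * mSk, "beta_POu": bPc, "phi1": phic}
        return ll + _log_prior(vals, pri2)

    def transform_alloc(nat):
        out = nat.copy()
        out[..., 0] = nat[..., 0] - nat[..., 1] * mSk
        return out

    stage2 = _run("allocation_plugin", alloc_names, [False, False, True],
                  log_post_alloc, np.array([aP + bP * mSk, bP, phi]), cfg,
                  flags={"n_dropped_invalid_latent": int((~keep).sum())},
                  transform=transform_alloc)
    return {"regression": stage1, "allocation": stage2}
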