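"""Scaled mass index (SMI): allometric body-condition standardization.

The SMI maps an individual's mass to the mass it would have at a reference
body length ``L0``, sliding along the population's log-log allometry:
``SMI = M * (L0 / L) ** b_sma``, where ``b_sma`` is the standardized major
axis (SMA) slope of ln(mass) on ln(length). The index is in kg and equals
the observed mass at the reference length, which makes it comparable across
bears of different structural size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class SMIError(ValueError):
    """Raised for degenerate inputs to the SMI fit or evaluation."""


@dataclass(frozen=True)
class SMIParams:
    """SMA scaling exponent and reference length (m)."""

    b_sma: float
    L0: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.b_sma):
            raise SMIError("b_sma must be finite")
        if not self.L0 > 0:
            raise SMIError("L0 must be positive")


def fit_sma(lengths: Sequence[float], masses: Sequence[float],
            L0: Optional[float] = None) -> SMIParams:
    """Fit the SMA slope on the log-log scale.

    The SMA slope is sign(r) * sd(ln M) / sd(ln L) — symmetric in the two
    variables, which is what makes it appropriate when both length and mass
    carry measurement error. ``L0`` defaults to the arithmetic mean of the
    training lengths and is persisted so fitted and prediction-time SMI
    agree.
    """
    L = np.asarray(lengths, dtype=float)
    M = np.asarray(masses, dtype=float)
    if L.shape != M.shape or L.ndim != 1:
        raise SMIError("lengths and masses must be 1-D and equal length")
    if L.size < 3:
        raise SMIError("at least 3 (length, mass) pairs required")
    if np.any(L <= 0) or np.any(M <= 0):
        raise SMIError("lengths and masses must be positive")
    lnL, lnM = np.log(L), np.log(M)
    sdL, sdM = np.std(lnL, ddof=1), np.std(lnM, ddof=1)
    if sdL == 0:
        raise SMIError("zero variance in ln(length)")
    if sdM == 0:
        b = 0.0
    else:
        r = np.corrcoef(lnL, lnM)[0, 1]
        b = float(np.sign(r) if r != 0 else 1.0) * sdM / sdL
    return SMIParams(b_sma=float(b), L0=float(np.mean(L)) if L0 is None else float(L0))


def scaled_mass_index(mass, length, p: SMIParams):
    """SMI (kg): mass standardized to the reference length."""
    mass = np.asarray(mass, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(mass <= 0) or np.any(length <= 0):
        raise SMIError("mass and length must be positive")
    out = mass * (p.L0 / length) ** p.b_sma
    return out if out.ndim else float(out)
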