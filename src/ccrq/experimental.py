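"""Experiment-facing arithmetic: doublet intensities -> CCR rates -> J values.

A longitudinal CCR rate is read off the differential relaxation of the two
doublet components after a mixing delay T as Gamma = ln(Ia/Ib) / (2T)
(natural logarithm: relaxation is exponential in e).  Which component is Ia
is the caller's choice; swapping them flips the sign.  Given the rate pair
(Gxy, Gz) for the 15N CSA / N-H dipole interference, the spectral density is
mapped exactly:

    J(wN) = Gz / (6 k dN),      J(0) = (Gxy - 0.5 Gz) / (4 k dN).

For the carbonyl channel the two in-plane CSA axes contribute jointly, so
only the composite (sxx - szz) Jxx(0) + (syy - szz) Jyy(0) is recoverable,
not Jxx and Jyy individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccr_rates import PhysicalConstants, RateSet, SpinPairSpec, k_prefactor

__all__ = [
    "DoubletRecord",
    "MappedJ",
    "rate_from_doublet",
    "rates_from_table",
    "map_j_from_rates",
    "map_j0_composite_C",
    "synth_doublets",
]


@dataclass(frozen=True)
class DoubletRecord:
    """One residue's doublet: component intensities and the mixing delay."""

    residue: str
    ia: float
    ib: float
    t_mix: float              # s
    sigma_i: float | None = None  # absolute intensity noise, same units as ia/ib

    def __post_init__(self) -> None:
        if self.ia <= 0 or self.ib <= 0:
            raise ValueError(f"residue {self.residue}: intensities must be positive")
        if self.t_mix <= 0:
            raise ValueError(f"residue {self.residue}: mixing delay must be positive")
        if self.sigma_i is not None and self.sigma_i < 0:
            raise ValueError(f"residue {self.residue}: sigma_I must be >= 0")


@dataclass(frozen=True)
class MappedJ:
    """Zero- and Larmor-frequency spectral-density values for one residue."""

    residue: str
    j0: float                 # s
    j_omega: float            # s
    sigma_j0: float = 0.0
    sigma_j_omega: float = 0.0


def rate_from_doublet(rec: DoubletRecord, swap: bool = False) -> tuple[float, float]:
    """CCR rate ln(Ia/Ib)/(2T) with first-order error propagation.

    Returns (gamma, sigma_gamma) in s^-1; sigma is 0 when no intensity noise
    is recorded.  ``swap`` exchanges the doublet components (sign flip).
    """
    ia, ib = (rec.ib, rec.ia) if swap else (rec.ia, rec.ib)
    gamma = math.log(ia / ib) / (2.0 * rec.t_mix)
    if rec.sigma_i is None:
        return gamma, 0.0
    sigma = rec.sigma_i / (2.0 * rec.t_mix) * math.sqrt(ia**-2 + ib**-2)
    return gamma, sigma


def rates_from_table(df: pd.DataFrame, swap: bool = False) -> pd.DataFrame:
    """Apply ``rate_from_doublet`` to a table with columns
    residue, Ia, Ib, T_s [, sigma_I]; invalid rows are reported in an
    ``error`` column and do not stop the processing of the others."""
    out = []
    for row in df.itertuples(index=False):
        sigma_i = getattr(row, "sigma_I", None)
        if sigma_i is not None and (sigma_i != sigma_i):  # NaN -> absent
            sigma_i = None
        try:
            rec = DoubletRecord(str(row.residue), float(row.Ia), float(row.Ib),
                                float(row.T_s), sigma_i)
            gamma, sigma = rate_from_doublet(rec, swap=swap)
            out.append((rec.residue, gamma, sigma, ""))
        except (ValueError, ZeroDivisionError) as exc:
            out.append((str(row.residue), np.nan, np.nan, str(exc)))
    return pd.DataFrame(out, columns=["residue", "gamma_s-1", "sigma_gamma_s-1",
                                      "error"])


def map_j_from_rates(
    rates: RateSet,
    pair: SpinPairSpec,
    c: PhysicalConstants,
    delta_n: float = 170.0,
    residue: str = "",
    sigma_xy: float = 0.0,
    sigma_z: float = 0.0,
) -> MappedJ:
    """Invert the N/NH rate equations: exact algebraic spectral-density mapping."""
    k = k_prefactor(pair, c)
    if k == 0:
        raise ZeroDivisionError("zero rate prefactor; check constants")
    scale = k * delta_n
    j_omega = rates.gamma_z / (6.0 * scale)
    j0 = rates.j0_combination / (4.0 * scale)
    sigma_jw = abs(sigma_z) / (6.0 * scale)
    sigma_j0 = math.sqrt(sigma_xy**2 + 0.25 * sigma_z**2) / (4.0 * scale)
    return MappedJ(residue, j0=j0, j_omega=j_omega,
                   sigma_j0=sigma_j0, sigma_j_omega=sigma_jw)


def map_j0_composite_C(rates: RateSet, pair: SpinPairSpec,
                       c: PhysicalConstants) -> float:
    """Composite (sxx - szz) Jxx(0) + (syy - szz) Jyy(0) in ppm.s.

    The two carbonyl CSA axes contribute to a single observable, so only
    this weighted sum of zero-frequency densities can be mapped, not the
    individual Jxx and Jyy.
    """
    k = k_prefactor(pair, c)
    if k == 0:
        raise ZeroDivisionError("zero rate prefactor; check constants")
    return rates.j0_combination / (4.0 * k)


def synth_doublets(
    true_rates: dict[str, float] | pd.Series,
    t_mix: float,
    noise: float = 0.0,
    seed: int | None = None,
    i0: float = 1e6,
) -> pd.DataFrame:
    """Synthesize a doublet-intensity table from known ground-truth rates.

    Ia/Ib = exp(2 Gamma T); each component gets multiplicative Gaussian
    noise of relative size ``noise``.  Deterministic for a fixed seed.
    Returns columns residue, Ia, Ib, T_s, sigma_I.
    """
    if t_mix <= 0:
        raise ValueError("mixing delay must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for residue, gamma in dict(true_rates).items():
        ia = i0 * math.exp(+gamma * t_mix)
        ib = i0 * math.exp(-gamma * t_mix)
        if noise > 0:
            ia *= 1.0 + noise * rng.standard_normal()
            ib *= 1.0 + noise * rng.standard_normal()
        rows.append((residue, ia, ib, t_mix, noise * i0))
    return pd.DataFrame(rows, columns=["residue", "Ia", "Ib", "T_s", "sigma_I"])
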