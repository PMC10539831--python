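"""CSA-dipole cross-correlated relaxation rates and the Q ratio.

Two interference pathways in the peptide plane are considered:

* the 15N CSA with the N-H dipole (transverse rate Gxy and longitudinal
  rate Gz of the 15N doublet components), and
* the carbonyl 13C' CSA with the C'-Ca dipole.

Both transverse rates carry 4 J(0) + 3 J(omega) and both longitudinal rates
6 J(omega), so the combination Gxy - 0.5 Gz isolates the zero-frequency
spectral density exactly.  The ratio of the two J(0) combinations,

    Q = (Gxy^C'/C'Ca - 0.5 Gz^C'/C'Ca) / (Gxy^N/NH - 0.5 Gz^N/NH),

is independent of the magnetic field and of the overall molecular size; it
equals a pure ratio of P2 geometry projections for isotropic tumbling and
deviates from that baseline when the segmental diffusion is anisotropic.

The absolute rate prefactor k = (2/5)(1/12)(mu0 hbar / 4 pi)(g1 g2 / r^3)
(B0 g_csa) x 1e-6 follows one common normalisation convention for the
spectral density (none of the quantities this package reports depend on the
choice: Q and all J extractions are prefactor-ratio-safe, and the same k is
used for synthesis and inversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants as sc

from .geometry import PeptidePlaneGeometry, build_peptide_plane
from .spectral_density import (
    DiffusionModel,
    MotionModel,
    build_spectrum,
    j_lorentzian,
)

__all__ = [
    "PhysicalConstants",
    "SpinPairSpec",
    "RateSet",
    "QRecord",
    "k_prefactor",
    "gamma_xy_N",
    "gamma_z_N",
    "gamma_xy_C",
    "gamma_z_C",
    "q_ratio",
    "rate_sets",
    "q_record",
]

# gyromagnetic ratios, rad s^-1 T^-1 (15N is negative)
GAMMA_H1 = sc.value("proton gyromag. ratio")  # 2.675e8
GAMMA_N15 = -2.7116e7
GAMMA_C13 = 6.728284e7


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants and the static field; defaults are CODATA + 18.8 T."""

    mu0: float = sc.mu_0
    hbar: float = sc.hbar
    gamma_h: float = GAMMA_H1
    gamma_n: float = GAMMA_N15
    gamma_c: float = GAMMA_C13
    b0: float = 18.8

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("B0 must be positive")

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency, rad/s."""
        return abs(self.gamma_n) * self.b0

    @property
    def omega_c(self) -> float:
        """13C Larmor frequency, rad/s."""
        return abs(self.gamma_c) * self.b0


@dataclass(frozen=True)
class SpinPairSpec:
    """A CSA-dipole interference pair: dipole distance plus CSA nucleus."""

    pair: str                 # "N/NH" or "C/CCA"
    r_angstrom: float         # internuclear distance of the dipole
    gamma_dip1: float         # gyromagnetic ratios of the two dipolar spins
    gamma_dip2: float
    gamma_csa: float          # gyromagnetic ratio of the CSA (relaxing) nucleus

    def __post_init__(self) -> None:
        if self.r_angstrom <= 0:
            raise ValueError("internuclear distance must be positive")


def nh_pair(c: PhysicalConstants, r_angstrom: float = 1.04) -> SpinPairSpec:
    return SpinPairSpec("N/NH", r_angstrom, c.gamma_n, c.gamma_h, c.gamma_n)


def cca_pair(c: PhysicalConstants, r_angstrom: float = 1.53) -> SpinPairSpec:
    return SpinPairSpec("C/CCA", r_angstrom, c.gamma_c, c.gamma_c, c.gamma_c)


@dataclass(frozen=True)
class RateSet:
    """Transverse and longitudinal CCR rates for one spin pair (s^-1)."""

    pair: str
    gamma_xy: float
    gamma_z: float

    @property
    def j0_combination(self) -> float:
        """Gxy - 0.5 Gz: the pure-J(0) combination, s^-1."""
        return self.gamma_xy - 0.5 * self.gamma_z


@dataclass(frozen=True)
class QRecord:
    """Rates for both pairs and the derived zero-frequency ratio."""

    n_rates: RateSet
    c_rates: RateSet
    q: float


def k_prefactor(pair: SpinPairSpec, c: PhysicalConstants) -> float:
    """Rate prefactor in s^-2: multiply by (sigma in ppm) x (J in s) for s^-1.

    The ppm-to-dimensionless factor 1e-6 is applied here, once.
    """
    r = pair.r_angstrom * 1e-10
    dipolar = c.mu0 * c.hbar / (4.0 * np.pi) * pair.gamma_dip1 * pair.gamma_dip2 / r**3
    csa = c.b0 * pair.gamma_csa
    return (2.0 / 5.0) * (1.0 / 12.0) * dipolar * csa * 1e-6


def _check_j0(j0: float, where: str) -> None:
    if j0 < 0:
        warnings.warn(
            f"negative J(0) passed to {where}; check spectrum inputs",
            RuntimeWarning,
            stacklevel=3,
        )


def gamma_xy_N(j0: float, jwn: float, pair: SpinPairSpec, c: PhysicalConstants,
               delta_n: float = 170.0) -> float:
    """Transverse 15N CSA / N-H dipole CCR: k dN [4 J(0) + 3 J(wN)], s^-1."""
    _check_j0(j0, "gamma_xy_N")
    return k_prefactor(pair, c) * delta_n * (4.0 * j0 + 3.0 * jwn)


def gamma_z_N(jwn: float, pair: SpinPairSpec, c: PhysicalConstants,
              delta_n: float = 170.0) -> float:
    """Longitudinal 15N CSA / N-H dipole CCR: k dN 6 J(wN), s^-1."""
    return k_prefactor(pair, c) * delta_n * 6.0 * jwn


def gamma_xy_C(jxx0: float, jxxw: float, jyy0: float, jyyw: float,
               pair: SpinPairSpec, c: PhysicalConstants,
               sigma_xx: float = 249.4, sigma_yy: float = 191.1,
               sigma_zz: float = 87.9) -> float:
    """Transverse 13C' CSA / C'-Ca dipole CCR, s^-1.

    k [ (sxx - szz)(4 Jxx(0) + 3 Jxx(wC)) + (syy - szz)(4 Jyy(0) + 3 Jyy(wC)) ]
    with Jxx/Jyy the cross spectral densities of the dipole with the two
    in-plane CSA axes.
    """
    k = k_prefactor(pair, c)
    return k * (
        (sigma_xx - sigma_zz) * (4.0 * jxx0 + 3.0 * jxxw)
        + (sigma_yy - sigma_zz) * (4.0 * jyy0 + 3.0 * jyyw)
    )


def gamma_z_C(jxxw: float, jyyw: float, pair: SpinPairSpec, c: PhysicalConstants,
              sigma_xx: float = 249.4, sigma_yy: float = 191.1,
              sigma_zz: float = 87.9) -> float:
    """Longitudinal 13C' CSA / C'-Ca dipole CCR, s^-1.

    k [ (sxx - szz) 6 Jxx(wC) + (syy - szz) 6 Jyy(wC) ]; the same principal
    value multiplies the same axis as in the transverse rate, so the
    combination Gxy - 0.5 Gz reduces to
    4 k [ (sxx - szz) Jxx(0) + (syy - szz) Jyy(0) ].
    """
    k = k_prefactor(pair, c)
    return k * 6.0 * (
        (sigma_xx - sigma_zz) * jxxw + (sigma_yy - sigma_zz) * jyyw
    )


def q_ratio(c_rates: RateSet, n_rates: RateSet) -> float:
    """Q = (Gxy - 0.5 Gz)_C'/C'Ca / (Gxy - 0.5 Gz)_N/NH, dimensionless."""
    denom = n_rates.j0_combination
    if abs(denom) < 1e-15:
        raise ZeroDivisionError(
            "N/NH J(0) combination is zero; Q is undefined"
        )
    return c_rates.j0_combination / denom


def rate_sets(
    plane: PeptidePlaneGeometry,
    d: DiffusionModel,
    m: MotionModel | None = None,
    c: PhysicalConstants | None = None,
) -> tuple[RateSet, RateSet]:
    """Compute (N/NH, C'/C'Ca) RateSets for one peptide plane and dynamics."""
    if c is None:
        c = PhysicalConstants()
    if m is None:
        m = MotionModel()
    prm = plane.params

    spec_n = build_spectrum(plane.orientation("n_h"), plane.orientation("csa_n"), d, m)
    jn0 = j_lorentzian(spec_n, 0.0)
    jnw = j_lorentzian(spec_n, c.omega_n)
    pn = nh_pair(c, prm.n_h)
    n_rates = RateSet(
        "N/NH",
        gamma_xy=gamma_xy_N(jn0, jnw, pn, c, prm.delta_n),
        gamma_z=gamma_z_N(jnw, pn, c, prm.delta_n),
    )

    spec_xx = build_spectrum(plane.orientation("c_ca"), plane.orientation("csa_c_xx"), d, m)
    spec_yy = build_spectrum(plane.orientation("c_ca"), plane.orientation("csa_c_yy"), d, m)
    jxx0 = j_lorentzian(spec_xx, 0.0)
    jxxw = j_lorentzian(spec_xx, c.omega_c)
    jyy0 = j_lorentzian(spec_yy, 0.0)
    jyyw = j_lorentzian(spec_yy, c.omega_c)
    pc = cca_pair(c, prm.ca_c)
    c_rates = RateSet(
        "C/CCA",
        gamma_xy=gamma_xy_C(jxx0, jxxw, jyy0, jyyw, pc, c,
                            prm.c_sigma_xx, prm.c_sigma_yy, prm.c_sigma_zz),
        gamma_z=gamma_z_C(jxxw, jyyw, pc, c,
                          prm.c_sigma_xx, prm.c_sigma_yy, prm.c_sigma_zz),
    )
    return n_rates, c_rates


def q_record(
    plane: PeptidePlaneGeometry | None = None,
    d: DiffusionModel | None = None,
    m: MotionModel | None = None,
    c: PhysicalConstants | None = None,
) -> QRecord:
    """One-shot pipeline: geometry + dynamics -> both RateSets and Q."""
    if plane is None:
        plane = build_peptide_plane()
    if d is None:
        d = DiffusionModel.from_tau_eff(1e-9, 1.0)
    n_rates, c_rates = rate_sets(plane, d, m, c)
    return QRecord(n_rates=n_rates, c_rates=c_rates, q=q_ratio(c_rates, n_rates))
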