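"""Spectral densities for axially symmetric rotational diffusion.

The orientational time-correlation function of two unit vectors u, v rigidly
attached to a symmetric-top diffusor is a sum of three exponentials whose
times are the inverted eigenvalues of the diffusion tensor,

    tau_k = [6 D_perp + k^2 (D_par - D_perp)]^-1,   k = 0, 1, 2,

with Woessner amplitudes A_k(u, v) set by the polar angles of u and v in the
tumbling frame.  A model-free extension adds a fourth Lorentzian carrying
fast isotropic internal motion: the slow anisotropic terms are weighted by
the order parameter S^2 and the internal term by (1 - S^2) P2(u.v) with

    tau_3^-1 = tau_int^-1 + 4 D_perp + 2 D_par = tau_int^-1 + tau_eff^-1.

No 2/5-type normalisation factor is applied inside J: spectral densities are
plain weighted sums of correlation times, so J(0) is literally the area
under the TCF.  All angle arguments are signed in-plane angles in degrees
(the peptide-plane workflow never leaves the plane; azimuth differences of
0 or 180 deg are absorbed into the sign of the polar angle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from .geometry import angle_between, p2

__all__ = [
    "DiffusionModel",
    "MotionModel",
    "LorentzianSpectrum",
    "tau_eigenvalues",
    "woessner_amplitudes",
    "j_lorentzian",
    "build_spectrum",
    "iso_ratio_limit",
    "numeric_j",
    "tcf_from_spectrum",
]


@dataclass(frozen=True)
class DiffusionModel:
    """Axially symmetric rotational diffusion tensor.

    Parameters
    ----------
    d_parallel, d_perp : float
        Diffusion rates about / perpendicular to the unique axis (s^-1).
    beta : float
        In-plane orientation of the unique axis, degrees counterclockwise
        from the C'->Ca direction.
    """

    d_parallel: float
    d_perp: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.d_parallel <= 0 or self.d_perp <= 0:
            raise ValueError("diffusion rates must be positive")

    @classmethod
    def from_tau_eff(
        cls, tau_eff: float, anisotropy: float, beta: float = 0.0
    ) -> "DiffusionModel":
        """Construct from the effective tumbling time tau_eff = (4 D_perp + 2 D_par)^-1
        and the anisotropy ratio D_par / D_perp."""
        if tau_eff <= 0 or anisotropy <= 0:
            raise ValueError("tau_eff and anisotropy must be positive")
        d_perp = 1.0 / (tau_eff * (4.0 + 2.0 * anisotropy))
        return cls(d_parallel=anisotropy * d_perp, d_perp=d_perp, beta=beta)

    @property
    def anisotropy(self) -> float:
        return self.d_parallel / self.d_perp

    @property
    def tau_eff(self) -> float:
        """Effective tumbling time (4 D_perp + 2 D_par)^-1 in seconds."""
        return 1.0 / (4.0 * self.d_perp + 2.0 * self.d_parallel)


@dataclass(frozen=True)
class MotionModel:
    """Model-free internal motion: order parameter and internal time (s)."""

    s2: float = 1.0
    tau_int: float = 100e-12

    def __post_init__(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_int <= 0:
            raise ValueError("tau_int must be positive")


@dataclass(frozen=True)
class LorentzianSpectrum:
    """J(omega) as an ordered list of (amplitude, correlation time) terms."""

    amplitudes: tuple = field(default=())
    taus: tuple = field(default=())

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.taus):
            raise ValueError("amplitudes and taus must have equal length")
        if any(t <= 0 for t in self.taus):
            raise ValueError("correlation times must be positive")
        total = sum(self.amplitudes)
        if not -0.5 - 1e-9 <= total <= 1.0 + 1e-9:
            raise ValueError(
                f"sum of amplitudes {total} outside the P2 range [-0.5, 1]"
            )

    @property
    def terms(self) -> list[tuple[float, float]]:
        return list(zip(self.amplitudes, self.taus))


def tau_eigenvalues(d: DiffusionModel) -> np.ndarray:
    """Correlation times (tau_0, tau_1, tau_2) of the symmetric top, seconds."""
    k = np.arange(3)
    return 1.0 / (6.0 * d.d_perp + k**2 * (d.d_parallel - d.d_perp))


def woessner_amplitudes(theta_u_deg, theta_v_deg):
    """Amplitudes (A0, A1, A2) for coplanar vectors at signed polar angles.

    theta are signed angles (degrees) from the diffusion main axis measured
    in the common plane.  For coplanar vectors the azimuthal factors
    cos(phi_u - phi_v) and cos(2 phi_u - 2 phi_v) are +-1 and are absorbed
    by the signs of theta, giving

        A0 = P2(cos th_u) P2(cos th_v)
        A1 = 0.75 sin(2 th_u) sin(2 th_v)
        A2 = 0.75 sin^2(th_u) sin^2(th_v)

    which satisfy A0 + A1 + A2 = P2(cos(th_u - th_v)).
    Inputs broadcast; outputs are stacked on the first axis.
    """
    tu = np.radians(np.asarray(theta_u_deg, dtype=float))
    tv = np.radians(np.asarray(theta_v_deg, dtype=float))
    a0 = p2(np.cos(tu)) * p2(np.cos(tv))
    a1 = 0.75 * np.sin(2.0 * tu) * np.sin(2.0 * tv)
    a2 = 0.75 * np.sin(tu) ** 2 * np.sin(tv) ** 2
    return np.stack(np.broadcast_arrays(a0, a1, a2))


def j_lorentzian(spec: LorentzianSpectrum, omega: float) -> float:
    """Evaluate J(omega) = sum_k a_k tau_k / (1 + (omega tau_k)^2), seconds."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    a = np.asarray(spec.amplitudes)
    t = np.asarray(spec.taus)
    return float(np.sum(a * t / (1.0 + (omega * t) ** 2)))


def build_spectrum(
    u_deg: float, v_deg: float, d: DiffusionModel, m: MotionModel | None = None
) -> LorentzianSpectrum:
    """Four-term model-free spectrum for in-plane vectors u and v.

    u_deg and v_deg are orientations in the peptide plane (degrees from
    C'->Ca); their polar angles in the tumbling frame are u - beta and
    v - beta.  With S^2 = 1 the internal term vanishes and the spectrum
    reduces to the rigid symmetric top; with S^2 = 0 only the isotropic
    internal Lorentzian survives.
    """
    if m is None:
        m = MotionModel()
    theta_u = u_deg - d.beta
    theta_v = v_deg - d.beta
    a_slow = woessner_amplitudes(theta_u, theta_v)
    taus = tau_eigenvalues(d)
    p2_uv = p2(np.cos(np.radians(theta_u - theta_v)))
    tau3 = 1.0 / (1.0 / m.tau_int + 1.0 / d.tau_eff)
    amplitudes = tuple(m.s2 * a_slow) + ((1.0 - m.s2) * p2_uv,)
    return LorentzianSpectrum(amplitudes=amplitudes, taus=tuple(taus) + (tau3,))


def iso_ratio_limit(u_deg, v_deg, x_deg, y_deg) -> float:
    """Isotropic limit of J_uv(0)/J_xy(0): P2(cos ang(u,v)) / P2(cos ang(x,y)).

    Raises if the reference pair (x, y) sits at the magic angle, where the
    denominator vanishes.
    """
    denom = p2(np.cos(np.radians(angle_between(x_deg, y_deg))))
    if abs(denom) < 1e-9:
        raise ZeroDivisionError(
            "reference pair at the magic angle: P2(x.y) ~ 0, ratio undefined"
        )
    return float(p2(np.cos(np.radians(angle_between(u_deg, v_deg)))) / denom)


def tcf_from_spectrum(spec: LorentzianSpectrum, t) -> np.ndarray:
    """Reconstruct C(t) = sum_k a_k exp(-t / tau_k) on a time grid (seconds)."""
    t = np.asarray(t, dtype=float)
    a = np.asarray(spec.amplitudes)[:, None]
    tau = np.asarray(spec.taus)[:, None]
    return np.sum(a * np.exp(-t[None, :] / tau), axis=0)


def numeric_j(t, c, omega: float) -> float:
    """Cosine-transform quadrature of a sampled TCF: int_0^inf C(t) cos(wt) dt.

    Serves as the numeric oracle for ``j_lorentzian``: the time grid must be
    strictly increasing, dense enough to resolve the fastest decay and the
    oscillation period 2 pi / omega, and extend to ~10x the slowest time.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.ndim != 1 or t.size < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    return float(simpson(c * np.cos(omega * t), x=t))
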