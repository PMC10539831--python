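"""Canonical peptide-plane geometry and in-plane interaction orientations.

The peptide plane is flat, so the whole construction is two-dimensional:
every dipole vector and every in-plane CSA principal axis is represented by
a signed angle in degrees measured counterclockwise from the C'->Ca(i)
direction.  The out-of-plane CSA component (zz for the carbonyl tensor) is
normal to the plane and never enters the in-plane angle bookkeeping.

Sign conventions (fixed, so that downstream angles are reproducible):

* C' sits at the origin with C'->Ca(i) along +x (angle 0).
* N lies at +114 deg (counterclockwise), O at -121 deg.
* The peptide bond is trans: Ca(i) and Ca(i+1) are on opposite sides of the
  C'-N bond, and the amide proton is on the side opposite Ca(i+1).

With these choices the N-H bond points to +57 deg, i.e. rotating an axis
counterclockwise from C'->Ca moves it *towards* the N-H vector, which is the
sense in which the diffusion-tensor orientation beta is swept elsewhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PlaneParams",
    "PeptidePlaneGeometry",
    "build_peptide_plane",
    "csa_axes",
    "p2",
    "angle_between",
    "wrap_angle",
]

_ANGLE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PlaneParams:
    """Bond lengths (angstrom), bond angles (degrees) and CSA parameters.

    Defaults are the canonical peptide-plane values: Engh-Huber-type bond
    geometry with an amide bond length of 1.04 A, an axially symmetric
    15N CSA of 170 ppm tilted 20 deg from the N-H bond, and a fully
    anisotropic carbonyl CSA (249.4/191.1/87.9 ppm) whose xx axis makes an
    angle alpha_c = 37 deg with the C'-N bond.
    """

    ca_c: float = 1.53
    c_o: float = 1.24
    c_n: float = 1.32
    n_ca: float = 1.47
    n_h: float = 1.04
    ca_c_o: float = 121.0
    ca_c_n: float = 114.0
    o_c_n: float = 125.0
    c_n_h: float = 123.0
    c_n_ca: float = 123.0
    h_n_ca: float = 114.0
    delta_n: float = 170.0
    alpha_n: float = 20.0
    c_sigma_xx: float = 249.4
    c_sigma_yy: float = 191.1
    c_sigma_zz: float = 87.9
    alpha_c: float = 37.0

    def __post_init__(self) -> None:
        for name in ("ca_c", "c_o", "c_n", "n_ca", "n_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name!r} must be positive")
        c_sum = self.ca_c_o + self.ca_c_n + self.o_c_n
        if abs(c_sum - 360.0) > _ANGLE_SUM_TOL:
            raise ValueError(
                f"bond angles around C' sum to {c_sum} deg, expected 360"
            )
        n_sum = self.c_n_h + self.c_n_ca + self.h_n_ca
        if abs(n_sum - 360.0) > _ANGLE_SUM_TOL:
            raise ValueError(
                f"bond angles around N sum to {n_sum} deg, expected 360"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlaneParams":
        """Load overrides from a JSON file keyed by the field names."""
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def wrap_angle(deg):
    """Wrap an angle (degrees) into (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def p2(c):
    """Second-order Legendre polynomial P2(c) = 1.5 c^2 - 0.5 for |c| <= 1."""
    arr = np.asarray(c, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("P2 argument must be a cosine, |c| <= 1")
    out = 1.5 * arr * arr - 0.5
    return out if out.ndim else float(out)


def angle_between(u_deg, v_deg):
    """Unsigned angle in [0, 180] between two in-plane directions (degrees)."""
    if u_deg is None or v_deg is None:
        raise ValueError("orientation must be a finite angle")
    d = np.abs(wrap_angle(np.asarray(u_deg, float) - np.asarray(v_deg, float)))
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class PeptidePlaneGeometry:
    """In-plane atom coordinates and named interaction orientations.

    ``coords`` maps atom labels (CA_i, C, O, N, H, CA_ip1) to 2-D positions
    in angstrom; ``orientations`` maps vector names to signed angles in
    degrees from the C'->Ca(i) axis:

    - ``c_ca``   : C'-Ca(i) dipole (0 by construction)
    - ``n_h``    : N-H amide dipole
    - ``ca_ca``  : Ca(i)->Ca(i+1) virtual vector
    - ``csa_n``  : unique axis of the axially symmetric 15N CSA
    - ``csa_c_xx`` / ``csa_c_yy`` : in-plane carbonyl CSA axes (zz is the
      plane normal)
    """

    params: PlaneParams
    coords: dict = field(repr=False)
    orientations: dict

    def orientation(self, name: str) -> float:
        try:
            return self.orientations[name]
        except KeyError:
            raise KeyError(
                f"unknown vector {name!r}; known: {sorted(self.orientations)}"
            ) from None

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.coords[a] - self.coords[b]))


def _unit(angle_deg: float) -> np.ndarray:
    r = math.radians(angle_deg)
    return np.array([math.cos(r), math.sin(r)])


def csa_axes(plane: "PeptidePlaneGeometry", nucleus: str) -> tuple[float, float]:
    """In-plane principal-axis orientations for a CSA tensor.

    For the carbonyl (``"C13prime"``) returns (xx, yy): xx lies at
    ``alpha_c`` from the C'-N bond line, rotated between the C'->Ca and
    N->C' directions, so that angle(xx, C'Ca) = (180 - 114) - alpha_c;
    yy is xx rotated by 90 deg in-plane.  For ``"N15"`` returns the unique
    axis twice: it lies ``alpha_n`` away from the N-H bond, tilted towards
    the N-C' bond.  These conventions reproduce the P2 projection bounds of
    the canonical geometry and must not be changed silently.
    """
    prm = plane.params
    if nucleus == "C13prime":
        xx = wrap_angle(prm.alpha_c - (180.0 - prm.ca_c_n))
        yy = wrap_angle(xx + 90.0)
        return float(xx), float(yy)
    if nucleus == "N15":
        axis = wrap_angle(plane.orientations["n_h"] - prm.alpha_n)
        return float(axis), float(axis)
    raise ValueError(f"unknown nucleus tag {nucleus!r}; use 'N15' or 'C13prime'")


def build_peptide_plane(params: PlaneParams | None = None) -> PeptidePlaneGeometry:
    """Place the peptide-plane atoms and derive all named orientations.

    Deterministic frame: C' at the origin, C'->Ca(i) along the +x axis, N at
    positive angles (O opposite), trans peptide bond, amide proton opposite
    Ca(i+1) across the C'-N bond.
    """
    prm = params if params is not None else PlaneParams()

    c = np.zeros(2)
    ca_i = prm.ca_c * _unit(0.0)
    n = c + prm.c_n * _unit(prm.ca_c_n)
    o = c + prm.c_o * _unit(-prm.ca_c_o)

    # directions out of N; N->C' points back towards the origin
    n_to_c = wrap_angle(prm.ca_c_n - 180.0)
    n_h_dir = wrap_angle(n_to_c + prm.c_n_h)      # proton on the Ca(i) side
    n_ca_dir = wrap_angle(n_to_c - prm.c_n_ca)    # trans: Ca(i+1) on the O side
    h = n + prm.n_h * _unit(n_h_dir)
    ca_ip1 = n + prm.n_ca * _unit(n_ca_dir)

    ca_ca_vec = ca_ip1 - ca_i
    ca_ca_dir = wrap_angle(math.degrees(math.atan2(ca_ca_vec[1], ca_ca_vec[0])))

    orientations = {
        "c_ca": 0.0,
        "n_h": float(n_h_dir),
        "ca_ca": float(ca_ca_dir),
        "csa_n": float(wrap_angle(n_h_dir - prm.alpha_n)),
        "csa_c_xx": float(wrap_angle(prm.alpha_c - (180.0 - prm.ca_c_n))),
        "csa_c_yy": float(wrap_angle(prm.alpha_c - (180.0 - prm.ca_c_n) + 90.0)),
    }
    coords = {"C": c, "CA_i": ca_i, "O": o, "N": n, "H": h, "CA_ip1": ca_ip1}
    return PeptidePlaneGeometry(params=prm, coords=coords, orientations=orientations)
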