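"""Helical parameters from backbone torsions, and a geometric screw-axis fit.

The closed-form mapping goes back to the classical treatment of a regular
helix of planar-amide residues: with the half-sum and half-difference of
the backbone torsions,

    s = (phi + psi)/2,    t = (phi - psi)/2        (radians)

the winding angle per residue theta satisfies

    cos(theta/2) = -0.817 sin(s) + 0.045 sin(t)

and the rise per residue d follows from

    d sin(theta/2) = -0.68 cos(t) + 2.9 cos(s).

Residues per turn n = 360/theta (theta in degrees), pitch p = n * d.  The
numeric coefficients embed one fixed covalent backbone geometry, so the
mapping is exact only for that geometry; the screw-axis fit below serves
as an independent geometric oracle on explicit coordinates.

Also provided: the classical point-dipole interaction energy, in the two
algebraic forms in circulation (with and without the 1/r^3 prefactor),
used to show that pure dipole-dipole electrostatics is minimized by
collinear (linear hydrogen bond) arrangements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "HelicalParams",
    "DipolePair",
    "HelixDomainError",
    "helical_params_from_torsions",
    "parameter_surface",
    "surface_to_rows",
    "fit_screw_axis",
    "dipole_interaction",
    "CLASSICAL_ALPHA",
    "CLASSICAL_310",
    "CONSENSUS_HELIX",
]

#: classical alpha-helix torsions (IUPAC 1970 / fiber diffraction)
CLASSICAL_ALPHA = (-57.0, -47.0)
#: classical 3_10-helix torsions
CLASSICAL_310 = (-49.0, -26.0)
#: consensus helix of high-resolution crystal structures
CONSENSUS_HELIX = (-62.0, -43.0)


class HelixDomainError(ValueError):
    """No real helical solution for the given torsions (|cos(theta/2)| > 1)."""


@dataclass(frozen=True)
class HelicalParams:
    """theta: winding per residue (deg); n: residues/turn; d: rise/residue (A);
    p: pitch, rise per turn (A)."""

    theta: float
    n: float
    d: float
    p: float


def helical_params_from_torsions(phi: float, psi: float) -> HelicalParams:
    """Closed-form helical parameters for a regular helix at (phi, psi) degrees.

    Raises :class:`HelixDomainError` outside the helical domain and a
    ValueError for the degenerate theta = 0 / 360 cases.
    """
    s = math.radians((phi + psi) / 2.0)
    t = math.radians((phi - psi) / 2.0)
    cos_half = -0.817 * math.sin(s) + 0.045 * math.sin(t)
    if abs(cos_half) > 1.0:
        raise HelixDomainError(
            f"no helical solution at (phi={phi}, psi={psi}): |cos(theta/2)| = "
            f"{abs(cos_half):.3f} > 1"
        )
    half = math.acos(cos_half)          # radians, in [0, pi]
    sin_half = math.sin(half)
    if sin_half < 1e-12:
        raise ValueError(f"degenerate winding angle at (phi={phi}, psi={psi})")
    theta = math.degrees(2.0 * half)
    n = 360.0 / theta
    d = (-0.68 * math.cos(t) + 2.9 * math.cos(s)) / sin_half
    return HelicalParams(theta=theta, n=n, d=d, p=n * d)


def parameter_surface(
    phi_range: tuple[float, float],
    psi_range: tuple[float, float],
    step: float = 1.0,
):
    """Dense (phi, psi) grid of helical parameters.

    Returns (phi_values, psi_values, params) where params is a dict of
    2-D float arrays ``theta``, ``n``, ``d``, ``p`` indexed [i_phi, i_psi],
    with NaN marking cells outside the helical domain, plus a boolean
    ``valid`` mask.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    phis = np.arange(phi_range[0], phi_range[1] + step / 2, step)
    psis = np.arange(psi_range[0], psi_range[1] + step / 2, step)
    shape = (len(phis), len(psis))
    out = {key: np.full(shape, np.nan) for key in ("theta", "n", "d", "p")}
    valid = np.zeros(shape, dtype=bool)
    for i, phi in enumerate(phis):
        for j, psi in enumerate(psis):
            try:
                hp = helical_params_from_torsions(float(phi), float(psi))
            except (HelixDomainError, ValueError):
                continue
            out["theta"][i, j] = hp.theta
            out["n"][i, j] = hp.n
            out["d"][i, j] = hp.d
            out["p"][i, j] = hp.p
            valid[i, j] = True
    out["valid"] = valid
    return phis, psis, out


SURFACE_TSV_HEADER = "phi\tpsi\ttheta\tn\td\tp\tvalid"


def surface_to_rows(phis, psis, params) -> list[str]:
    """Flatten a parameter surface to TSV rows matching SURFACE_TSV_HEADER."""
    rows = []
    for i, phi in enumerate(phis):
        for j, psi in enumerate(psis):
            ok = bool(params["valid"][i, j])
            fmt = (lambda v: f"{v:.4f}" if ok else "nan")
            rows.append(
                f"{phi:.1f}\t{psi:.1f}\t{fmt(params['theta'][i, j])}"
                f"\t{fmt(params['n'][i, j])}\t{fmt(params['d'][i, j])}"
                f"\t{fmt(params['p'][i, j])}\t{int(ok)}"
            )
    return rows


# -- geometric oracle: screw-axis fit ---------------------------------------

def fit_screw_axis(calpha_coords, window: int = 4) -> tuple[float, float]:
    """Rotation per residue and rise per residue from explicit CA coordinates.

    Superposes the leading window of CA positions (i .. i+window) onto the
    trailing window (i+1 .. i+window+1) with an optimal rigid transform
    (Kabsch); for a regular helix that transform is the helix's screw
    operation, so its rotation angle is the winding per residue and the
    translation component along the rotation axis is the rise per residue.

    Returns (theta_geo degrees, d_geo angstroms), averaged over all
    window positions.  Requires >= window + 2 points, window >= 3, and
    non-collinear input.
    """
    coords = np.asarray(calpha_coords, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    if len(coords) < window + 2:
        raise ValueError(f"need at least {window + 2} CA positions")
    spread = np.linalg.norm(np.cross(coords[1] - coords[0], coords - coords[0]), axis=1)
    if np.max(spread) < 1e-8:
        raise ValueError("collinear CA positions: screw axis undefined")

    thetas: list[float] = []
    rises: list[float] = []
    m = window + 1  # points per window
    for i in range(len(coords) - m):
        a = coords[i : i + m]
        b = coords[i + 1 : i + 1 + m]
        theta, rise = _screw_from_superposition(a, b)
        thetas.append(theta)
        rises.append(rise)
    return float(np.mean(thetas)), float(np.mean(rises))


def _screw_from_superposition(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Screw parameters of the rigid transform mapping point set a onto b."""
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T                     # maps a-frame onto b-frame
    cos_theta = max(-1.0, min(1.0, (np.trace(rot) - 1.0) / 2.0))
    theta = math.degrees(math.acos(cos_theta))
    # rotation axis: eigenvector of rot for eigenvalue 1
    w, v = np.linalg.eig(rot)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    translation = cb - rot @ ca
    rise = float(np.dot(translation, axis))
    return theta, abs(rise)


# -- dipole-dipole interaction ----------------------------------------------

@dataclass(frozen=True)
class DipolePair:
    """Two point dipoles: magnitudes (Debye), separation r (A), theta1/theta2
    between each dipole and the inter-dipole axis, theta12 between the
    dipoles (degrees)."""

    mu1: float
    mu2: float
    r: float
    theta1: float
    theta2: float
    theta12: float

    def __post_init__(self) -> None:
        if self.mu1 < 0 or self.mu2 < 0:
            raise ValueError("dipole magnitudes must be >= 0")
        if self.r <= 0:
            raise ValueError("separation must be positive")


def dipole_interaction(pair: DipolePair, form: str = "as_printed") -> float:
    """Point-dipole interaction energy.

    ``as_printed`` evaluates V = -mu1*mu2*(cos theta12 - 3 cos theta1 cos
    theta2) with no radial dependence (the angular analysis is unchanged);
    ``textbook`` multiplies the same angular factor by +mu1*mu2/r^3, the
    conventional form in which an aligned head-to-tail pair (theta1 =
    theta2 = theta12 = 0) is attractive: V = -2 mu1 mu2 / r^3.
    """
    angular = (
        math.cos(math.radians(pair.theta12))
        - 3.0 * math.cos(math.radians(pair.theta1)) * math.cos(math.radians(pair.theta2))
    )
    if form == "as_printed":
        return -pair.mu1 * pair.mu2 * angular
    if form == "textbook":
        if pair.r <= 0:
            raise ValueError("separation must be positive")
        return pair.mu1 * pair.mu2 / pair.r**3 * angular
    raise ValueError(f"unknown form {form!r}; use 'as_printed' or 'textbook'")
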