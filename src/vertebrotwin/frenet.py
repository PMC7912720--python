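"""Discrete Frenet curvature and torsion of a polyline centerline.

Curvature at an interior point is the inverse circumradius of the
circumscribed circle through the point and its two neighbours (the local
osculating circle).  Torsion is the signed dihedral angle between
consecutive osculating planes divided by the arc step; the sign is positive
for a right-handed helix.  Both are boundary-trimmed: the profile covers the
interior points only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import Centerline, CenterlineError

_COLLINEAR_EPS = 1e-12


@dataclass(frozen=True)
class FrenetProfile:
    """Per-interior-point curvature/torsion along a centerline."""

    arclengths: np.ndarray       # (m,) arc coordinate of each interior point
    curvature: np.ndarray        # (m,) 1/mm, >= 0
    torsion: np.ndarray          # (m,) 1/mm, signed
    torsion_defined: np.ndarray  # (m,) bool; False where a collinear triple
                                 # forced tau to the 0 placeholder

    @property
    def mean_curvature(self) -> float:
        return float(np.mean(self.curvature))

    @property
    def mean_abs_torsion(self) -> float:
        return float(np.mean(np.abs(self.torsion)))


def _circumcurvature(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorised inverse circumradius for stacked triples."""
    a = p1 - p0
    b = p2 - p1
    c = p2 - p0
    cross = np.cross(a, b)
    num = 2.0 * np.linalg.norm(cross, axis=-1)
    den = (
        np.linalg.norm(a, axis=-1)
        * np.linalg.norm(b, axis=-1)
        * np.linalg.norm(c, axis=-1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(den > 0, num / den, 0.0)
    return kappa


def frenet_profile(c: Centerline) -> FrenetProfile:
    """Estimate curvature and torsion at every interior point.

    Requires at least 5 points (torsion needs two consecutive osculating
    planes).  At a collinear triple the curvature is exactly 0 and the
    torsion is undefined; it is reported as 0 with ``torsion_defined`` False
    at that index.
    """
    pts = c.points
    n = pts.shape[0]
    if n < 5:
        raise CenterlineError("frenet_profile needs at least 5 points")
    s = c.arclengths

    p0, p1, p2 = pts[:-2], pts[1:-1], pts[2:]
    kappa = _circumcurvature(p0, p1, p2)

    # Osculating-plane normals at interior points.
    normals = np.cross(p1 - p0, p2 - p1)
    norm_len = np.linalg.norm(normals, axis=1)
    defined = norm_len > _COLLINEAR_EPS
    unit = np.zeros_like(normals)
    unit[defined] = normals[defined] / norm_len[defined, None]

    # Signed dihedral rate between consecutive interior points.
    ni, nj = unit[:-1], unit[1:]
    both = defined[:-1] & defined[1:]
    dot = np.clip(np.einsum("ij,ij->i", ni, nj), -1.0, 1.0)
    angle = np.arccos(dot)
    tangent = pts[2:-1] - pts[1:-2]  # shared edge of the two triples
    sign = np.sign(np.einsum("ij,ij->i", np.cross(ni, nj), tangent))
    ds = s[2:-1] - s[1:-2]
    rate = np.where(both, sign * angle / ds, 0.0)

    # Assign per-point torsion as the mean of the adjacent dihedral rates.
    m = n - 2
    tau = np.zeros(m)
    tau_def = np.zeros(m, dtype=bool)
    left_ok = np.concatenate([[False], both])
    right_ok = np.concatenate([both, [False]])
    left_rate = np.concatenate([[0.0], rate])
    right_rate = np.concatenate([rate, [0.0]])
    cnt = left_ok.astype(int) + right_ok.astype(int)
    with np.errstate(invalid="ignore"):
        tau = np.where(cnt > 0, (left_rate * left_ok + right_rate * right_ok) / np.maximum(cnt, 1), 0.0)
    tau_def = cnt > 0
    # A straight point inside a curve: curvature 0 is exact, torsion flagged.
    return FrenetProfile(
        arclengths=s[1:-1].copy(),
        curvature=kappa,
        torsion=tau,
        torsion_defined=tau_def,
    )
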