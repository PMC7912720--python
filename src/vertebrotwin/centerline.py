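"""Centerline and vessel-network containers plus resampling and smoothing.

A centerline is an ordered 3D polyline with a per-point maximum-inscribed-
sphere radius, the atomic object every geometric index is computed from.  A
vessel network is the labelled Y of the posterior circulation: left and right
vertebral arteries (VA) meeting at the vertebrobasilar confluence, and the
basilar artery (BA) running from the confluence to the basilar tip.

Coordinate convention (fixed throughout the package): a patient-LPS-like
frame with +X = patient left and +Z = superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CenterlineError(ValueError):
    """Invalid centerline geometry or parameters."""


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D polyline (mm) with per-point radius (mm)."""

    points: np.ndarray  # (n, 3) float
    radii: np.ndarray   # (n,) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        rad = np.asarray(self.radii, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise CenterlineError("points must be an (n, 3) array")
        if rad.shape != (pts.shape[0],):
            raise CenterlineError("radii must match point count")
        if pts.shape[0] < 4:
            raise CenterlineError("a centerline needs at least 4 points")
        if not np.all(np.isfinite(pts)) or not np.all(np.isfinite(rad)):
            raise CenterlineError("non-finite coordinates or radii")
        if np.any(rad <= 0):
            raise CenterlineError("radii must be strictly positive")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise CenterlineError("consecutive points must be distinct")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "radii", rad)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arc length, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Total polyline arc length in mm."""
        return float(self.arclengths[-1])

    @property
    def chord(self) -> float:
        """Straight-line distance between the two endpoints."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(), self.radii[::-1].copy())


@dataclass(frozen=True)
class VesselNetwork:
    """Labelled vertebrobasilar Y: two VAs merging into the BA.

    Both VAs are oriented to *end* at the confluence; the BA starts at the
    confluence and ends at the basilar tip.
    """

    left_va: Centerline
    right_va: Centerline
    ba: Centerline
    confluence: np.ndarray    # (3,)
    basilar_tip: np.ndarray   # (3,)
    extra_branches: tuple = field(default=())  # unlabelled spurs, pre-pruning

    def __post_init__(self) -> None:
        conf = np.asarray(self.confluence, dtype=float)
        tip = np.asarray(self.basilar_tip, dtype=float)
        object.__setattr__(self, "confluence", conf)
        object.__setattr__(self, "basilar_tip", tip)
        tol = 1e-6
        for name, cl in (("left_va", self.left_va), ("right_va", self.right_va)):
            if np.linalg.norm(cl.points[-1] - conf) > tol:
                raise CenterlineError(f"{name} does not terminate at the confluence")
        if np.linalg.norm(self.ba.points[0] - conf) > tol:
            raise CenterlineError("ba does not originate at the confluence")
        if np.linalg.norm(self.ba.points[-1] - tip) > tol:
            raise CenterlineError("ba does not end at the basilar tip")

    def vessels(self) -> dict:
        return {"left_va": self.left_va, "right_va": self.right_va, "ba": self.ba}


def _chord_walk(points: np.ndarray, seg_len: np.ndarray, cum: np.ndarray, step: float, n_steps: int):
    """Step along a polyline taking Euclidean (chord) steps of fixed length.

    Returns (sample points, their source arc coordinates, arc coordinate of
    the last reached sample or +inf if the polyline was exhausted early).
    """
    P = points.tolist()
    L = seg_len.tolist()
    C = cum.tolist()
    sqrt = np.sqrt
    samples = [tuple(P[0])]
    arcs = [0.0]
    seg = 0            # current segment index
    t = 0.0            # fraction along current segment
    n_seg = len(L)
    step2 = step * step
    for _ in range(n_steps):
        px, py, pz = samples[-1]
        found = False
        j, tj = seg, t
        while j < n_seg:
            x0, y0, z0 = P[j]
            x1, y1, z1 = P[j + 1]
            dx, dy, dz = x1 - x0, y1 - y0, z1 - z0
            ax = x0 + tj * dx - px
            ay = y0 + tj * dy - py
            az = z0 + tj * dz - pz
            rem = 1.0 - tj
            ex, ey, ez = rem * dx, rem * dy, rem * dz
            # solve |a + u*e| = step for u in (0, 1]
            aa = ex * ex + ey * ey + ez * ez
            bb = 2.0 * (ex * ax + ey * ay + ez * az)
            cc = ax * ax + ay * ay + az * az - step2
            disc = bb * bb - 4.0 * aa * cc
            if disc >= 0.0 and aa > 0.0:
                u = (-bb + sqrt(disc)) / (2.0 * aa)
                if 0.0 < u <= 1.0 + 1e-12:
                    u = min(u, 1.0)
                    frac = tj + u * rem
                    samples.append((x0 + frac * dx, y0 + frac * dy, z0 + frac * dz))
                    arcs.append(C[j] + frac * L[j])
                    seg, t = j, frac
                    found = True
                    break
            j += 1
            tj = 0.0
        if not found:
            return samples, arcs, np.inf
    return samples, arcs, arcs[-1]


def resample_arclength(c: Centerline, spacing: float) -> Centerline:
    """Resample a centerline into segments of equal length.

    The polyline is resampled by stepping equal Euclidean chords whose
    size is solved (bisection) so that ``ceil(length / spacing)`` steps land
    exactly on the far endpoint.  The output is therefore *exactly* uniform
    in its own arc length, endpoints are preserved, and re-running the
    operation at the same spacing is idempotent to floating precision.
    Radii are linearly interpolated in source arc length.
    """
    if not np.isfinite(spacing) or spacing <= 0:
        raise CenterlineError("spacing must be positive and finite")
    pts = c.points
    radii = c.radii
    # Decimate very dense inputs first (plain arc-length interpolation keeps
    # points on the polyline) so the chord walk below stays cheap.
    s_src = c.arclengths
    if len(pts) > 4 * s_src[-1] / spacing + 8:
        fine = np.arange(0.0, s_src[-1], spacing / 4.0)
        fine = np.append(fine, s_src[-1])
        pts = np.column_stack([np.interp(fine, s_src, pts[:, k]) for k in range(3)])
        radii = np.interp(fine, s_src, radii)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = float(cum[-1])
    if spacing >= total:
        raise CenterlineError("spacing must be smaller than the total length")
    n_steps = int(np.ceil(total / spacing - 1e-9))

    # The arc position reached after n_steps chord steps grows with the step
    # size until the walk overshoots the far end early (reported as +inf);
    # bisect to the critical step where the walk lands exactly on the end.
    lo, hi = total / n_steps * 0.25, float(spacing) * (1.0 + 1e-9)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if lo == mid or hi == mid:
            break
        _, _, reached = _chord_walk(pts, seg_len, cum, mid, n_steps)
        if np.isinf(reached):
            hi = mid
        else:
            lo = mid
    samples, arcs, _ = _chord_walk(pts, seg_len, cum, lo, n_steps)
    out = np.asarray(samples)
    out[-1] = pts[-1]
    rad = np.interp(np.clip(arcs, 0.0, total), cum, radii)
    return Centerline(out, rad)


def taubin_smooth(
    c: Centerline,
    lambda_pass: float = 0.5,
    mu_pass: float = -0.53,
    iterations: int = 20,
) -> Centerline:
    """Taubin low-pass polyline smoothing with fixed endpoints.

    Alternates a shrinking Laplacian step (factor ``lambda_pass`` > 0) with an
    inflating step (``mu_pass`` < -lambda_pass) using uniform umbrella
    weights; the negative pass cancels most of the shrinkage that a pure
    Laplacian smoother of the same strength would cause.  Radii are smoothed
    with the same operator so the radius profile stays registered with the
    points.
    """
    if not (0.0 < lambda_pass < 1.0):
        raise CenterlineError("lambda_pass must be in (0, 1)")
    if not (mu_pass < -lambda_pass):
        raise CenterlineError("mu_pass must be < -lambda_pass")
    if int(iterations) != iterations or iterations < 1:
        raise CenterlineError("iterations must be an integer >= 1")

    pts = c.points.copy()
    rad = c.radii.copy()

    def _step(arr: np.ndarray, factor: float) -> np.ndarray:
        lap = 0.5 * (arr[:-2] + arr[2:]) - arr[1:-1]
        out = arr.copy()
        out[1:-1] = arr[1:-1] + factor * lap
        return out

    for _ in range(int(iterations)):
        pts = _step(pts, lambda_pass)
        rad = _step(rad, lambda_pass)
        pts = _step(pts, mu_pass)
        rad = _step(rad, mu_pass)
    rad = np.maximum(rad, 1e-12)
    return Centerline(pts, rad)


def laplacian_smooth(c: Centerline, lambda_pass: float = 0.5, iterations: int = 20) -> Centerline:
    """Pure Laplacian smoothing (shrinking); kept as a comparison baseline."""
    if not (0.0 < lambda_pass < 1.0):
        raise CenterlineError("lambda_pass must be in (0, 1)")
    pts = c.points.copy()
    for _ in range(int(iterations)):
        lap = 0.5 * (pts[:-2] + pts[2:]) - pts[1:-1]
        pts[1:-1] = pts[1:-1] + lambda_pass * lap
    return Centerline(pts, c.radii.copy())


def transform_network(
    net: VesselNetwork, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0), scale: float = 1.0
) -> VesselNetwork:
    """Apply ``x -> scale * R x + t`` to every point, radius and landmark."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)

    def _tx(cl: Centerline) -> Centerline:
        return Centerline(scale * cl.points @ R.T + t, scale * cl.radii)

    return VesselNetwork(
        left_va=_tx(net.left_va),
        right_va=_tx(net.right_va),
        ba=_tx(net.ba),
        confluence=scale * R @ net.confluence + t,
        basilar_tip=scale * R @ net.basilar_tip + t,
        extra_branches=tuple(_tx(b) for b in net.extra_branches),
    )
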