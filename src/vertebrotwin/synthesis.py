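"""Parametric synthesis of vertebrobasilar vessel networks.

Stands in for MRI-reconstructed centerlines: given target values of the
morphological indices, build a labelled three-vessel network whose measured
indices recover the targets.

Construction:

* Basilar artery — a smooth space curve whose chord joins the confluence
  (origin) to the basilar tip on the +Z axis.  An in-plane sine bow along
  +X sets the bend (median |X| deviation from the chord) and an orthogonal
  double-lobe sine along Y adds arc length without changing the median X
  deviation; the two amplitudes are solved numerically against dense
  continuum measurements so that bend and tortuosity hit their targets.
* Vertebral arteries — circular-helix arcs.  A helix of radius ``a`` and
  pitch parameter ``b`` has constant curvature a/(a²+b²) and torsion
  b/(a²+b²), so the curvature/torsion indices are met in closed form; the
  swept angle is solved from the tortuosity target.  Each helix is placed
  rigidly (no blending) with its distal end on the confluence — a rigid
  placement preserves the closed-form curvature and torsion exactly,
  whereas any blend-in segment would bias them.

All radii are constant along a vessel, so the equivalent diameter equals
the target diameter exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import brentq

from .centerline import Centerline, VesselNetwork
from ._rng import substream

_DENSE = 4001  # samples for continuum calibration of the BA curve
_STORE_SPACING = 0.15  # mm, sampling of the stored polylines


class GeometryError(ValueError):
    """Infeasible or invalid geometry targets."""


@dataclass(frozen=True)
class GeometryTargets:
    """Target morphological indices for one synthetic network (mm / %)."""

    ba_length: float = 24.08
    ba_mean_diameter: float = 3.42
    ba_bend: float = 2.57            # median |X| deviation from the chord, mm
    ba_tortuosity: float = 6.37      # (1 - chord/arc) * 100
    left_va_diameter: float = 2.44
    right_va_diameter: float = 2.36
    left_va_curvature: float = 7.79   # mean curvature (1/mm) * 100
    right_va_curvature: float = 8.10
    left_va_torsion: float = 12.34    # mean |torsion| (1/mm) * 100
    right_va_torsion: float = 12.62
    left_va_tortuosity: float = 11.77
    right_va_tortuosity: float = 11.57

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise GeometryError(f"{f.name} must be finite")
        for name in ("ba_length", "ba_mean_diameter", "left_va_diameter", "right_va_diameter"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        for name in ("ba_tortuosity", "left_va_tortuosity", "right_va_tortuosity"):
            if not (0.0 <= getattr(self, name) < 100.0):
                raise GeometryError(f"{name} must be in [0, 100)")
        if self.ba_bend < 0:
            raise GeometryError("ba_bend must be non-negative")
        for name in ("left_va_curvature", "right_va_curvature", "left_va_torsion", "right_va_torsion"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be non-negative")


# ---------------------------------------------------------------- BA

def _ba_curve(amp_x: float, amp_y: float, chord: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([
        amp_x * np.sin(np.pi * t),
        amp_y * np.sin(2.0 * np.pi * t),
        chord * t,
    ])


def _continuum_bend_arc(amp_x: float, amp_y: float, chord: float) -> tuple[float, float]:
    """Dense-sampling (arc-length weighted) bend and arc length of the bow."""
    pts = _ba_curve(amp_x, amp_y, chord, _DENSE)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = float(seg.sum())
    # weighted median of |x| over arc-length-uniform sampling
    x_mid = np.abs(0.5 * (pts[:-1, 0] + pts[1:, 0]))
    order = np.argsort(x_mid)
    cw = np.cumsum(seg[order])
    bend = float(x_mid[order][np.searchsorted(cw, 0.5 * arc)])
    return bend, arc


def minimum_ba_tortuosity(ba_length: float, ba_bend: float) -> float:
    """Smallest tortuosity (%) a basilar bow of the given bend can have."""
    if ba_bend == 0:
        return 0.0
    # With no Y lobe, solve amplitude for the bend at each candidate chord.
    def excess(tort):
        chord = ba_length * (1.0 - tort / 100.0)
        amp = _solve_bend_amplitude(ba_bend, 0.0, chord)
        _, arc = _continuum_bend_arc(amp, 0.0, chord)
        return arc - ba_length
    lo, hi = 1e-6, 95.0
    if excess(lo) <= 0:
        return lo
    if excess(hi) > 0:
        # bend cannot be reached by any chord shortening in range
        return hi
    return float(brentq(excess, lo, hi, xtol=1e-4))


def _solve_bend_amplitude(bend: float, amp_y: float, chord: float) -> float:
    if bend == 0:
        return 0.0
    def f(amp):
        b, _ = _continuum_bend_arc(amp, amp_y, chord)
        return b - bend
    hi = max(4.0 * bend, 1.0)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise GeometryError("cannot reach requested bend")
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def _build_ba(targets: GeometryTargets) -> Centerline:
    L = targets.ba_length
    tort = targets.ba_tortuosity
    chord = L * (1.0 - tort / 100.0)
    if targets.ba_bend == 0 and tort == 0:
        n = int(np.ceil(L / _STORE_SPACING)) + 1
        t = np.linspace(0.0, 1.0, n)
        pts = np.column_stack([np.zeros(n), np.zeros(n), L * t])
        return Centerline(pts, np.full(n, targets.ba_mean_diameter / 2.0))

    amp_x, amp_y = 0.0, 0.0
    for _ in range(12):
        amp_x = _solve_bend_amplitude(targets.ba_bend, amp_y, chord)
        _, arc = _continuum_bend_arc(amp_x, amp_y, chord)
        if arc > L * (1.0 + 1e-6) and amp_y == 0.0:
            raise GeometryError(
                "ba_bend incompatible with ba_tortuosity: bend alone already "
                f"needs arc {arc:.3f} mm > target {L:.3f} mm"
            )
        def arc_gap(ay):
            _, a = _continuum_bend_arc(amp_x, ay, chord)
            return a - L
        if arc_gap(0.0) >= 0:
            amp_y_new = 0.0
        else:
            hi = max(chord, 1.0)
            while arc_gap(hi) < 0:
                hi *= 2.0
            amp_y_new = float(brentq(arc_gap, 0.0, hi, xtol=1e-10))
        if abs(amp_y_new - amp_y) < 1e-9:
            amp_y = amp_y_new
            break
        amp_y = amp_y_new
    amp_x = _solve_bend_amplitude(targets.ba_bend, amp_y, chord)

    n = max(int(np.ceil(L / _STORE_SPACING)) + 1, 24)
    pts = _ba_curve(amp_x, amp_y, chord, n)
    return Centerline(pts, np.full(n, targets.ba_mean_diameter / 2.0))


# ---------------------------------------------------------------- VA

def maximum_va_tortuosity(curvature_pct: float, torsion_pct: float) -> float:
    """Largest tortuosity (%) a helix with these indices can reach.

    The chord/arc ratio of a helix arc decreases with the swept angle down
    to its one-turn value tau/sqrt(kappa^2+tau^2), so high torsion at low
    curvature caps the attainable tortuosity.
    """
    kappa = curvature_pct / 100.0
    tau = torsion_pct / 100.0
    if kappa <= 0:
        return 0.0
    return (1.0 - tau / np.hypot(kappa, tau)) * 100.0


def _helix_sweep_angle(tortuosity_pct: float, a: float, b: float) -> float:
    """Swept angle giving the requested tortuosity for helix (a, b)."""
    target_ratio = 1.0 - tortuosity_pct / 100.0
    speed = np.hypot(a, b)

    def ratio(theta):
        chord = np.hypot(2.0 * a * np.sin(theta / 2.0), b * theta)
        return chord / (speed * theta)

    lo, hi = 1e-4, 2.0 * np.pi - 1e-6
    if ratio(hi) > target_ratio:
        raise GeometryError("requested VA tortuosity not reachable within one helix turn")
    return float(brentq(lambda th: ratio(th) - target_ratio, lo, hi, xtol=1e-12))


def _build_va(
    diameter: float,
    curvature_pct: float,
    torsion_pct: float,
    tortuosity_pct: float,
    side: str,
    rng: np.random.Generator,
) -> Centerline:
    kappa = curvature_pct / 100.0
    tau = torsion_pct / 100.0
    if kappa <= 0:
        if tortuosity_pct > 1e-9:
            raise GeometryError("a straight VA (zero curvature) cannot have tortuosity > 0")
        length = 35.0
        n = int(np.ceil(length / _STORE_SPACING)) + 1
        t = np.linspace(0.0, 1.0, n)
        sx = 1.0 if side == "left" else -1.0
        start = np.array([sx * 12.0, 0.0, -30.0])
        pts = start[None, :] * (1.0 - t)[:, None]
        return Centerline(pts, np.full(n, diameter / 2.0))

    denom = kappa * kappa + tau * tau
    a, b = kappa / denom, tau / denom
    theta = _helix_sweep_angle(tortuosity_pct, a, b)
    arc = theta * np.hypot(a, b)
    n = max(int(np.ceil(arc / _STORE_SPACING)) + 1, 24)
    th = np.linspace(0.0, theta, n)
    pts = np.column_stack([a * np.cos(th), a * np.sin(th), b * th])

    # Rigid placement: distal end at the origin (confluence), approaching
    # from below and from the vessel's own side of the midline.
    end = pts[-1]
    tang_end = np.array([-a * np.sin(th[-1]), a * np.cos(th[-1]), b])
    tang_end /= np.linalg.norm(tang_end)
    sx = 1.0 if side == "left" else -1.0
    approach = np.array([-sx * 0.45, 0.0, 1.0])
    approach /= np.linalg.norm(approach)

    def rot_between(u, v):
        c = float(np.clip(u @ v, -1.0, 1.0))
        axis = np.cross(u, v)
        s = np.linalg.norm(axis)
        if s < 1e-14:
            if c > 0:
                return np.eye(3)
            # opposite: rotate pi about any axis orthogonal to u
            w = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            axis = np.cross(u, w)
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
            return np.eye(3) + 2.0 * K @ K
        axis /= s
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + s * K + (1.0 - c) * K @ K

    R_align = rot_between(tang_end, approach)
    rolls = rng.uniform(0.0, 2.0 * np.pi) + np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    for roll in rolls:
        cr, sr = np.cos(roll), np.sin(roll)
        K = np.array([[0, -approach[2], approach[1]], [approach[2], 0, -approach[0]], [-approach[1], approach[0], 0]])
        R_roll = np.eye(3) + sr * K + (1.0 - cr) * K @ K
        R = R_roll @ R_align
        placed = (pts - end) @ R.T
        free = placed[0]
        # free end must sit on its own side and clearly below the tip
        if sx * free[0] > 1.0 and free[2] < -1.0:
            return Centerline(placed, np.full(n, diameter / 2.0))
    raise GeometryError(f"could not place {side} VA on its own side of the midline")


# ---------------------------------------------------------------- network

def build_vessel_network(targets: GeometryTargets, seed: int = 0) -> VesselNetwork:
    """Build a labelled synthetic network matching the geometry targets."""
    rng = substream(seed, "geometry")
    ba = _build_ba(targets)
    left = _build_va(
        targets.left_va_diameter, targets.left_va_curvature,
        targets.left_va_torsion, targets.left_va_tortuosity, "left", rng,
    )
    right = _build_va(
        targets.right_va_diameter, targets.right_va_curvature,
        targets.right_va_torsion, targets.right_va_tortuosity, "right", rng,
    )
    return VesselNetwork(
        left_va=left, right_va=right, ba=ba,
        confluence=np.zeros(3), basilar_tip=ba.points[-1],
    )


def perturb_network(
    network: VesselNetwork,
    noise_sd_point: float = 0.0,
    noise_sd_radius: float = 0.0,
    spur_probability: float = 0.0,
    seed: int = 0,
    spur_length: float = 1.5,
) -> VesselNetwork:
    """Emulate reconstruction artifacts: point/radius jitter and short spurs.

    Interior points are jittered with isotropic Gaussian noise; endpoints
    (hence the landmarks and the confluence) are left untouched.  With
    probability ``spur_probability`` one short (< pruning threshold)
    unlabelled branch is attached at a random interior point.
    """
    if noise_sd_point < 0 or noise_sd_radius < 0 or not (0 <= spur_probability <= 1):
        raise GeometryError("noise magnitudes must be non-negative, spur probability in [0, 1]")
    if noise_sd_point == 0 and noise_sd_radius == 0 and spur_probability == 0:
        return network
    rng = substream(seed, "perturb")

    def jitter(cl: Centerline) -> Centerline:
        pts = cl.points.copy()
        rad = cl.radii.copy()
        if noise_sd_point > 0:
            pts[1:-1] += rng.normal(0.0, noise_sd_point, size=(cl.n_points - 2, 3))
        if noise_sd_radius > 0:
            rad = np.maximum(rad + rng.normal(0.0, noise_sd_radius, size=cl.n_points), 0.05)
        return Centerline(pts, rad)

    vessels = {name: jitter(cl) for name, cl in network.vessels().items()}
    extras = list(network.extra_branches)
    if rng.uniform() < spur_probability:
        host = vessels[rng.choice(["left_va", "right_va", "ba"])]
        i = int(rng.integers(1, host.n_points - 1))
        base = host.points[i]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = np.linspace(0.0, 1.0, 6)
        spur_pts = base[None, :] + np.outer(t, direction * spur_length)
        extras.append(Centerline(spur_pts, np.full(6, 0.4)))
    return VesselNetwork(
        left_va=vessels["left_va"], right_va=vessels["right_va"], ba=vessels["ba"],
        confluence=network.confluence, basilar_tip=network.basilar_tip,
        extra_branches=tuple(extras),
    )


def sample_physiological_targets(rng: np.random.Generator) -> GeometryTargets:
    """Draw a random target vector in a physiologically plausible range."""
    ba_length = rng.uniform(18.0, 32.0)
    ba_bend = rng.uniform(0.2, 4.5)
    min_tort = minimum_ba_tortuosity(ba_length, ba_bend)
    ba_tort = rng.uniform(min_tort * 1.15 + 0.4, max(min_tort * 1.3 + 3.0, 14.0))

    def va_side():
        kappa = rng.uniform(4.0, 12.0)
        tau = rng.uniform(2.0, 20.0)
        while maximum_va_tortuosity(kappa, tau) < 6.0:
            tau *= 0.6
        hi = min(18.0, 0.85 * maximum_va_tortuosity(kappa, tau))
        tort = rng.uniform(min(5.0, 0.5 * hi), hi)
        return kappa, tau, tort

    lk, lt, ltt = va_side()
    rk, rt, rtt = va_side()
    return GeometryTargets(
        ba_length=ba_length,
        ba_mean_diameter=rng.uniform(2.5, 4.5),
        ba_bend=ba_bend,
        ba_tortuosity=ba_tort,
        left_va_diameter=rng.uniform(1.4, 3.6),
        right_va_diameter=rng.uniform(1.4, 3.6),
        left_va_curvature=lk,
        right_va_curvature=rk,
        left_va_torsion=lt,
        right_va_torsion=rt,
        left_va_tortuosity=ltt,
        right_va_tortuosity=rtt,
    )
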