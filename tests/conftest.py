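import numpy as np
import pytest

import vertebrotwin as vt


def make_line(length=24.0, n=25, radius=1.0, axis=(0.0, 0.0, 1.0)):
    axis = np.asarray(axis, float)
    t = np.linspace(0.0, 1.0, n)
    return vt.Centerline(np.outer(t, axis * length), np.full(n, radius))


def make_circle_arc(radius=10.0, angle=np.pi, n=300, r_tube=1.0):
    th = np.linspace(0.0, angle, n)
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.zeros(n)])
    return vt.Centerline(pts, np.full(n, r_tube))


def make_helix(a=3.0, b=1.0, turns=2.0, n=500, r_tube=0.5):
    th = np.linspace(0.0, 2.0 * np.pi * turns, n)
    pts = np.column_stack([a * np.cos(th), a * np.sin(th), b * th])
    return vt.Centerline(pts, np.full(n, r_tube))


@pytest.fixture
def canonical_y():
    """Straight-limbed Y: BA up +Z, left VA inlet at +X, right at -X."""
    n = 30
    t = np.linspace(1.0, 0.0, n)[:, None]
    left = vt.Centerline(t * np.array([14.0, 1.0, -22.0]), np.full(n, 1.2))
    right = vt.Centerline(t * np.array([-13.0, -0.5, -23.0]), np.full(n, 1.1))
    s = np.linspace(0.0, 1.0, n)[:, None]
    ba = vt.Centerline(s * np.array([0.3, 0.4, 24.0]), np.full(n, 1.7))
    return vt.VesselNetwork(left_va=left, right_va=right, ba=ba,
                            confluence=np.zeros(3), basilar_tip=ba.points[-1])


@pytest.fixture
def small_cohort():
    spec = vt.CohortSpec(n_mz_pairs=40, n_dz_pairs=20, seed=11)
    return vt.simulate_cohort(spec)
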