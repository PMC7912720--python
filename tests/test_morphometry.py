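"""Geometric indices, basilar bend, dominance rule, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import vertebrotwin as vt
from vertebrotwin.morphometry import MorphometryError
from vertebrotwin.centerline import transform_network

from conftest import make_line, make_circle_arc
from oracles import dense_bend_oracle


class TestGeometryIndices:
    def test_straight_cylinder_closed_forms(self):
        c = vt.resample_arclength(make_line(24.0, 49, radius=1.75), 0.5)
        gi = vt.geometry_indices(c)
        assert gi.length_mm == pytest.approx(24.0, abs=1e-9)
        assert gi.tortuosity_pct == pytest.approx(0.0, abs=1e-9)
        assert gi.mean_area_mm2 == pytest.approx(np.pi * 1.75 ** 2, rel=1e-9)
        assert gi.volume_mm3 == pytest.approx(np.pi * 1.75 ** 2 * 24.0, rel=1e-9)
        assert gi.equivalent_diameter_mm == pytest.approx(3.5, rel=1e-9)
        assert gi.curvature_index_pct == pytest.approx(0.0, abs=1e-9)

    def test_semicircle_tortuosity(self):
        """Chord 2R over arc piR: tortuosity (1 - 2/pi)*100 ~ 36.34%."""
        c = vt.resample_arclength(make_circle_arc(10.0, np.pi, 2000), 0.05)
        gi = vt.geometry_indices(c)
        assert gi.tortuosity_pct == pytest.approx((1 - 2 / np.pi) * 100, abs=0.05)
        assert gi.chord_arc_ratio == pytest.approx(2 / np.pi, abs=1e-3)

    def test_curvature_index_is_mean_kappa_times_100(self):
        c = vt.resample_arclength(make_circle_arc(12.3456, 2.0, 2000), 0.1)
        gi = vt.geometry_indices(c)
        assert gi.curvature_index_pct == pytest.approx(100 / 12.3456, rel=0.01)


class TestBaBend:
    def test_straight_ba_zero_bend_no_lean(self):
        ba = make_line(24.0, 49)
        bend, lean = vt.ba_bend(ba, ba.points[0], ba.points[-1])
        assert bend == pytest.approx(0.0, abs=1e-12)
        assert lean == "none"

    def test_planar_arc_matches_dense_oracle_and_mirror(self):
        """Arc bowed to +X: bend equals the dense-sampling weighted median
        of |x| offsets; mirroring to -X flips the lean, not the bend."""
        R, half = 50.0, 24.0 / 2
        phi = np.arcsin(half / R)
        th = np.linspace(-phi, phi, 4001)
        # chord along Z, bow toward +X
        pts = np.column_stack([R * np.cos(th) - R * np.cos(phi),
                               np.zeros_like(th), R * np.sin(th)])
        ba = vt.resample_arclength(vt.Centerline(pts, np.ones(len(th))), 0.02)
        bend, lean = vt.ba_bend(ba, ba.points[0], ba.points[-1])

        def curve(t):
            return np.column_stack([R * np.cos(t) - R * np.cos(phi),
                                    np.zeros_like(t), R * np.sin(t)])

        oracle = dense_bend_oracle(curve, -phi, phi)
        assert bend == pytest.approx(oracle, abs=1e-3)
        assert lean == "left"

        mirrored = vt.Centerline(pts * np.array([-1.0, 1.0, 1.0]), np.ones(len(th)))
        mb = vt.resample_arclength(mirrored, 0.02)
        bend2, lean2 = vt.ba_bend(mb, mb.points[0], mb.points[-1])
        assert bend2 == pytest.approx(bend, abs=1e-9)
        assert lean2 == "right"

    def test_landmark_mismatch_rejected(self):
        ba = make_line(24.0, 49)
        with pytest.raises(MorphometryError):
            vt.ba_bend(ba, ba.points[0] + [0, 0, 1.0], ba.points[-1])


class TestDominance:
    @pytest.mark.parametrize("dl,dr,diff,side", [
        (2.8, 2.4, 0.4, "left"),
        (2.44, 2.36, 0.08, "equal"),
        (2.4, 2.7, 0.3, "equal"),        # boundary is non-dominant (strict rule)
        (2.0, 2.31, 0.31, "right"),
    ])
    def test_rule(self, dl, dr, diff, side):
        got_diff, got_side = vt.classify_dominance(dl, dr)
        assert got_diff == pytest.approx(diff, abs=1e-12)
        assert got_side == side

    def test_invalid_diameters_rejected(self):
        with pytest.raises(MorphometryError):
            vt.classify_dominance(-1.0, 2.0)
        with pytest.raises(MorphometryError):
            vt.classify_dominance(2.0, np.nan)

    @given(dl=st.floats(0.5, 6.0), dr=st.floats(0.5, 6.0))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_threshold_property(self, dl, dr):
        diff, side = vt.classify_dominance(dl, dr)
        diff2, side2 = vt.classify_dominance(dr, dl)
        assert diff == pytest.approx(diff2)
        flip = {"left": "right", "right": "left", "equal": "equal"}
        assert side2 == flip[side]
        assert (side == "equal") == (diff <= vt.DOMINANCE_THRESHOLD_MM + 1e-9)


@pytest.fixture(scope="module")
def net_and_record():
    net = vt.build_vessel_network(vt.GeometryTargets(), seed=4)
    return net, vt.network_morphometry(net).to_dict()


class TestNetworkInvariances:

    def test_rigid_motion_invariance(self, net_and_record):
        """Every index except the X-referenced bend/lean and the left/right
        labels is invariant under a rigid motion of the whole network."""
        net, rec = net_and_record
        R = Rotation.from_euler("xyz", [31, -17, 64], degrees=True).as_matrix()
        rec2 = vt.network_morphometry(transform_network(net, R, (4.2, -7.7, 1.3))).to_dict()
        for k, v in rec.items():
            if k in ("ba_bend", "ba_lean", "dominance"):
                continue
            if isinstance(v, float):
                assert rec2[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k

    def test_scale_covariance(self, net_and_record):
        net, rec = net_and_record
        s = 2.5
        rec2 = vt.network_morphometry(
            transform_network(net, None, (0, 0, 0), scale=s), spacing=0.5 * s
        ).to_dict()
        powers = {"length": 1, "diameter": 1, "bend": 1, "difference": 1,
                  "area": 2, "volume": 3, "curvature": -1, "torsion": -1,
                  "tortuosity": 0}
        for k, v in rec.items():
            if not isinstance(v, float):
                continue
            power = next(p for key, p in powers.items() if key in k)
            assert rec2[k] == pytest.approx(v * s ** power, rel=1e-9, abs=1e-12), k

    def test_reversal_invariance(self, net_and_record):
        net, _ = net_and_record
        for cl in net.vessels().values():
            a = vt.geometry_indices(vt.resample_arclength(vt.taubin_smooth(cl), 0.5))
            b = vt.geometry_indices(vt.resample_arclength(vt.taubin_smooth(cl.reversed()), 0.5))
            for f in ("length_mm", "tortuosity_pct", "curvature_index_pct",
                      "torsion_index_pct", "mean_area_mm2", "volume_mm3"):
                assert getattr(b, f) == pytest.approx(getattr(a, f), rel=1e-9, abs=1e-9), f

    def test_tortuosity_range_and_zero_iff_straight(self, net_and_record):
        net, rec = net_and_record
        for k in ("ba_tortuosity", "left_va_tortuosity", "right_va_tortuosity"):
            assert 0 <= rec[k] < 100
        straight = vt.geometry_indices(vt.resample_arclength(make_line(24.0, 49), 0.5))
        assert straight.tortuosity_pct == pytest.approx(0.0, abs=1e-12)
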