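"""DNA builder: step transforms, duplex construction, enhancer composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invertasome.dna import (StepParams, BasePairFrame, GENERIC_BDNA,
                             step_transform, params_from_transform,
                             build_duplex, analyze_duplex,
                             compose_enhancer_params, axis_curve,
                             EnhancerLayout, read_step_params,
                             write_step_params)
from invertasome.structure import RigidTransform


bend_angle = st.one_of(st.just(0.0), st.floats(0.001, 60),
                       st.floats(-60, -0.001))

valid_steps = st.builds(
    StepParams,
    shift=st.floats(-2, 2), slide=st.floats(-2, 2),
    rise=st.floats(2.0, 5.0),
    tilt=bend_angle, roll=bend_angle,
    twist=st.floats(-170, 170),
)


class TestStepTransform:
    def test_pure_rise_is_translation(self):
        t = step_transform(StepParams(rise=3.4, twist=0.0))
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, [0, 0, 3.4])

    def test_average_helical_twist(self):
        # mean protein-bound B-DNA step: 34.2 deg about the helix axis
        t = step_transform(StepParams(rise=3.4, twist=34.2))
        angle = math.degrees(math.acos((np.trace(t.rotation) - 1) / 2))
        assert angle == pytest.approx(34.2, abs=1e-9)
        assert np.allclose(t.translation, [0, 0, 3.4])

    def test_generic_step_reextraction_exact(self):
        p = StepParams(shift=0.0, slide=0.5, rise=3.4, tilt=0.0, roll=5.0,
                       twist=32.0)
        q = params_from_transform(step_transform(p))
        assert np.allclose(p.as_array(), q.as_array(), atol=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(valid_steps)
    def test_parameter_roundtrip(self, p):
        q = params_from_transform(step_transform(p))
        # near-zero bends sit at the acos() precision floor; generic steps
        # round-trip far below this tolerance
        assert np.allclose(p.as_array(), q.as_array(), atol=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(rise=-1.0), dict(rise=0.0), dict(twist=185.0),
        dict(roll=95.0), dict(tilt=-95.0), dict(rise=float("nan")),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            StepParams(**bad)


class TestBuildDuplex:
    def test_straight_helix_end_to_end(self):
        m = build_duplex("A" * 11, [GENERIC_BDNA] * 10)
        d = np.linalg.norm(m.frames[-1].origin - m.frames[0].origin)
        assert d == pytest.approx(34.0, abs=1e-9)

    def test_cumulative_helical_rotation(self):
        m = build_duplex("A" * 11, [GENERIC_BDNA] * 10)
        total = sum(s.twist for s in analyze_duplex(m))
        assert total == pytest.approx(342.0, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_duplex("ACGTA", [GENERIC_BDNA] * 3)

    def test_invalid_nucleotides_rejected(self):
        with pytest.raises(ValueError):
            build_duplex("AXGT", [GENERIC_BDNA] * 3)

    def test_backbone_proxies_on_both_strands(self):
        m = build_duplex("ACGT", [GENERIC_BDNA] * 3)
        assert m.backbone.shape == (2, 4, 3)

    def test_build_is_equivariant_under_first_frame_rotation(self):
        steps = [StepParams(roll=5, slide=0.5, twist=32)] * 6
        m0 = build_duplex("A" * 7, steps)
        rot = RigidTransform.from_rotvec([1, 2, 0.5], 0.9, [3.0, -1.0, 2.0])
        first = BasePairFrame.canonical().transformed(rot)
        m1 = build_duplex("A" * 7, steps, first_frame=first)
        d0 = np.linalg.norm(axis_curve(m0)[:, None] - axis_curve(m0)[None], axis=2)
        d1 = np.linalg.norm(axis_curve(m1)[:, None] - axis_curve(m1)[None], axis=2)
        assert np.allclose(d0, d1, atol=1e-9)


class TestAnalyzeDuplex:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(valid_steps, min_size=2, max_size=8))
    def test_analyze_inverts_build(self, steps):
        m = build_duplex("A" * (len(steps) + 1), steps)
        rec = analyze_duplex(m)
        # rebuilding from the recovered parameters reproduces the frame
        # origins (the analysis contract)
        m2 = build_duplex(m.sequence, rec)
        got_ax = np.array([f.origin for f in m2.frames])
        want_ax = np.array([f.origin for f in m.frames])
        assert np.allclose(got_ax, want_ax, atol=1e-6)
        # parameters themselves match away from the +/-180 twist boundary
        for s_in, s_out in zip(steps, rec):
            if abs(s_in.twist) < 178.0:
                assert np.allclose(s_in.as_array(), s_out.as_array(),
                                   atol=1e-6)

    def test_straight_helix_has_no_roll_or_tilt(self):
        m = build_duplex("A" * 9, [GENERIC_BDNA] * 8)
        for s in analyze_duplex(m):
            assert abs(s.roll) < 1e-9 and abs(s.tilt) < 1e-9

    def test_single_bp_model_is_an_error(self):
        m = build_duplex("A", [])
        with pytest.raises(ValueError):
            analyze_duplex(m)


class TestEnhancerComposition:
    def test_default_layout_dimensions(self, spec):
        from invertasome.synthetic import make_fis_site_params
        params = compose_enhancer_params(make_fis_site_params(spec),
                                         GENERIC_BDNA, spec.layout)
        assert len(params) == 64
        m = build_duplex("A" * 65, params)
        assert len(m) == 65
        lay = spec.layout
        assert abs(lay.site2_center_index - lay.site1_center_index) == 47

    def test_straight_block_gives_collinear_axis(self):
        lay = EnhancerLayout()
        params = compose_enhancer_params([GENERIC_BDNA] * 20, GENERIC_BDNA, lay)
        ax = axis_curve(build_duplex("A" * 65, params))
        t = ax[-1] - ax[0]
        t /= np.linalg.norm(t)
        dev = (ax - ax[0]) - np.outer((ax - ax[0]) @ t, t)
        assert np.max(np.linalg.norm(dev, axis=1)) < 1e-6

    def test_bent_blocks_give_nonplanar_s_shape(self, spec):
        """The two site-bend planes are rotated by the intervening twist."""
        from invertasome.synthetic import make_fis_site_params
        params = compose_enhancer_params(make_fis_site_params(spec),
                                         GENERIC_BDNA, spec.layout)
        m = build_duplex("A" * 65, params)
        ax = axis_curve(m)
        lay = spec.layout

        def bend_normal(c):
            v = ax[c - 7] + ax[c + 7] - 2 * ax[c]
            return v / np.linalg.norm(v)

        n1 = bend_normal(lay.site1_center_index)
        n2 = bend_normal(lay.site2_center_index)
        # expected dihedral: the twist accumulated between the two centers,
        # modulo full turns
        twist_between = sum(s.twist for s in params[
            lay.site1_center_index:lay.site2_center_index])
        expected = abs(((twist_between + 180) % 360) - 180)
        got = math.degrees(math.acos(np.clip(abs(n1 @ n2), 0, 1)))
        expected_acute = min(expected, 180 - expected)
        assert got == pytest.approx(expected_acute, abs=8.0)
        # and the shape is genuinely non-planar / S-like, not a U
        assert n1 @ n2 < 0.5

    def test_block_size_mismatch_rejected(self, spec):
        with pytest.raises(ValueError):
            compose_enhancer_params([GENERIC_BDNA] * 5, GENERIC_BDNA,
                                    spec.layout)

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError):
            EnhancerLayout(total_bp=30, center_separation_bp=10,
                           site1_center_index=10, site2_center_index=20)


class TestAxisCurve:
    def test_one_point_per_bp(self):
        m = build_duplex("A" * 12, [GENERIC_BDNA] * 11)
        assert axis_curve(m).shape == (12, 3)

    def test_planar_bend_tangent_angle(self):
        # total roll of 90 deg spread over 9 steps, no twist: planar arc
        steps = [StepParams(rise=3.4, twist=0.0, roll=10.0)] * 9
        ax = axis_curve(build_duplex("A" * 10, steps))
        t_in = ax[1] - ax[0]
        t_out = ax[-1] - ax[-2]
        angle = math.degrees(math.acos(
            np.clip(t_in @ t_out / np.linalg.norm(t_in) / np.linalg.norm(t_out),
                    -1, 1)))
        assert angle == pytest.approx(90.0 * 8 / 9, abs=1.0)


class TestStepTableIO:
    def test_roundtrip(self):
        steps = [StepParams(shift=0.1, slide=-0.2, rise=3.3, tilt=1.5,
                            roll=-4.0, twist=33.0)] * 3
        back = read_step_params(write_step_params(steps))
        assert np.allclose([s.as_array() for s in back],
                           [s.as_array() for s in steps], atol=1e-4)

    def test_header_required(self):
        with pytest.raises(ValueError):
            read_step_params("0 0 3.4 0 0 34.2\n")
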