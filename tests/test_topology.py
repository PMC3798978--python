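"""Writhe, linking number, node counting, knot determinants."""

import numpy as np
import pytest

from invertasome.topology import (ClosedCurve, NODE_PROJECTION, count_nodes,
                                  knot_determinant, linking_number,
                                  read_curve, reduced_crossing_number, writhe,
                                  write_curve)


def circle(n=64, radius=1.0, center=(0, 0, 0), plane="xy"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c = np.asarray(center, dtype=float)
    if plane == "xy":
        pts = np.stack([radius * np.cos(t), radius * np.sin(t), 0 * t], 1)
    else:
        pts = np.stack([radius * np.cos(t), 0 * t, radius * np.sin(t)], 1)
    return ClosedCurve(pts + c)


def torus_knot(p, q, n=160):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ClosedCurve(np.stack([(2 + np.cos(q * t)) * np.cos(p * t),
                                 (2 + np.cos(q * t)) * np.sin(p * t),
                                 np.sin(q * t)], 1))


def figure_eight(n=200):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ClosedCurve(np.stack([(2 + np.cos(2 * t)) * np.cos(3 * t),
                                 (2 + np.cos(2 * t)) * np.sin(3 * t),
                                 np.sin(4 * t)], 1))


def solenoid(n):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ClosedCurve(np.stack([(3 + 0.5 * np.cos(8 * t)) * np.cos(t),
                                 (3 + 0.5 * np.cos(8 * t)) * np.sin(t),
                                 0.5 * np.sin(8 * t)], 1))


class TestWrithe:
    def test_planar_circle_zero(self):
        assert writhe(circle()) == pytest.approx(0.0, abs=1e-3)

    def test_solenoid_converges_under_refinement(self):
        coarse = writhe(solenoid(256))
        fine = writhe(solenoid(2560))
        assert coarse == pytest.approx(fine, abs=2e-2)

    def test_mirror_negates_writhe(self):
        c = solenoid(256)
        assert writhe(c.mirrored()) == pytest.approx(-writhe(c), abs=1e-9)

    def test_self_intersecting_rejected(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [2, 1, 0], [1, 1, 0],
                        [1, -1, 0], [0, -1, 0.0]])
        with pytest.raises(ValueError):
            writhe(ClosedCurve(pts))


class TestLinkingNumber:
    def test_far_separated_circles_unlinked(self):
        assert linking_number(circle(), circle(center=(10, 0, 0))) == 0

    def test_hopf_link(self):
        a = circle()
        b = circle(center=(1, 0, 0), plane="xz")
        assert abs(linking_number(a, b)) == 1

    def test_orientation_flips_sign(self):
        a = circle()
        b = circle(center=(1, 0, 0), plane="xz")
        b_rev = ClosedCurve(b.points[::-1].copy())
        assert linking_number(a, b) == -linking_number(a, b_rev)

    def test_touching_curves_rejected(self):
        a = circle()
        with pytest.raises(ValueError):
            linking_number(a, ClosedCurve(a.points + [1e-12, 0, 0]))

    @staticmethod
    def _projection_crossing_sum(a, b, direction):
        """Independent oracle: signed crossings between two projected
        closed polylines, right-hand convention, implemented directly."""
        d = direction / np.linalg.norm(direction)
        helper = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
        e1 = np.cross(d, helper); e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        total = 0
        pa = np.stack([a.points @ e1, a.points @ e2], 1)
        pb = np.stack([b.points @ e1, b.points @ e2], 1)
        za, zb = a.points @ d, b.points @ d
        na, nb = len(pa), len(pb)
        for i in range(na):
            p1, p2 = pa[i], pa[(i + 1) % na]
            for j in range(nb):
                q1, q2 = pb[j], pb[(j + 1) % nb]
                d1, d2 = p2 - p1, q2 - q1
                denom = d1[0] * d2[1] - d1[1] * d2[0]
                if abs(denom) < 1e-12:
                    continue
                r = q1 - p1
                s_par = (r[0] * d2[1] - r[1] * d2[0]) / denom
                t_par = (r[0] * d1[1] - r[1] * d1[0]) / denom
                if not (0 < s_par < 1 and 0 < t_par < 1):
                    continue
                zi = za[i] + s_par * (za[(i + 1) % na] - za[i])
                zj = zb[j] + t_par * (zb[(j + 1) % nb] - zb[j])
                ta = a.points[(i + 1) % na] - a.points[i]
                tb = b.points[(j + 1) % nb] - b.points[j]
                sign = int(np.sign(np.cross(ta, tb) @ d))
                # over/under-aware right-hand rule
                total += sign if zi > zj else -sign
        return total

    @pytest.mark.parametrize("seed", range(6))
    def test_gauss_integral_matches_projection_count(self, seed):
        """Half the signed inter-curve crossing sum over a generic
        projection equals the Gauss linking integral."""
        rng = np.random.default_rng(seed)
        a = circle(48)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        b = ClosedCurve(circle(48, plane="xz").points @ R.T
                        + rng.normal(0, 0.8, 3))
        try:
            lk = linking_number(a, b)
        except ValueError:
            pytest.skip("curves touch for this draw")
        signed = self._projection_crossing_sum(a, b, rng.normal(size=3))
        assert signed == 2 * lk


class TestCountNodes:
    def test_substrate_has_two_negative_hix_enhancer_nodes(self, substrate):
        nodes = count_nodes(substrate.curve, NODE_PROJECTION,
                            "hix", "enhancer")
        assert [s for _, s in nodes] == [-1, -1]

    def test_mirrored_substrate_has_positive_nodes(self, substrate):
        # view the mirrored geometry along the mirrored direction so the
        # diagram is the exact mirror image
        proj = NODE_PROJECTION * np.array([1.0, 1.0, -1.0])
        nodes = count_nodes(substrate.curve.mirrored(), proj,
                            "hix", "enhancer")
        assert [s for _, s in nodes] == [1, 1]

    def test_parallel_segments_do_not_cross(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [10, 1, 5], [0, 1, 5.0]])
        curve = ClosedCurve(pts, ("a", "link", "b", "link"))
        assert count_nodes(curve, np.array([0.05, 0.1, 1.0]), "a", "b") == []

    def test_node_signed_sum_stable_over_projections(self, substrate):
        rng = np.random.default_rng(2024)
        sums = set()
        for _ in range(5):
            d = NODE_PROJECTION + rng.normal(0, 0.2, 3)
            nodes = count_nodes(substrate.curve, d, "hix", "enhancer")
            sums.add(sum(s for _, s in nodes))
        assert sums == {-2}


class TestKnotDeterminant:
    def test_unknot(self):
        assert knot_determinant(circle()) == 1

    def test_trefoil(self):
        assert knot_determinant(torus_knot(2, 3)) == 3

    def test_figure_eight(self):
        assert knot_determinant(figure_eight()) == 5

    def test_invariant_over_projection_directions(self):
        rng = np.random.default_rng(5)
        tre = torus_knot(2, 3)
        dets = {knot_determinant(tre, rng.normal(size=3)) for _ in range(5)}
        assert dets == {3}

    def test_determinant_unchanged_by_mirror(self):
        tre = torus_knot(2, 3)
        assert knot_determinant(tre.mirrored()) == 3

    def test_reduced_crossing_number_of_standard_knots(self):
        assert reduced_crossing_number(circle()) == 0
        assert reduced_crossing_number(torus_knot(2, 3)) == 3


class TestCurveIO:
    def test_roundtrip_with_labels(self, substrate):
        text = write_curve(substrate.curve)
        back = read_curve(text)
        assert np.allclose(back.points, substrate.curve.points, atol=1e-3)
        assert back.labels == substrate.curve.labels

    def test_malformed_line_rejected(self):
        with pytest.raises(ValueError):
            read_curve("1.0 2.0\n")


class TestClosedCurveInvariants:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ClosedCurve(np.zeros((3, 3)) + np.arange(3)[:, None])

    def test_repeated_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        with pytest.raises(ValueError):
            ClosedCurve(pts)
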