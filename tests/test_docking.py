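"""Superposition, site docking, invertasome assembly, refinement."""

import numpy as np
import pytest

from invertasome.docking import (AssemblyConfig, AssemblyError, PoseConstraint,
                                 assemble_invertasome, constraint_score,
                                 dock_on_site, refine_by_constraints,
                                 superpose)
from invertasome.structure import RigidTransform
from invertasome.synthetic import (FixtureSpec, make_fis_dimer,
                                   make_toy_components)
from invertasome.dna import GENERIC_BDNA, build_duplex


def _cloud(rng, n=8):
    return rng.normal(0, 10, (n, 3))


class TestSuperpose:
    def test_identity_on_itself(self):
        pts = _cloud(np.random.default_rng(0))
        t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_recovers_generating_transform(self, seed):
        rng = np.random.default_rng(seed)
        pts = _cloud(rng)
        gen = RigidTransform.from_rotvec(rng.normal(size=3),
                                         rng.uniform(-np.pi, np.pi),
                                         rng.normal(0, 5, 3))
        t, rmsd = superpose(pts, gen.apply(pts))
        assert rmsd < 1e-6
        assert np.allclose(t.rotation, gen.rotation, atol=1e-6)
        assert np.allclose(t.translation, gen.translation, atol=1e-6)

    def test_mirror_image_stays_proper(self):
        rng = np.random.default_rng(7)
        pts = _cloud(rng)
        mirror = pts * np.array([1.0, 1.0, -1.0])
        t, rmsd = superpose(pts, mirror)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.5

    def test_rmsd_invariant_under_common_motion(self):
        rng = np.random.default_rng(11)
        a, b = _cloud(rng), _cloud(rng)
        _, rmsd0 = superpose(a, b)
        common = RigidTransform.from_rotvec([0.3, 1.0, -0.2], 1.1, [4, 5, 6])
        _, rmsd1 = superpose(common.apply(a), common.apply(b))
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_degenerate_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            superpose(line, line + [0, 1, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestDockOnSite:
    def setup_method(self):
        self.spec = FixtureSpec()
        self.fis = make_fis_dimer(self.spec)
        self.dna = build_duplex("A" * 21, [GENERIC_BDNA] * 20)

    def test_interface_lands_near_backbone(self):
        import math
        prox = np.array([8.9 * math.cos(math.radians(77)),
                         8.9 * math.sin(math.radians(77)), 0.0])
        pose = {
            "A.98": (8, prox + np.array([0, 0, 2.0])),
            "B.98": (12, -prox + np.array([0, 0, -2.0])),
            "X.900": (10, np.array([0.0, 11.0, 0.0])),
        }
        placed = dock_on_site(self.fis, self.dna, (0, 20), pose)
        bb = self.dna.backbone.reshape(-1, 3)
        for ch in "AB":
            d = np.min(np.linalg.norm(bb - placed.landmark_xyz(f"{ch}.98"),
                                      axis=1))
            assert d <= 6.0

    def test_site_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dock_on_site(self.fis, self.dna, (10, 30),
                         {"A.98": (0, np.zeros(3)),
                          "B.98": (1, np.zeros(3)),
                          "X.900": (2, np.zeros(3))})

    def test_insufficient_correspondences_rejected(self):
        with pytest.raises(ValueError):
            dock_on_site(self.fis, self.dna, (0, 20),
                         {"A.98": (0, np.zeros(3)), "B.98": (5, np.zeros(3))})


class TestAssembly:
    def test_arm_engages_only_proximal_subunits(self, cleaved):
        cut = cleaved.contact_cutoff
        for fis, sub in (("fis1", "hin_hix1L"), ("fis2", "hin_hix2R")):
            d = min(np.linalg.norm(cleaved.landmark_xyz(f"{fis}.{ch}.21")
                                   - cleaved.landmark_xyz(f"{sub}.H.155"))
                    for ch in "AB")
            assert d <= cut
        for fis in ("fis1", "fis2"):
            for sub in ("hin_hix1R", "hin_hix2L"):
                d = min(np.linalg.norm(cleaved.landmark_xyz(f"{fis}.{ch}.21")
                                       - cleaved.landmark_xyz(f"{sub}.H.155"))
                        for ch in "AB")
                assert d > cut

    def test_exactly_two_subunits_satisfy_arm_proximity(self, cleaved):
        cut = cleaved.contact_cutoff
        engaged = []
        for sub in ("hin_hix1L", "hin_hix1R", "hin_hix2L", "hin_hix2R"):
            d = min(np.linalg.norm(cleaved.landmark_xyz(f"{fis}.{ch}.21")
                                   - cleaved.landmark_xyz(f"{sub}.H.155"))
                    for fis in ("fis1", "fis2") for ch in "AB")
            if d <= cut:
                engaged.append(sub)
        assert sorted(engaged) == ["hin_hix1L", "hin_hix2R"]

    def test_helix_b_distance_ordered_by_state(self, cleaved, pre_cleaved,
                                               dimer_docked):
        def d47(asm):
            bb = asm.duplexes["enhancer"].backbone.reshape(-1, 3)
            p = asm.landmark_xyz("hin_hix1L.H.47")
            return float(np.min(np.linalg.norm(bb - p, axis=1)))

        assert d47(cleaved) <= d47(pre_cleaved) <= d47(dimer_docked)
        assert d47(cleaved) < 6.0
        assert d47(dimer_docked) > 15.0

    def test_no_steric_overlap(self, cleaved):
        assert cleaved.min_intercomponent_distance() > 0.5

    def test_missing_subunit_rejected(self, spec, enhancer):
        comp = make_toy_components(spec, "cleaved")
        del comp["hin_hix2L"]
        with pytest.raises(ValueError):
            AssemblyConfig(enhancer=enhancer, layout=spec.layout,
                           components=comp)

    def test_hix_paths_cross_enhancer_with_two_negative_nodes(self, cleaved):
        from invertasome.topology import count_nodes
        zhat = cleaved.provenance["synapse_frame"].rotation[:, 2]
        rng = np.random.default_rng(42)
        signs = [s for _, s in count_nodes(cleaved.dna_path(),
                                           zhat + rng.normal(0, 0.1, 3),
                                           "hix", "enhancer")]
        assert signs == [-1, -1]


class TestRefinement:
    def _constraints(self):
        return [PoseConstraint("fis1.A.21", "hin_hix1L.H.155", 6.0),
                PoseConstraint("fis2.A.21", "hin_hix2R.H.155", 6.0)]

    def test_zero_violation_input_returned_unchanged(self, cleaved):
        refined, score = refine_by_constraints(cleaved, self._constraints(),
                                               seed=5)
        assert score == 0.0
        assert refined is cleaved or constraint_score(
            refined, self._constraints()) == 0.0

    def test_perturbed_assembly_improves(self, cleaved):
        from dataclasses import replace
        comp = cleaved.components["fis1"]
        moved = comp.with_coords(comp.coords + np.array([12.0, 5.0, 0.0]))
        perturbed = replace(cleaved,
                            components={**cleaved.components, "fis1": moved})
        cons = self._constraints()
        s0 = constraint_score(perturbed, cons)
        assert s0 > 0
        refined, s1 = refine_by_constraints(perturbed, cons, seed=3,
                                            iterations=400)
        assert s1 < s0

    def test_same_seed_is_deterministic(self, cleaved):
        from dataclasses import replace
        comp = cleaved.components["fis1"]
        moved = comp.with_coords(comp.coords + np.array([4.0, 1.0, 0.0]))
        perturbed = replace(cleaved,
                            components={**cleaved.components, "fis1": moved})
        cons = self._constraints()
        a1, s1 = refine_by_constraints(perturbed, cons, seed=9, iterations=150)
        a2, s2 = refine_by_constraints(perturbed, cons, seed=9, iterations=150)
        assert s1 == s2
        assert np.array_equal(a1.components["fis1"].coords,
                              a2.components["fis1"].coords)
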