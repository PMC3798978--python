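"""Synthetic fixtures: bent Fis-site step parameters, toy protein components,
and branched substrate geometries.

Every stage of the pipeline is testable without external structure files:
this module generates (a) step-parameter blocks whose built duplex bends by
a configured angle, standing in for the Fis-DNA co-crystal values; (b)
residue-level point models of Fis dimers and Hin subunits carrying the
landmark residues used by the crosslinking and footprinting constraints;
and (c) the branched supercoiled substrate curve consumed by the topology
module.  All generators are pure functions of a :class:`FixtureSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dna import (EnhancerLayout, StepParams, GENERIC_BDNA, build_duplex,
                  axis_curve, compose_enhancer_params)
from .structure import AtomRecord, AtomSet
from .topology import (SubstrateGeometry, SynapseParams, build_invertasome_curve)

__all__ = [
    "FixtureSpec",
    "FIS_LANDMARK_RESIDUES",
    "HIN_LANDMARK_RESIDUES",
    "make_fis_site_params",
    "make_toy_components",
    "make_substrate_geometry",
]

#: Fis residues represented in the toy dimer (per chain): beta-hairpin arm
#: tip (16-22), R71 near the DNA-binding region, N98 in the
#: helix-turn-helix DNA contact region.
FIS_LANDMARK_RESIDUES = (16, 19, 20, 21, 22, 71, 98)

#: Hin residues represented per subunit: helix-B basic patch and FeBABE
#: coupling site (47/48/51/54), catalytic-domain sites (28, 101, 107), and
#: the DBD helix-1 region contacting Fis (146-160).
HIN_LANDMARK_RESIDUES = (28, 47, 48, 51, 54, 101, 107, 146, 147, 150, 151,
                         154, 155, 158, 160)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study system.

    ``fis_bend`` is the per-site DNA bend in degrees (a configured default,
    not a measured value); ``loop_bp`` the enhancer-to-hix spacing (99 bp
    native, 696/868 bp for long-spacer substrates); ``toy_scale`` a global
    scale for the coarse-grained protein domains.
    """

    seed: int = 0
    fis_bend: float = 65.0
    layout: EnhancerLayout = field(default_factory=EnhancerLayout)
    loop_bp: int = 99
    plasmid_bp: int = 2300
    toy_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fis_bend < 0 or self.fis_bend >= 180.0:
            raise ValueError("per-site bend must be in [0, 180) degrees")
        if self.loop_bp <= 0 or self.plasmid_bp <= 0 or self.toy_scale <= 0:
            raise ValueError("geometric parameters must be positive")


# ---------------------------------------------------------------------------
# Bent Fis-site step parameters
# ---------------------------------------------------------------------------

def _bent_block(amplitude: float, n_steps: int, twist: float, rise: float
                ) -> list[StepParams]:
    """Planar-bend block: roll/tilt rotate with the accumulated helical
    twist so all per-step bends add in one global plane."""
    steps = []
    for i in range(n_steps):
        psi = math.radians(twist) * (i + 0.5)
        steps.append(StepParams(rise=rise, twist=twist,
                                roll=amplitude * math.cos(psi),
                                tilt=amplitude * math.sin(psi)))
    return steps


def _tangent_deflection(steps: list[StepParams]) -> float:
    """Entry/exit tangent angle (degrees) of the duplex built from steps."""
    model = build_duplex("A" * (len(steps) + 1), steps)
    t_in = model.frames[0].axes[:, 2]
    t_out = model.frames[-1].axes[:, 2]
    return math.degrees(math.acos(float(np.clip(t_in @ t_out, -1, 1))))


def make_fis_site_params(spec: FixtureSpec) -> list[StepParams]:
    """Step parameters of one 21-bp Fis binding site (20 steps).

    The block bends the helix axis by ``spec.fis_bend`` degrees overall,
    distributed as phased roll/tilt across the block so the bend is planar;
    the amplitude is calibrated against the built duplex so the measured
    entry/exit tangent deflection matches the requested bend.
    """
    n_steps = spec.layout.site_block_bp - 1
    if spec.fis_bend == 0:
        return [GENERIC_BDNA] * n_steps
    twist, rise = GENERIC_BDNA.twist, GENERIC_BDNA.rise
    amp = spec.fis_bend / n_steps
    for _ in range(25):  # fixed-point calibration of the per-step amplitude
        got = _tangent_deflection(_bent_block(amp, n_steps, twist, rise))
        if abs(got - spec.fis_bend) < 0.02:
            break
        amp *= spec.fis_bend / max(got, 1e-9)
    return _bent_block(amp, n_steps, twist, rise)


def make_enhancer_model(spec: FixtureSpec):
    """Convenience: the composed 65-bp enhancer duplex for this spec."""
    params = compose_enhancer_params(make_fis_site_params(spec), GENERIC_BDNA,
                                     spec.layout)
    seq = _default_enhancer_sequence(spec.layout)
    return build_duplex(seq, params)


def _default_enhancer_sequence(layout: EnhancerLayout) -> str:
    """Synthetic stand-in enhancer sequence: A/T-rich central segment
    (the helix-B contact region) between G/C-containing Fis cores."""
    seq = ["T"] * layout.total_bp
    (a0, a1), (b0, b1) = layout.core_intervals()
    core = "GCTCAAATATTGATC"  # synthetic 15-mer, not the natural sequence
    for k in range(layout.core_bp):
        seq[a0 + k] = core[k]
        seq[b0 + k] = core[k]
    mid = "ATTTATTTAATGATAATTTATTAACTTAATTTATT"
    for i, pos in enumerate(range(a1 + 1, b0)):
        seq[pos] = mid[i % len(mid)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Toy protein components
# ---------------------------------------------------------------------------

def _atoms_from_points(points: dict, chain_points: dict | None = None
                       ) -> AtomSet:
    """Build an AtomSet from {(chain, resseq): xyz}; one CA-like point per
    residue, landmark index keyed 'chain.resseq'."""
    records = []
    landmarks = {}
    for (chain, resseq), xyz in sorted(points.items()):
        landmarks[f"{chain}.{resseq}"] = len(records)
        records.append(AtomRecord(chain=chain, resseq=resseq, resname="GLY",
                                  name="CA", element="C",
                                  xyz=tuple(float(v) for v in xyz)))
    return AtomSet(tuple(records), landmarks)


def make_fis_dimer(spec: FixtureSpec) -> AtomSet:
    """Coarse-grained Fis dimer in its local frame.

    Local convention: origin at the DNA-contact center, +z toward the
    synapse (the beta-hairpin arms), x along the binding-site axis.  Chains
    A and B are related by the dimer twofold (x -> -x, y -> -y).
    """
    s = spec.toy_scale
    half = {
        16: (-1.5, 0.5, 17.0),
        19: (-1.6, 1.5, 20.5),
        20: (-1.2, 0.8, 22.5),
        21: (-0.8, 0.0, 24.5),
        22: (-0.9, -1.2, 22.0),
        71: (-4.0, 1.0, 4.0),
        98: (-6.0, 2.5, 1.0),
    }
    pts = {}
    for resi, (x, y, z) in half.items():
        pts[("A", resi)] = (s * x, s * y, s * z)
        pts[("B", resi)] = (-s * x, -s * y, s * z)
    # three anchor pseudo-residues defining the docking frame
    pts[("X", 900)] = (0.0, 0.0, 0.0)
    pts[("X", 901)] = (5.0 * s, 0.0, 0.0)
    pts[("X", 902)] = (0.0, 5.0 * s, 0.0)
    return _atoms_from_points(pts)


#: state-dependent position of the Hin catalytic domain relative to the DBD
#: (local y is the helix-B face; more negative y = closer to the enhancer
#: when the subunit is docked with y pointing at the enhancer)
_CATALYTIC_OFFSET = {"cleaved": 0.0, "pre_cleaved": 8.0, "dimer_docked": 20.0}


def make_hin_subunit(spec: FixtureSpec, state: str = "cleaved") -> AtomSet:
    """Coarse-grained Hin subunit in its local frame.

    Local convention: DBD (helix-1 region, residues 146-160) around the
    origin where the subunit grips its hix half-site; the catalytic domain
    sits at +z (toward the tetramer core); local -y is the helix-B face
    that clamps onto enhancer DNA in the cleaved state.  ``state`` moves
    the catalytic domain along +y away from the enhancer for the
    pre-cleaved and dimer-docked conformations.
    """
    if state not in _CATALYTIC_OFFSET:
        raise ValueError(f"unknown assembly state {state!r}")
    s = spec.toy_scale
    dy = _CATALYTIC_OFFSET[state]
    dbd = {
        146: (-2.4, 1.2, 2.4),
        147: (-2.3, 1.8, 2.2),
        150: (-4.0, 1.0, 1.0),
        151: (-5.2, 0.5, 0.5),
        154: (-6.8, -0.5, 0.0),
        155: (-7.8, -1.0, -0.5),
        158: (-9.2, -2.0, -1.0),
        160: (-10.0, 0.0, 1.0),
    }
    catalytic = {
        28: (4.0, 3.0, 49.0),
        47: (-5.0, -8.0, 55.0),
        48: (-3.2, -8.2, 55.5),
        51: (-1.0, -8.5, 56.0),
        54: (1.5, -8.5, 56.5),
        101: (0.0, 2.0, 62.0),
        107: (0.5, 4.0, 59.0),
    }
    pts = {}
    for resi, (x, y, z) in dbd.items():
        pts[("H", resi)] = (s * x, s * y, s * z)
    for resi, (x, y, z) in catalytic.items():
        pts[("H", resi)] = (s * x, s * (y + dy), s * z)
    pts[("X", 900)] = (0.0, 0.0, 0.0)
    pts[("X", 901)] = (5.0 * s, 0.0, 0.0)
    pts[("X", 902)] = (0.0, 5.0 * s, 0.0)
    return _atoms_from_points(pts)


def make_toy_components(spec: FixtureSpec, state: str = "cleaved"
                        ) -> dict[str, AtomSet]:
    """All protein units for one assembly state: two Fis dimers and four
    Hin subunits named by the half-site they occupy."""
    fis = make_fis_dimer(spec)
    hin = make_hin_subunit(spec, state)
    return {
        "fis1": fis,
        "fis2": fis,
        "hin_hix1L": hin,
        "hin_hix1R": hin,
        "hin_hix2L": hin,
        "hin_hix2R": hin,
    }


# ---------------------------------------------------------------------------
# Branched substrate geometry
# ---------------------------------------------------------------------------

def make_substrate_geometry(spec: FixtureSpec) -> SubstrateGeometry:
    """Branched supercoiled substrate with the native (-2)-noded geometry.

    The curve is the clasped-head invertasome model; bp lengths of the
    labeled segments are bookkeeping that sums to the plasmid size.
    """
    if spec.loop_bp >= spec.plasmid_bp:
        raise ValueError("loop length exceeds plasmid size")
    params = SynapseParams(loop_bp=spec.loop_bp, plasmid_bp=spec.plasmid_bp)
    curve = build_invertasome_curve(params, 0)
    labs = np.array(curve.labels)
    h1 = np.nonzero(labs == "hix1")[0]
    h2 = np.nonzero(labs == "hix2")[0]
    hix_bp, enh_bp = 26, 65
    inv_rest = spec.plasmid_bp - 2 * hix_bp - enh_bp - spec.loop_bp
    vector_bp = inv_rest // 2
    segment_bp = {
        "hix1": hix_bp, "hix2": hix_bp, "enhancer": enh_bp,
        "loop99": spec.loop_bp,
        "loop_inv": inv_rest - vector_bp,
        "vector": vector_bp,
    }
    assert sum(segment_bp.values()) == spec.plasmid_bp
    return SubstrateGeometry(curve, int(h1[len(h1) // 2]),
                             int(h2[len(h2) // 2]), params,
                             segment_bp=segment_bp)
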