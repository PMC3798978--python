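"""Placement of protein units on DNA models and invertasome assembly.

The assembly follows the architecture established by site-directed
crosslinking and footprinting: two Fis dimers on the bent enhancer ends
with their beta-hairpin arms raised, the Hin tetramer core above the
central enhancer segment, the two hix duplexes running through the core,
and -- in the DNA-cleaved state -- the helix-B basic patches of the two
enhancer-proximal subunits (those on half-sites hix1L and hix2R) clamped
onto the DNA between the Fis core sites.  Only those two subunits place
their DBD helix-1 region within arm's reach of a Fis beta-hairpin tip,
reproducing the observed crosslinking asymmetry.

Poses are constructed deterministically from the enhancer geometry; a
seeded rigid-body refinement (:func:`refine_by_constraints`) stands in for
interactive manual docking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dna import DuplexModel, EnhancerLayout, StepParams, GENERIC_BDNA, \
    build_duplex, axis_curve, BasePairFrame
from .structure import AtomSet, RigidTransform, apply_transform, min_distance
from .topology import ClosedCurve, count_nodes

__all__ = [
    "AssemblyConfig",
    "Assembly",
    "ASSEMBLY_STATES",
    "superpose",
    "dock_on_site",
    "assemble_invertasome",
    "refine_by_constraints",
    "PoseConstraint",
]

ASSEMBLY_STATES = ("dimer_docked", "pre_cleaved", "cleaved")

#: landmark-to-landmark contact cutoff (A); absorbs the side-chain reach of
#: the residue-level representation
DEFAULT_CONTACT_CUTOFF = 6.0

HIX_BP = 26
_HALF_CENTER = {"L": 6, "R": 19}  # bp index of each half-site center


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(moving: np.ndarray, target: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns the proper rigid transform minimizing the RMSD and the RMSD
    itself.  Mirror solutions are excluded (determinant forced to +1), so a
    chiral point set superposed on its mirror image keeps a nonzero RMSD.
    """
    A = np.asarray(moving, dtype=float).reshape(-1, 3)
    B = np.asarray(target, dtype=float).reshape(-1, 3)
    if A.shape != B.shape:
        raise ValueError("point lists must have equal length")
    if len(A) < 3:
        raise ValueError("need at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    s = np.linalg.svd(A0.T @ B0)
    if s[1][1] < 1e-9 * max(1.0, s[1][0]):
        raise ValueError("degenerate (collinear) point configuration")
    U, _, Vt = s
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A0 @ R.T - B0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def dock_on_site(protein: AtomSet, dna: DuplexModel,
                 site: tuple[int, int],
                 reference_pose: dict[str, tuple[int, np.ndarray]]) -> AtomSet:
    """Place a protein so its landmarks superpose onto site base-pair frames.

    ``site`` is a 0-based inclusive bp interval; ``reference_pose`` maps
    landmark labels to ``(bp_offset_from_site_start, offset_xyz)`` where the
    offset is expressed in that base pair's frame.
    """
    lo, hi = site
    if lo < 0 or hi >= len(dna) or lo > hi:
        raise ValueError(f"site {site} outside duplex of {len(dna)} bp")
    if len(reference_pose) < 3:
        raise ValueError("reference pose needs at least 3 correspondences")
    moving, target = [], []
    for label, (bp_off, off) in reference_pose.items():
        bp = lo + bp_off
        if bp < lo or bp > hi:
            raise ValueError(f"pose bp offset {bp_off} outside the site")
        frame = dna.frames[bp]
        moving.append(protein.landmark_xyz(label))
        target.append(frame.origin + frame.axes @ np.asarray(off, dtype=float))
    t, _ = superpose(np.array(moving), np.array(target))
    return apply_transform(protein, t)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyConfig:
    """Inputs of the invertasome assembly.

    ``components`` must contain two Fis dimers (``fis1``, ``fis2``) and four
    Hin subunits named by half-site (``hin_hix1L`` ... ``hin_hix2R``), each
    in its local reference frame; the half-site naming is part of the
    configuration, not inferred from sequence.
    """

    enhancer: DuplexModel
    layout: EnhancerLayout
    components: dict[str, AtomSet]
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    loop_bp: int = 99
    hix_steps: tuple[StepParams, ...] = tuple([GENERIC_BDNA] * (HIX_BP - 1))
    half_site_labels: tuple[str, str, str, str] = ("hix1L", "hix1R",
                                                  "hix2L", "hix2R")

    def __post_init__(self) -> None:
        fis = [k for k in self.components if k.startswith("fis")]
        hin = [k for k in self.components if k.startswith("hin_")]
        if len(fis) != 2 or len(hin) != 4:
            raise ValueError("assembly needs exactly 2 Fis dimers and 4 Hin subunits")
        if sorted(self.half_site_labels) != ["hix1L", "hix1R", "hix2L", "hix2R"]:
            raise ValueError("half-site labels must be a permutation of the four names")
        if self.loop_bp <= 0:
            raise ValueError("loop length must be positive")


@dataclass(frozen=True)
class Assembly:
    """Positioned invertasome model in one assembly state."""

    state: str
    components: dict[str, AtomSet]
    duplexes: dict[str, DuplexModel]
    layout: EnhancerLayout
    contact_cutoff: float
    provenance: dict[str, RigidTransform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in ASSEMBLY_STATES:
            raise ValueError(f"unknown assembly state {self.state!r}")

    def landmark_xyz(self, label: str) -> np.ndarray:
        """Resolve ``component.chain.resseq`` or ``component.resseq``."""
        parts = label.split(".")
        comp = self.components.get(parts[0])
        if comp is None:
            raise KeyError(f"unknown component {parts[0]!r}")
        if len(parts) == 3:
            return comp.landmark_xyz(f"{parts[1]}.{parts[2]}")
        if len(parts) == 2:
            hits = [k for k in comp.landmarks if k.endswith(f".{parts[1]}")
                    and not k.startswith("X.")]
            if not hits:
                raise KeyError(f"no landmark residue {parts[1]} in {parts[0]}")
            if len(hits) > 1:
                raise KeyError(f"ambiguous landmark {label!r}: {hits}")
            return comp.landmark_xyz(hits[0])
        raise KeyError(f"bad landmark label {label!r}")

    def min_intercomponent_distance(self) -> float:
        names = sorted(self.components)
        best = np.inf
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                best = min(best, min_distance(self.components[a],
                                              self.components[b]))
        return float(best)

    def dna_path(self) -> ClosedCurve:
        """Labeled closed curve through the assembly's DNA axes, following
        plasmid connectivity (hix1, invertible loop, hix2, vector, enhancer,
        small loop), for node counting."""
        e = axis_curve(self.duplexes["enhancer"])
        h1 = axis_curve(self.duplexes["hix1"])
        h2 = axis_curve(self.duplexes["hix2"])
        up = np.array([0.0, 0.0, 1.0])
        # generous linkers well clear of the complex
        span = float(np.linalg.norm(e[-1] - e[0])) + 60.0

        def linker(p, q, via):
            # first/last legs stay short so crossings happen on linker-labeled
            # segments only where intended
            return [0.88 * p + 0.12 * q + 0.3 * via,
                    0.5 * (p + q) + via,
                    0.12 * p + 0.88 * q + 0.3 * via]

        pts, labs = [], []

        def add(block, lab):
            for p in block:
                pts.append(p)
                labs.append(lab)

        add(h1, "hix1")
        add(linker(h1[-1], h2[0], 90.0 * self._zhat()), "loop_inv")
        add(h2, "hix2")
        add(linker(h2[-1], e[-1], -span * self._zhat()), "vector")
        add(e[::-1], "enhancer")  # traversed toward the hix1-proximal end
        add(linker(e[0], h1[0], 30.0 * self._yhat()), "loop99")
        return ClosedCurve(np.array(pts), tuple(labs))

    def _zhat(self) -> np.ndarray:
        t = self.provenance.get("synapse_frame")
        return t.rotation[:, 2] if t is not None else np.array([0.0, 0.0, 1.0])

    def _yhat(self) -> np.ndarray:
        t = self.provenance.get("synapse_frame")
        return t.rotation[:, 1] if t is not None else np.array([0.0, 1.0, 0.0])


class AssemblyError(ValueError):
    """Raised when constraints cannot be satisfied; lists the violations."""

    def __init__(self, violations: list[str]):
        super().__init__("assembly constraints violated: " + "; ".join(violations))
        self.violations = violations


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _frame_from(z: np.ndarray, x_hint: np.ndarray) -> np.ndarray:
    z = _unit(z)
    x = x_hint - (x_hint @ z) * z
    x = _unit(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _place(component: AtomSet, anchors: tuple[str, str, str],
           origin: np.ndarray, axes: np.ndarray) -> tuple[AtomSet, RigidTransform]:
    """Superpose the component's three anchor pseudo-residues onto the frame
    (origin, origin + 5x, origin + 5y)."""
    moving = np.array([component.landmark_xyz(a) for a in anchors])
    target = np.array([origin,
                       origin + 5.0 * axes[:, 0],
                       origin + 5.0 * axes[:, 1]])
    t, _ = superpose(moving, target)
    return apply_transform(component, t), t


# geometric parameters of the constructed assembly (Angstroms)
_FIS_BODY_OFFSET = 11.0      # Fis body center above the site axis
_ARM_TIP_LOCAL = 24.5        # arm tip height in the Fis local frame
_ARM_TO_DBD = 4.2            # Fis arm tip to Hin-155 design distance
_DBD_GRIP = 8.5              # arm tip to half-site-center distance
_SYNAPSE_HEIGHT = 18.0       # synapse core above the enhancer center


def assemble_invertasome(cfg: AssemblyConfig, state: str) -> Assembly:
    """Construct the invertasome model for one assembly state.

    The pose is derived from the enhancer geometry: Fis dimers sit on the
    concave face of their bent sites with arms toward the synapse; the hix
    duplexes run from the enhancer-proximal half-sites (hix1L, hix2R, next
    to the Fis arms) through the tetramer core above the central enhancer
    segment; Hin subunits are superposed onto their half-sites with
    catalytic domains toward the core, the helix-B face of the two
    enhancer-proximal subunits toward the enhancer.
    """
    if state not in ASSEMBLY_STATES:
        raise ValueError(f"unknown assembly state {state!r}")
    lay = cfg.layout
    enh = cfg.enhancer
    ax = axis_curve(enh)
    c1, c2 = lay.site1_center_index, lay.site2_center_index
    mid_bp = (c1 + c2) // 2

    def concave_normal(c):
        chord = ax[c - 7] + ax[c + 7] - 2.0 * ax[c]
        n = np.linalg.norm(chord)
        if n < 1e-6:  # straight site: fall back to the bp frame x-axis
            return enh.frames[c].axes[:, 0]
        return chord / n

    n1, n2 = concave_normal(c1), concave_normal(c2)
    # the S-shaped enhancer is roughly planar with the two bends in-plane;
    # the tetramer sits along the plane normal, above the central segment
    centered = ax - ax.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    z_s = Vt[2]
    chord = ax[c2] - ax[c1]
    if np.cross(chord, n1) @ z_s < 0:  # deterministic handedness choice
        z_s = -z_s
    x_s = _unit(chord - (chord @ z_s) * z_s)
    y_s = np.cross(z_s, x_s)
    S = ax[mid_bp] + _SYNAPSE_HEIGHT * z_s

    placed: dict[str, AtomSet] = {}
    prov: dict[str, RigidTransform] = {
        "synapse_frame": RigidTransform(np.column_stack([x_s, y_s, z_s]), S)}

    anchors = ("X.900", "X.901", "X.902")
    # --- Fis dimers on the concave faces of their sites ---
    tips = {}
    for name, c, n in (("fis1", c1, n1), ("fis2", c2, n2)):
        origin = ax[c] + _FIS_BODY_OFFSET * n
        tangent = ax[c + 1] - ax[c - 1]
        axes = _frame_from(n, tangent)  # local +z = arm direction
        placed[name], prov[name] = _place(cfg.components[name], anchors,
                                          origin, axes)
        tips[name] = origin + (_FIS_BODY_OFFSET + _ARM_TIP_LOCAL) * 0.0 + \
            axes @ np.array([-0.8, 0.0, _ARM_TIP_LOCAL])

    # --- hix duplexes through the synapse core ---
    prox_anchor = {"hix1": tips["fis1"] + _DBD_GRIP * z_s,
                   "hix2": tips["fis2"] + _DBD_GRIP * z_s}
    hix_axes = {}
    duplexes = {"enhancer": enh}
    for hname, lane in (("hix1", +1.0), ("hix2", -1.0)):
        # ducts run steeply across the S so each crosses the enhancer once
        through = S + lane * (-20.0 * x_s - 40.0 * y_s)
        A = prox_anchor[hname]
        d = _unit(through - A)
        # enhancer-proximal half-site: hix1L (bp 6) and hix2R (bp 19)
        prox_bp = _HALF_CENTER["L"] if hname == "hix1" else _HALF_CENTER["R"]
        sign = 1.0 if hname == "hix1" else -1.0  # traversal L->R for both
        bp0 = A - sign * d * 3.4 * prox_bp
        frames = []
        zax = sign * d
        xax = _unit(z_s - (z_s @ zax) * zax)
        M = _frame_from(zax, xax)
        for k in range(HIX_BP):
            frames.append(BasePairFrame(bp0 + sign * d * 3.4 * k, M))
        bb = np.stack([[f.origin + f.axes @ np.array(
            [8.9 * math.cos(s * math.radians(77.0)),
             8.9 * math.sin(s * math.radians(77.0)), 0.0])
            for f in frames] for s in (1.0, -1.0)], axis=0)
        duplexes[hname] = DuplexModel("A" * HIX_BP, tuple(frames), bb)
        hix_axes[hname] = (bp0, sign * d)

    # --- Hin subunits ---
    proximal = {"hin_hix1L", "hin_hix2R"}
    for sub in ("hin_hix1L", "hin_hix1R", "hin_hix2L", "hin_hix2R"):
        hname = "hix1" if "hix1" in sub else "hix2"
        half = sub[-1]
        bp0, dvec = hix_axes[hname]
        P = bp0 + dvec * 3.4 * _HALF_CENTER[half]
        z_l = _unit(S - P) if float(np.linalg.norm(S - P)) > 1e-6 else z_s
        y_l = z_s if sub in proximal else -z_s
        y_l = _unit(y_l - (y_l @ z_l) * z_l)
        x_l = np.cross(y_l, z_l)
        M = np.column_stack([x_l, y_l, z_l])
        comp = cfg.components[sub]
        if sub in proximal:
            # place so landmark 155 sits at arm-tip + design distance
            fname = "fis1" if sub == "hin_hix1L" else "fis2"
            target155 = tips[fname] + _ARM_TO_DBD * z_s
            local155 = comp.landmark_xyz("H.155")
            origin = target155 - M @ local155
        else:
            origin = P + 7.0 * _unit(P - S + 1e-9 * z_s) + 2.0 * z_s
        placed[sub], prov[sub] = _place(comp, anchors, origin, M)

    asm = Assembly(state=state, components=placed, duplexes=duplexes,
                   layout=lay, contact_cutoff=cfg.contact_cutoff,
                   provenance=prov)
    violations = _check_assembly(asm)
    if violations:
        raise AssemblyError(violations)
    return asm


def _check_assembly(asm: Assembly) -> list[str]:
    """Hard contracts every accepted assembly must satisfy."""
    out = []
    cut = asm.contact_cutoff
    d = asm.min_intercomponent_distance()
    if d <= 0.5:
        out.append(f"steric overlap: min inter-component distance {d:.2f} A")
    for fis, sub in (("fis1", "hin_hix1L"), ("fis2", "hin_hix2R")):
        arm = min(np.linalg.norm(asm.landmark_xyz(f"{fis}.A.21")
                                 - asm.landmark_xyz(f"{sub}.H.155")),
                  np.linalg.norm(asm.landmark_xyz(f"{fis}.B.21")
                                 - asm.landmark_xyz(f"{sub}.H.155")))
        if arm > cut:
            out.append(f"{fis} arm not engaging {sub} ({arm:.1f} A > {cut} A)")
    for fis, sub in (("fis1", "hin_hix1R"), ("fis1", "hin_hix2L"),
                     ("fis2", "hin_hix1R"), ("fis2", "hin_hix2L")):
        arm = min(np.linalg.norm(asm.landmark_xyz(f"{fis}.A.21")
                                 - asm.landmark_xyz(f"{sub}.H.155")),
                  np.linalg.norm(asm.landmark_xyz(f"{fis}.B.21")
                                 - asm.landmark_xyz(f"{sub}.H.155")))
        if arm <= cut:
            out.append(f"{fis} arm within cutoff of rotating subunit {sub}")
    # Fis dimers must sit on their sites in every state
    enh = asm.duplexes["enhancer"]
    bb = enh.backbone.reshape(-1, 3)
    for fis in ("fis1", "fis2"):
        dmin = min(float(np.min(np.linalg.norm(
            bb - asm.landmark_xyz(f"{fis}.{ch}.98"), axis=1)))
            for ch in "AB")
        if dmin > cut:
            out.append(f"{fis} DNA-binding landmark {dmin:.1f} A off its site")
    return out


# ---------------------------------------------------------------------------
# Constraint-guided refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseConstraint:
    """One distance restraint between two assembly landmarks."""

    landmark_a: str
    landmark_b: str
    limit: float
    kind: str = "max"  # "max": violated when farther; "min": when closer

    def violation(self, asm: Assembly) -> float:
        d = float(np.linalg.norm(asm.landmark_xyz(self.landmark_a)
                                 - asm.landmark_xyz(self.landmark_b)))
        if self.kind == "max":
            return max(0.0, d - self.limit)
        return max(0.0, self.limit - d)


def constraint_score(asm: Assembly, constraints: list[PoseConstraint]) -> float:
    return float(sum(c.violation(asm) for c in constraints))


def refine_by_constraints(asm: Assembly, constraints: list[PoseConstraint],
                          step_rot: float = 0.05, step_trans: float = 1.0,
                          iterations: int = 200, seed: int = 0
                          ) -> tuple[Assembly, float]:
    """Seeded rigid-body hill climbing over protein component poses.

    Each iteration perturbs one component by a small random rotation and
    translation and keeps the move only if the total constraint violation
    decreases.  The returned score never exceeds the input score, and
    identical seeds give identical trajectories.
    """
    rng = np.random.default_rng(seed)
    names = sorted(asm.components)
    best = asm
    best_score = constraint_score(asm, constraints)
    for _ in range(iterations):
        if best_score == 0.0:
            break
        name = names[rng.integers(len(names))]
        axis = rng.normal(size=3)
        angle = rng.normal(0.0, step_rot)
        shift = rng.normal(0.0, step_trans, size=3)
        comp = best.components[name]
        center = comp.coords.mean(axis=0)
        t = RigidTransform.from_rotvec(axis, angle)
        moved = comp.with_coords((comp.coords - center) @ t.rotation.T
                                 + center + shift)
        trial = replace(best, components={**best.components, name: moved})
        score = constraint_score(trial, constraints)
        if score < best_score:
            best, best_score = trial, score
    return best, best_score
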