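"""Duplex DNA models built from base-pair step parameters.

A duplex is represented at base-pair resolution: one orthonormal reference
frame per base pair plus one pseudo-phosphate backbone proxy per strand per
position.  Successive frames are related by the six rigid-body step
parameters (shift, slide, rise / tilt, roll, twist) composed with the
standard mid-step-triad scheme: the frame-to-frame rotation is the ZYZ
factorization ``Rz(omega/2 - phi) @ Ry(Gamma) @ Rz(omega/2 + phi)`` with
``Gamma = sqrt(roll^2 + tilt^2)`` and ``phi = atan2(tilt, roll)``, and the
translation is expressed in the mid-step frame.  This composition is exactly
invertible, so building a duplex from parameters and re-deriving parameters
from the frames round-trips to numerical precision.

The recombinational enhancer model is assembled here as well: a 65-bp duplex
with two Fis-site step-parameter blocks whose centers sit 47 bp apart, and
mean protein-bound B-DNA parameters (twist 34.2 deg, rise 3.4 A) everywhere
else.  Fis bending at the two sites, phased by the intervening helical
twist, produces the S-shaped enhancer trajectory.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import RigidTransform

__all__ = [
    "StepParams",
    "BasePairFrame",
    "DuplexModel",
    "EnhancerLayout",
    "GENERIC_BDNA",
    "step_transform",
    "build_duplex",
    "analyze_duplex",
    "compose_enhancer_params",
    "axis_curve",
    "read_step_params",
    "write_step_params",
    "read_fasta_sequence",
]

#: Backbone proxy placement in the base-pair frame: one pseudo-phosphate per
#: strand at cylindrical radius 8.9 A, phased +/-77 deg from the bp x-axis.
BACKBONE_RADIUS = 8.9
BACKBONE_PHASE_DEG = 77.0

_VALID_NT = set("ACGTUacgtu")


@dataclass(frozen=True)
class StepParams:
    """Six rigid-body parameters of one dinucleotide step (A / degrees)."""

    shift: float = 0.0
    slide: float = 0.0
    rise: float = 3.4
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 34.2

    def __post_init__(self) -> None:
        vals = (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite step parameter")
        if self.rise <= 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if abs(self.twist) >= 180.0:
            raise ValueError(f"|twist| must be < 180 deg, got {self.twist}")
        if abs(self.roll) >= 90.0 or abs(self.tilt) >= 90.0:
            raise ValueError("|roll| and |tilt| must be < 90 deg")

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist], dtype=float)


#: Mean protein-bound B-DNA step (helical twist 34.2 deg, rise 3.4 A).
GENERIC_BDNA = StepParams()


@dataclass(frozen=True)
class BasePairFrame:
    """Base-pair reference frame: origin plus right-handed orthonormal axes.

    ``axes`` columns are the frame x (into the major groove), y, and z
    (direction of helix advance) unit vectors in global coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame axes are left-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)

    @classmethod
    def canonical(cls) -> "BasePairFrame":
        return cls(np.zeros(3), np.eye(3))

    def transformed(self, t: RigidTransform) -> "BasePairFrame":
        return BasePairFrame(t.apply(self.origin), t.rotation @ self.axes)


@dataclass(frozen=True)
class DuplexModel:
    """A duplex DNA model: sequence, per-bp frames, per-strand backbone proxies."""

    sequence: str
    frames: tuple[BasePairFrame, ...]
    backbone: np.ndarray = field(repr=False)  # (2, N, 3): strand 0 = top

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.sequence):
            raise ValueError("one frame per base pair required")
        bb = np.asarray(self.backbone, dtype=float)
        if bb.shape != (2, len(self.sequence), 3):
            raise ValueError("backbone proxies must be shaped (2, N, 3)")
        object.__setattr__(self, "backbone", bb)

    def __len__(self) -> int:
        return len(self.sequence)

    def transformed(self, t: RigidTransform) -> "DuplexModel":
        frames = tuple(f.transformed(t) for f in self.frames)
        bb = t.apply(self.backbone.reshape(-1, 3)).reshape(self.backbone.shape)
        return DuplexModel(self.sequence, frames, bb)


def _rz(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def step_transform(step: StepParams) -> RigidTransform:
    """Rigid transform carrying base-pair frame ``i`` onto frame ``i+1``.

    The rotation is the mid-step ZYZ composition; the (shift, slide, rise)
    displacement is expressed in the mid-step triad, i.e. the frame rotated
    halfway between the two base pairs.
    """
    if not isinstance(step, StepParams):
        step = StepParams(*step)
    omega = math.radians(step.twist)
    rho = math.radians(step.roll)
    tau = math.radians(step.tilt)
    gamma = math.hypot(rho, tau)
    phi = math.atan2(tau, rho) if gamma > 0 else 0.0
    rotation = _rz(omega / 2 - phi) @ _ry(gamma) @ _rz(omega / 2 + phi)
    mid = _rz(omega / 2 - phi) @ _ry(gamma / 2) @ _rz(phi)
    translation = mid @ np.array([step.shift, step.slide, step.rise])
    return RigidTransform(rotation, translation)


def params_from_transform(t: RigidTransform) -> StepParams:
    """Invert :func:`step_transform`: recover the six parameters from a transform."""
    A = t.rotation
    cos_gamma = float(np.clip(A[2, 2], -1.0, 1.0))
    gamma = math.acos(cos_gamma)
    # below ~1e-7 rad the off-diagonal elements are dominated by matrix
    # roundoff and the ZYZ split is ill-conditioned; treat as an unbent step
    if gamma < 2e-7:
        gamma = 0.0
        phi = 0.0
        omega = math.atan2(A[1, 0], A[0, 0])
    else:
        a = math.atan2(A[1, 2], A[0, 2])
        b = math.atan2(A[2, 1], -A[2, 0])
        omega = a + b
        phi = (b - a) / 2.0
    # (omega, phi) -> (omega -+ 2*pi, phi + pi) leaves the rotation unchanged;
    # use it to wrap twist into (-pi, pi]
    if omega > math.pi:
        omega -= 2 * math.pi
        phi += math.pi
    elif omega <= -math.pi:
        omega += 2 * math.pi
        phi += math.pi
    # float noise can land exactly on the +/-180 boundary; clamp inside it
    limit = math.pi * (1.0 - 1e-14)
    omega = max(-limit, min(limit, omega))
    rho = gamma * math.cos(phi)
    tau = gamma * math.sin(phi)
    mid = _rz(omega / 2 - phi) @ _ry(gamma / 2) @ _rz(phi)
    disp = mid.T @ t.translation
    return StepParams(shift=float(disp[0]), slide=float(disp[1]), rise=float(disp[2]),
                      tilt=math.degrees(tau), roll=math.degrees(rho),
                      twist=math.degrees(omega))


def _backbone_pair(frame: BasePairFrame) -> np.ndarray:
    phase = math.radians(BACKBONE_PHASE_DEG)
    out = np.empty((2, 3))
    for k, sign in enumerate((1.0, -1.0)):
        local = np.array([BACKBONE_RADIUS * math.cos(sign * phase),
                          BACKBONE_RADIUS * math.sin(sign * phase), 0.0])
        out[k] = frame.origin + frame.axes @ local
    return out


def build_duplex(sequence: str, steps: list[StepParams],
                 first_frame: BasePairFrame | None = None) -> DuplexModel:
    """Build a duplex by sequential composition of step transforms.

    The first base pair sits at ``first_frame`` (canonical frame at the
    origin by default); each subsequent frame is the previous frame carried
    through that step's rigid transform, expressed in global coordinates.
    """
    bad = set(sequence) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    if len(steps) != len(sequence) - 1:
        raise ValueError(
            f"need len(sequence)-1 steps, got {len(steps)} for {len(sequence)} nt")
    frame = first_frame if first_frame is not None else BasePairFrame.canonical()
    frames = [frame]
    for step in steps:
        local = step_transform(step)
        # local transform acts in the current frame; push to global coordinates
        origin = frame.origin + frame.axes @ local.translation
        axes = frame.axes @ local.rotation
        frame = BasePairFrame(origin, axes)
        frames.append(frame)
    backbone = np.stack([_backbone_pair(f) for f in frames], axis=1)
    return DuplexModel(sequence.upper(), tuple(frames), backbone)


def analyze_duplex(model: DuplexModel) -> list[StepParams]:
    """Recover the step-parameter table from a built duplex (inverse of build)."""
    if len(model.frames) < 2:
        raise ValueError("duplex analysis needs at least 2 base-pair frames")
    out: list[StepParams] = []
    for f0, f1 in zip(model.frames[:-1], model.frames[1:]):
        rot = f0.axes.T @ f1.axes
        trans = f0.axes.T @ (f1.origin - f0.origin)
        out.append(params_from_transform(RigidTransform(rot, trans)))
    return out


def axis_curve(model: DuplexModel) -> np.ndarray:
    """Helical-axis polyline: one 3D point per base pair (the frame origins)."""
    return np.array([f.origin for f in model.frames], dtype=float)


# ---------------------------------------------------------------------------
# Enhancer layout and composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnhancerLayout:
    """Geometry of the 65-bp two-Fis-site recombinational enhancer.

    Indices are 0-based internally; file interfaces report 1-based
    coordinates.  The 15-bp Fis binding cores must lie fully inside the
    element; the wider 21-bp step-parameter blocks taken from the Fis-DNA
    co-crystal are allowed to be clipped at the enhancer ends, because two
    21-bp blocks with centers 47 bp apart necessarily overhang a 65-bp
    element by a few steps on each side.
    """

    total_bp: int = 65
    site_block_bp: int = 21
    core_bp: int = 15
    center_separation_bp: int = 47
    site1_center_index: int = 9
    site2_center_index: int = 56

    def __post_init__(self) -> None:
        if min(self.total_bp, self.site_block_bp, self.core_bp,
               self.center_separation_bp) <= 0:
            raise ValueError("layout dimensions must be positive")
        if self.site_block_bp % 2 == 0 or self.core_bp % 2 == 0:
            raise ValueError("site block and core lengths must be odd (centered)")
        if abs(self.site2_center_index - self.site1_center_index) != \
                self.center_separation_bp:
            raise ValueError("site centers inconsistent with center_separation_bp")
        ch = self.core_bp // 2
        for c in (self.site1_center_index, self.site2_center_index):
            if c - ch < 0 or c + ch > self.total_bp - 1:
                raise ValueError("15-bp Fis core extends past the enhancer ends")
        r1, r2 = self.block_step_ranges()
        if r1[1] > r2[0]:
            raise ValueError("Fis site blocks overlap")

    def block_step_ranges(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Clipped half-open step-index ranges covered by the two site blocks."""
        half = self.site_block_bp // 2
        out = []
        for c in sorted((self.site1_center_index, self.site2_center_index)):
            lo = max(0, c - half)
            hi = min(self.total_bp - 1, c + half)  # steps lo .. hi-1
            out.append((lo, hi))
        return out[0], out[1]

    def core_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """0-based inclusive bp intervals of the two 15-bp Fis cores."""
        ch = self.core_bp // 2
        c1, c2 = sorted((self.site1_center_index, self.site2_center_index))
        return (c1 - ch, c1 + ch), (c2 - ch, c2 + ch)


def compose_enhancer_params(fis_block: list[StepParams], generic: StepParams,
                            layout: EnhancerLayout) -> list[StepParams]:
    """Compile the full enhancer step table: Fis blocks at both sites, mean
    B-DNA parameters for the intervening and flanking DNA."""
    n_block_steps = layout.site_block_bp - 1
    if len(fis_block) != n_block_steps:
        raise ValueError(
            f"Fis block must have {n_block_steps} steps, got {len(fis_block)}")
    params = [generic] * (layout.total_bp - 1)
    half = layout.site_block_bp // 2
    for center in (layout.site1_center_index, layout.site2_center_index):
        start = center - half
        for j, step in enumerate(fis_block):
            idx = start + j
            if 0 <= idx < layout.total_bp - 1:
                params[idx] = step
    return params


# ---------------------------------------------------------------------------
# Text interfaces
# ---------------------------------------------------------------------------

_STEP_COLUMNS = ["shift", "slide", "rise", "tilt", "roll", "twist"]


def read_step_params(text: str) -> list[StepParams]:
    """Read a step-parameter table (whitespace/comma delimited, header required).

    Columns: shift slide rise tilt roll twist, in Angstroms and degrees.
    """
    df = pd.read_csv(io.StringIO(text), sep=r"[,\s]+", engine="python")
    cols = [c.lower() for c in df.columns]
    if cols[: len(_STEP_COLUMNS)] != _STEP_COLUMNS:
        raise ValueError(
            f"step table header must be '{' '.join(_STEP_COLUMNS)}', got {list(df.columns)}")
    df.columns = cols
    return [StepParams(**{c: float(row[c]) for c in _STEP_COLUMNS})
            for _, row in df.iterrows()]


def write_step_params(steps: list[StepParams]) -> str:
    lines = ["\t".join(_STEP_COLUMNS)]
    for s in steps:
        lines.append("\t".join(f"{v:.4f}" for v in s.as_array()))
    return "\n".join(lines) + "\n"


def read_fasta_sequence(text: str) -> str:
    """First sequence of a FASTA document."""
    from Bio import SeqIO

    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        return str(rec.seq)
    raise ValueError("no FASTA records found")
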