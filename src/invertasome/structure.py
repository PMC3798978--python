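"""Labeled coordinate sets, rigid-body transforms, and PDB-format I/O.

The modeling pipeline moves coarse-grained protein units (Fis dimers, Hin
subunits) and duplex DNA models around as rigid bodies.  Everything here is
deliberately small: an :class:`AtomSet` is a flat table of
(chain, residue, atom) records with coordinates plus a *landmark index* that
maps semantic labels such as ``"Fis1.A.21"`` (the tip of a Fis beta-hairpin
arm) to individual records, and a :class:`RigidTransform` is a proper
rotation plus translation.

The PDB dialect is strict fixed-column v3.3 ``ATOM``/``HETATM`` records:
malformed lines raise :class:`PDBFormatError` naming the offending line, and
alternate-location indicators other than blank are rejected.  Landmark labels
travel in a two-column sidecar file (``chain:resseq<TAB>label``) so real
crystallographic templates and toy fixtures share one constraint vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RigidTransform",
    "AtomRecord",
    "AtomSet",
    "PDBFormatError",
    "read_structure",
    "write_structure",
    "read_landmark_map",
    "write_landmark_map",
]


class PDBFormatError(ValueError):
    """Raised for malformed fixed-column PDB input (message names the line)."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion ``x -> R @ x + t`` in Angstroms.

    ``rotation`` must be orthonormal with determinant +1; reflections are
    rejected because a physical docking move can never mirror a protein.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite entries in rigid transform")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) is not a rigid motion")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, axis: np.ndarray, angle_rad: float,
                    translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``angle_rad`` about ``axis`` (Rodrigues), plus translation."""
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("zero rotation axis")
        a = a / n
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))


# ---------------------------------------------------------------------------
# Atom sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    chain: str
    resseq: int
    resname: str
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class AtomSet:
    """Labeled 3D point set for one protein unit or DNA fragment.

    ``landmarks`` maps semantic labels to record indices; the same label
    vocabulary is used by the docking and constraint modules regardless of
    whether the coordinates came from a toy generator or a real template.
    """

    records: tuple[AtomRecord, ...]
    landmarks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.records:
            key = (r.chain, r.resseq, r.name)
            if key in seen:
                raise ValueError(f"duplicate atom record {key}")
            seen.add(key)
            if not all(np.isfinite(v) for v in r.xyz):
                raise ValueError(f"non-finite coordinates for {key}")
        for label, idx in self.landmarks.items():
            if not 0 <= idx < len(self.records):
                raise ValueError(f"landmark {label!r} points outside the record table")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.xyz for r in self.records], dtype=float).reshape(-1, 3)

    def landmark_xyz(self, label: str) -> np.ndarray:
        if label not in self.landmarks:
            raise KeyError(f"unknown landmark {label!r}")
        return np.asarray(self.records[self.landmarks[label]].xyz, dtype=float)

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        coords = np.asarray(coords, dtype=float).reshape(len(self.records), 3)
        recs = tuple(replace(r, xyz=tuple(float(v) for v in c))
                     for r, c in zip(self.records, coords))
        return AtomSet(recs, dict(self.landmarks))

    def find(self, chain: str, resseq: int) -> list[AtomRecord]:
        return [r for r in self.records if r.chain == chain and r.resseq == resseq]


def apply_transform(a: AtomSet, t: RigidTransform) -> AtomSet:
    """Map every coordinate through ``t``; labels and record order untouched."""
    return a.with_coords(t.apply(a.coords))


def min_distance(a: AtomSet, b: AtomSet) -> float:
    """Minimum inter-set point distance (steric-clash screen)."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(b.coords).query(a.coords, k=1)
    return float(np.min(d))


# ---------------------------------------------------------------------------
# PDB I/O (strict fixed-column v3.3 dialect)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBFormatError(
            f"line {lineno}: ATOM record shorter than 54 columns (truncated coordinates)")
    altloc = line[16]
    if altloc not in (" ", ""):
        raise PDBFormatError(f"line {lineno}: alternate location {altloc!r} not supported")
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: malformed fixed-width field ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = (name[:1] or "X").upper()
    return AtomRecord(chain=chain, resseq=resseq, resname=resname or "UNK",
                      name=name or "X", element=element, xyz=(x, y, z))


def read_structure(text: str, landmarks: dict[str, str] | None = None) -> AtomSet:
    """Parse PDB-format text into an :class:`AtomSet`.

    Parameters
    ----------
    text:
        PDB file content.  Only ``ATOM``/``HETATM`` records are read.
    landmarks:
        Optional mapping ``"chain:resseq" -> label`` (the sidecar vocabulary);
        each entry is attached to the first atom of the matching residue.
    """
    records: list[AtomRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            records.append(_parse_atom_line(line, lineno))
    if not records:
        raise PDBFormatError("no ATOM/HETATM records found")
    index: dict[str, int] = {}
    if landmarks:
        by_residue: dict[tuple[str, int], int] = {}
        for i, r in enumerate(records):
            by_residue.setdefault((r.chain, r.resseq), i)
        for key, label in landmarks.items():
            chain, resseq = key.split(":")
            loc = by_residue.get((chain, int(resseq)))
            if loc is None:
                raise KeyError(f"landmark {label!r}: residue {key} absent from structure")
            index[label] = loc
    return AtomSet(tuple(records), index)


def write_structure(a: AtomSet) -> str:
    """Serialize to fixed-column PDB text (coordinates at 3 decimals)."""
    lines = []
    for i, r in enumerate(a.records, start=1):
        name = r.name if len(r.name) == 4 else f" {r.name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4.4s} {r.resname:<3.3s} {r.chain:1.1s}{r.resseq:4d}    "
            f"{r.xyz[0]:8.3f}{r.xyz[1]:8.3f}{r.xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {r.element:>2.2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_landmark_map(text: str) -> dict[str, str]:
    """Parse the two-column sidecar (``chain:resseq<whitespace>label``)."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or ":" not in parts[0]:
            raise ValueError(f"landmark map line {lineno}: expected 'chain:resseq label'")
        mapping[parts[0]] = parts[1]
    return mapping


def write_landmark_map(mapping: dict[str, str]) -> str:
    return "".join(f"{key}\t{label}\n" for key, label in mapping.items())
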