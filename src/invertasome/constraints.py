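"""Crosslink compatibility, tethered-nuclease footprints, basic-patch contacts.

Chemical crosslinkers of known spacer length report on landmark-landmark
distances in the assembled invertasome: a constraint is satisfied when the
modeled separation is within spacer + tolerance for an observed crosslink,
or beyond it for an observed non-crosslink.  The packaged spacer set covers
SIA (1.5 A), AMAS (4.4), GMBS (7.3), BMOE (8.0), EMCS (9.4), SMPH (14.2)
and KMUS (16.3 A).

FeBABE footprinting is modeled purely geometrically: an iron chelate on an
engineered cysteine cleaves backbone positions within tether length (12 A
to the Fe) plus a hydroxyl-radical diffusion radius; predicted scission
sites are the backbone proxies within that reach, ranked by distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .docking import Assembly

__all__ = [
    "CrosslinkConstraint",
    "FeBABEReach",
    "FootprintPrediction",
    "PACKAGED_SPACERS",
    "crosslink_compatibility",
    "score_crosslink_set",
    "predict_febabe_footprint",
    "basic_patch_contacts",
    "read_crosslink_set",
    "write_crosslink_set",
    "footprint_to_bed",
    "packaged_crosslink_set",
    "DEFAULT_TOLERANCE",
]

#: crosslinker spacer lengths (A) of the packaged reagent set
PACKAGED_SPACERS = (1.5, 4.4, 7.3, 8.0, 9.4, 14.2, 16.3)

#: side-chain flexibility allowance added to the spacer length (A)
DEFAULT_TOLERANCE = 3.0


@dataclass(frozen=True)
class CrosslinkConstraint:
    """Residue pair + spacer length + observed outcome."""

    residue_a: str
    residue_b: str
    spacer: float
    observed: str  # "crosslinked" | "not_crosslinked"

    def __post_init__(self) -> None:
        if self.spacer <= 0:
            raise ValueError("spacer length must be positive")
        if self.observed not in ("crosslinked", "not_crosslinked"):
            raise ValueError(f"bad observation {self.observed!r}")


@dataclass(frozen=True)
class FeBABEReach:
    """Geometric reach of a tethered hydroxyl-radical source."""

    tether_length: float = 12.0   # cysteine S-gamma to Fe (A)
    radical_radius: float = 10.0  # hydroxyl-radical diffusion range (A)

    def __post_init__(self) -> None:
        if self.tether_length <= 0 or self.radical_radius <= 0:
            raise ValueError("reach lengths must be positive")

    @property
    def max_reach(self) -> float:
        return self.tether_length + self.radical_radius


@dataclass(frozen=True)
class FootprintPrediction:
    """One predicted scission position (1-based bp, top/bottom strand)."""

    bp: int
    strand: str
    distance: float
    rank: int


def crosslink_compatibility(a: Assembly, c: CrosslinkConstraint,
                            tolerance: float = DEFAULT_TOLERANCE
                            ) -> tuple[float, bool]:
    """Measured landmark separation and whether it matches the observation."""
    d = float(np.linalg.norm(a.landmark_xyz(c.residue_a)
                             - a.landmark_xyz(c.residue_b)))
    limit = c.spacer + tolerance
    satisfied = d <= limit if c.observed == "crosslinked" else d > limit
    return d, satisfied


def score_crosslink_set(a: Assembly, constraints: list[CrosslinkConstraint],
                        tolerance: float = DEFAULT_TOLERANCE) -> list[dict]:
    """Per-constraint report rows (distance, satisfied flag)."""
    rows = []
    for c in constraints:
        d, ok = crosslink_compatibility(a, c, tolerance)
        rows.append({"residue_a": c.residue_a, "residue_b": c.residue_b,
                     "spacer": c.spacer, "observed": c.observed,
                     "distance": round(d, 2), "satisfied": ok})
    return rows


def predict_febabe_footprint(a: Assembly, tether: str,
                             reach: FeBABEReach = FeBABEReach(),
                             duplex: str = "enhancer"
                             ) -> list[FootprintPrediction]:
    """Backbone positions within reach of the tether point, nearest first.

    Positions are reported 1-based; strand 0 of the duplex model is "top".
    """
    point = a.landmark_xyz(tether)
    model = a.duplexes[duplex]
    out = []
    for strand_idx, strand in enumerate(("top", "bottom")):
        d = np.linalg.norm(model.backbone[strand_idx] - point, axis=1)
        for bp0 in np.nonzero(d <= reach.max_reach)[0]:
            out.append((float(d[bp0]), int(bp0) + 1, strand))
    out.sort()
    return [FootprintPrediction(bp=bp, strand=strand, distance=round(dist, 2),
                                rank=i + 1)
            for i, (dist, bp, strand) in enumerate(out)]


def basic_patch_contacts(a: Assembly, subunit: str, duplex: str,
                         cutoff: float,
                         residues: tuple[int, ...] = (47, 48, 51)
                         ) -> list[tuple[int, float]]:
    """Basic helix-B residues of ``subunit`` within ``cutoff`` of any
    backbone proxy of ``duplex``, sorted by distance."""
    if subunit not in a.components:
        raise KeyError(f"unknown subunit {subunit!r}")
    bb = a.duplexes[duplex].backbone.reshape(-1, 3)
    found = []
    for resi in residues:
        p = a.landmark_xyz(f"{subunit}.H.{resi}")
        d = float(np.min(np.linalg.norm(bb - p, axis=1)))
        if d <= cutoff:
            found.append((d, resi))
    found.sort()
    return [(resi, round(d, 2)) for d, resi in found]


# ---------------------------------------------------------------------------
# Packaged constraint set (the crosslinking pattern of the cleaved complex)
# ---------------------------------------------------------------------------

def packaged_crosslink_set() -> list[CrosslinkConstraint]:
    """Constraints encoding the observed Fis-Hin crosslinking pattern.

    The Fis beta-hairpin tip (Q21C) crosslinks to the Hin DBD helix-1
    region of the enhancer-proximal subunits with short-spacer reagents,
    but never to catalytic-domain positions or to the subunits on the
    rotating half-sites.
    """
    xl = []
    for fis, sub in (("fis1.A.21", "hin_hix1L"), ("fis2.A.21", "hin_hix2R")):
        xl.append(CrosslinkConstraint(fis, f"{sub}.H.146", 8.0, "crosslinked"))
        xl.append(CrosslinkConstraint(fis, f"{sub}.H.155", 4.4, "crosslinked"))
        xl.append(CrosslinkConstraint(fis, f"{sub}.H.151", 7.3, "crosslinked"))
    # catalytic-domain positions never crosslink at 8 A
    for resi in (28, 51, 101):
        xl.append(CrosslinkConstraint("fis1.A.21", f"hin_hix1L.H.{resi}",
                                      8.0, "not_crosslinked"))
    # rotating-pair subunits never crosslink to Fis
    for sub in ("hin_hix1R", "hin_hix2L"):
        xl.append(CrosslinkConstraint("fis1.A.21", f"{sub}.H.146",
                                      8.0, "not_crosslinked"))
        xl.append(CrosslinkConstraint("fis2.A.21", f"{sub}.H.146",
                                      8.0, "not_crosslinked"))
    return xl


# ---------------------------------------------------------------------------
# Text interfaces
# ---------------------------------------------------------------------------

def read_crosslink_set(text: str) -> list[CrosslinkConstraint]:
    """Delimited text: landmarkA landmarkB spacer_A observed (header optional)."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if parts[0].lower() in ("landmarka", "residue_a"):
            continue
        if len(parts) != 4:
            raise ValueError(f"crosslink set line {lineno}: need 4 columns")
        out.append(CrosslinkConstraint(parts[0], parts[1], float(parts[2]),
                                       parts[3]))
    return out


def write_crosslink_set(constraints: list[CrosslinkConstraint]) -> str:
    lines = ["residue_a\tresidue_b\tspacer_A\tobserved"]
    for c in constraints:
        lines.append(f"{c.residue_a}\t{c.residue_b}\t{c.spacer}\t{c.observed}")
    return "\n".join(lines) + "\n"


def footprint_to_bed(preds: list[FootprintPrediction],
                     chrom: str = "enhancer") -> str:
    """BED6: 0-based half-open 1-bp intervals; score = distance in A."""
    lines = []
    for p in preds:
        strand = "+" if p.strand == "top" else "-"
        lines.append(f"{chrom}\t{p.bp - 1}\t{p.bp}\tscission_rank_{p.rank}\t"
                     f"{p.distance}\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")
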