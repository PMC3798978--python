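"""DNA topology of closed axis curves: writhe, linking, nodes, knots.

Closed duplex DNA is modeled by its axis, an embedded closed polyline
(:class:`ClosedCurve`).  Three layers of machinery live here:

* **Gauss integrals.**  Writhe and linking number are evaluated with the
  exact per-segment-pair solid-angle formula (the standard closed form for
  the Gauss double integral over two straight segments), so both converge
  as written and linking numbers round cleanly to integers.

* **Planar diagrams.**  Projecting a curve (or a pair of labeled segments)
  along a generic direction yields signed crossings; the right-handed sign
  convention is used, under which the two hix-over-enhancer crossings of a
  branch on negatively supercoiled DNA count as (-) nodes.  From the same
  diagram a Gauss code is built and the knot determinant |Delta(-1)| is
  computed via the Alexander matrix evaluated at t = -1 (at t = -1 the
  crossing relation is sign-independent: 2 x over = x under_in + x under_out),
  which cleanly separates the unknot (1), trefoil (3), figure-eight (5) and
  the rest of the twist-knot ladder.

* **Subunit rotation.**  :func:`simulate_rotation` cuts both hix sites of a
  branched substrate, sweeps one cut-end pair through n successive 180 deg
  rotations about the synapse axis (a helical interpolation of the attached
  ends), and reseals.  Parity of n decides parental vs inverted orientation;
  the linking-number change is read from the writhe change of the modeled
  axis under the rigid-twist approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClosedCurve",
    "SubstrateGeometry",
    "RotationProduct",
    "Crossing",
    "writhe",
    "linking_number",
    "count_nodes",
    "knot_determinant",
    "reduced_crossing_number",
    "simulate_rotation",
    "delta_linking",
    "read_curve",
    "write_curve",
]


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClosedCurve:
    """Embedded closed 3D polyline with optional per-segment labels.

    ``points[i]`` connects to ``points[i+1]`` and the last point closes back
    to the first.  ``labels[i]`` names the segment starting at ``points[i]``
    (e.g. ``"hix1"``, ``"enhancer"``, ``"loop"``, ``"plectoneme"``).
    """

    points: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
            raise ValueError("a closed curve needs an (N>=4, 3) point array")
        seg = np.roll(pts, -1, axis=0) - pts
        if np.any(np.linalg.norm(seg, axis=1) < 1e-9):
            raise ValueError("repeated consecutive points")
        object.__setattr__(self, "points", pts)
        if self.labels is not None:
            if len(self.labels) != len(pts):
                raise ValueError("one label per segment required")
            object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of all N closing segments."""
        return self.points, np.roll(self.points, -1, axis=0)

    def mirrored(self) -> "ClosedCurve":
        m = self.points.copy()
        m[:, 2] *= -1.0
        return ClosedCurve(m, self.labels)

    def segment_indices(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("curve has no segment labels")
        return np.nonzero(np.array(self.labels) == label)[0]

    def min_self_distance(self) -> float:
        """Minimum distance between non-adjacent segments (embeddedness check)."""
        a, b = self.segments
        n = len(a)
        best = np.inf
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                best = min(best, _segment_distance(a[i], b[i], a[j], b[j]))
        return float(best)


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between segments [p1,p2] and [q1,q2]."""
    d1, d2, r = p2 - p1, q2 - q1, p1 - q1
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    c, b = d1 @ r, d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = np.clip((b * s + f) / e, 0.0, 1.0) if e > 1e-12 else 0.0
    s = np.clip((b * t - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(p1 + s * d1 - (q1 + t * d2)))


# ---------------------------------------------------------------------------
# Gauss integrals
# ---------------------------------------------------------------------------

def _pairwise_gauss(a1, a2, b1, b2) -> np.ndarray:
    """Exact Gauss integral contribution (in units of 4*pi) for segment pairs.

    Vectorized over leading axes; the solid-angle formula of Klenin &
    Langowski (method 1a).  Inputs are the endpoints of segment A (a1->a2)
    and segment B (b1->b2).
    """
    r13 = b1 - a1
    r14 = b2 - a1
    r23 = b1 - a2
    r24 = b2 - a2

    def _unit_cross(u, v):
        c = np.cross(u, v)
        n = np.linalg.norm(c, axis=-1, keepdims=True)
        return np.divide(c, n, out=np.zeros_like(c), where=n > 1e-14)

    n1 = _unit_cross(r13, r14)
    n2 = _unit_cross(r14, r24)
    n3 = _unit_cross(r24, r23)
    n4 = _unit_cross(r23, r13)

    def _asin_dot(u, v):
        return np.arcsin(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0))

    omega = _asin_dot(n1, n2) + _asin_dot(n2, n3) + _asin_dot(n3, n4) + _asin_dot(n4, n1)
    sign = np.sign(np.sum(np.cross(b2 - b1, a2 - a1) * r13, axis=-1))
    return omega * sign / (4.0 * math.pi)


def writhe(c: ClosedCurve) -> float:
    """Writhe of an embedded closed curve (discrete Gauss double sum)."""
    if c.min_self_distance() < 1e-9:
        raise ValueError("self-intersecting curve has no well-defined writhe")
    a, b = c.segments
    n = len(a)
    ii, jj = np.triu_indices(n, k=2)
    keep = ~((ii == 0) & (jj == n - 1))
    ii, jj = ii[keep], jj[keep]
    w = _pairwise_gauss(a[ii], b[ii], a[jj], b[jj])
    return float(2.0 * np.sum(w))


def linking_number(a: ClosedCurve, b: ClosedCurve, max_residual: float = 0.1) -> int:
    """Gauss linking number of two disjoint closed curves, as an integer."""
    pa, ea = a.segments
    pb, eb = b.segments
    ii, jj = np.meshgrid(np.arange(len(pa)), np.arange(len(pb)), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    lk = float(np.sum(_pairwise_gauss(pa[ii], ea[ii], pb[jj], eb[jj])))
    nearest = min(
        _segment_distance(pa[i], ea[i], pb[j], eb[j])
        for i in range(len(pa)) for j in range(len(pb)))
    if nearest < 1e-9:
        raise ValueError("curves touch; linking number undefined")
    rounded = int(round(lk))
    if abs(lk - rounded) > max_residual:
        raise ValueError(
            f"linking integral {lk:.4f} too far from an integer "
            f"(residual {abs(lk - rounded):.3f}); refine the discretization")
    return rounded


# ---------------------------------------------------------------------------
# Planar diagrams: crossings, nodes, Gauss code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Crossing:
    """One transversal crossing in a planar projection.

    ``over``/``under`` record (segment index, parameter along segment) of
    the strand nearer to / farther from the viewer; ``sign`` follows the
    right-handed convention sign((t_over x t_under) . view).
    """

    over: tuple[int, float]
    under: tuple[int, float]
    sign: int


def _projection_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    return e1, e2, v


def _seg_cross_2d(p1, p2, q1, q2, eps=1e-12):
    """Intersection parameters (s, t) of open 2D segments, or None."""
    d1, d2 = p2 - p1, q2 - q1
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < eps:
        return None
    r = q1 - p1
    s = (r[0] * d2[1] - r[1] * d2[0]) / denom
    t = (r[0] * d1[1] - r[1] * d1[0]) / denom
    if eps < s < 1 - eps and eps < t < 1 - eps:
        return float(s), float(t)
    return None


def _diagram_crossings(points: np.ndarray, direction: np.ndarray,
                       closed: bool = True) -> list[Crossing]:
    """All self-crossings of the projected polyline, with depth and sign."""
    e1, e2, v = _projection_basis(direction)
    p2d = np.stack([points @ e1, points @ e2], axis=1)
    depth = points @ v
    n = len(points)
    last = n if closed else n - 1
    crossings: list[Crossing] = []
    for i in range(last):
        i2 = (i + 1) % n
        for j in range(i + 2, last):
            j2 = (j + 1) % n
            if closed and i == 0 and j == n - 1:
                continue
            hit = _seg_cross_2d(p2d[i], p2d[i2], p2d[j], p2d[j2])
            if hit is None:
                continue
            s, t = hit
            zi = depth[i] + s * (depth[i2] - depth[i])
            zj = depth[j] + t * (depth[j2] - depth[j])
            if abs(zi - zj) < 1e-9:
                raise ValueError("non-generic projection: segments touch in depth")
            ti = points[i2] - points[i]
            tj = points[j2] - points[j]
            if zi > zj:
                over, under = (i, s), (j, t)
                sign = int(np.sign(np.cross(ti, tj) @ v))
            else:
                over, under = (j, t), (i, s)
                sign = int(np.sign(np.cross(tj, ti) @ v))
            if sign == 0:
                raise ValueError("non-generic projection: parallel tangents at crossing")
            crossings.append(Crossing(over, under, sign))
    return crossings


_GENERIC_TRIES = 8


def _with_generic_projection(points, direction, fn):
    """Run ``fn(direction)`` retrying with perturbed directions if degenerate."""
    rng = np.random.default_rng(20211)
    d = np.asarray(direction, dtype=float)
    for attempt in range(_GENERIC_TRIES):
        try:
            return fn(d)
        except ValueError:
            d = np.asarray(direction, dtype=float) + rng.normal(0, 1e-3 * (attempt + 1), 3)
    raise ValueError("no generic projection found after perturbation retries")


def count_nodes(curve: ClosedCurve, projection: np.ndarray,
                label_a: str | None = None, label_b: str | None = None
                ) -> list[tuple[tuple[int, int], int]]:
    """Signed crossings of a labeled curve in a generic planar projection.

    If ``label_a``/``label_b`` are given, only crossings between a segment
    labeled ``label_a`` (prefix match) and one labeled ``label_b`` are
    reported.  Returns ``[((segment_i, segment_j), sign), ...]``.
    """

    def run(d):
        return _diagram_crossings(curve.points, d)

    crossings = _with_generic_projection(curve.points, projection, run)
    out = []
    for c in crossings:
        i, j = c.over[0], c.under[0]
        if label_a is not None:
            if curve.labels is None:
                raise ValueError("label filter requested but curve is unlabeled")
            la, lb = curve.labels[i], curve.labels[j]
            pair_ok = (la.startswith(label_a) and lb.startswith(label_b)) or \
                      (la.startswith(label_b) and lb.startswith(label_a))
            if not pair_ok:
                continue
        out.append(((i, j), c.sign))
    return out


# ---------------------------------------------------------------------------
# Knot determinant from the Gauss code
# ---------------------------------------------------------------------------

def _gauss_word(points: np.ndarray, direction: np.ndarray):
    """Cyclic word of crossing passages: list of (crossing id, is_over, sign),
    ordered along the curve."""
    crossings = _diagram_crossings(points, direction)
    passages = []
    for cid, c in enumerate(crossings):
        passages.append((c.over[0] + c.over[1], cid, True, c.sign))
        passages.append((c.under[0] + c.under[1], cid, False, c.sign))
    passages.sort(key=lambda p: p[0])
    return [(cid, over, sign) for _, cid, over, sign in passages]


def _reduce_word(word):
    """Reidemeister I/II reduction on the Gauss word (crossing count only)."""
    word = list(word)
    changed = True
    while changed and word:
        changed = False
        n = len(word)
        # R1: a crossing whose two passages are cyclically adjacent
        for k in range(n):
            a, b = word[k], word[(k + 1) % n]
            if a[0] == b[0]:
                word = [w for w in word if w[0] != a[0]]
                changed = True
                break
        if changed:
            continue
        # R2: two crossings adjacent in two places, one strand over both,
        # the other under both
        n = len(word)
        pairs = {}
        for k in range(n):
            a, b = word[k], word[(k + 1) % n]
            if a[0] == b[0]:
                continue
            key = frozenset((a[0], b[0]))
            pairs.setdefault(key, []).append((a, b))
        for key, occ in pairs.items():
            if len(occ) < 2:
                continue
            for x in range(len(occ)):
                for y in range(x + 1, len(occ)):
                    (a1, b1), (a2, b2) = occ[x], occ[y]
                    overs = {a1[1], b1[1], a2[1], b2[1]}
                    if a1[1] == b1[1] and a2[1] == b2[1] and len(overs) == 2:
                        drop = key
                        word = [w for w in word if w[0] not in drop]
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
    return word


def _determinant_from_word(word) -> int:
    """|Alexander polynomial at t = -1| from a Gauss word.

    Arcs run between consecutive under-passages; each crossing contributes
    the t = -1 relation  2*x_over - x_under_in - x_under_out = 0.  The
    determinant of the matrix with one row and one column deleted is the
    knot determinant.
    """
    if not word:
        return 1
    crossing_ids = sorted({cid for cid, _, _ in word})
    n = len(crossing_ids)
    # assign arcs: walk the word; an arc ends at every under-passage
    under_positions = [k for k, (_, over, _) in enumerate(word) if not over]
    if not under_positions:
        return 1
    # arc id for each position in the word
    arc_of_pos = [0] * len(word)
    arc = 0
    # start right after the first under-passage
    start = (under_positions[0] + 1) % len(word)
    k = start
    for _ in range(len(word)):
        arc_of_pos[k] = arc
        if not word[k][1]:  # under-passage ends the current arc
            arc += 1
        k = (k + 1) % len(word)
    n_arcs = arc  # equals number of under-passages = n crossings
    cid_index = {cid: i for i, cid in enumerate(crossing_ids)}
    M = np.zeros((n, n_arcs), dtype=np.int64)
    # for each crossing find over arc, incoming and outgoing under arcs
    for k, (cid, over, _) in enumerate(word):
        row = cid_index[cid]
        if over:
            M[row, arc_of_pos[k]] += 2
        else:
            incoming = arc_of_pos[k]          # arc that ends here
            outgoing = arc_of_pos[(k + 1) % len(word)]
            M[row, incoming] -= 1
            M[row, outgoing] -= 1
    if n == 1:
        return 1
    minor = M[: n - 1, : n_arcs - 1].astype(float)
    det = np.linalg.det(minor)
    return max(1, int(round(abs(det))))


def knot_determinant(c: ClosedCurve, projection: np.ndarray | None = None) -> int:
    """Knot determinant |Delta(-1)|: 1 for the unknot, 3 trefoil, 5 figure-eight."""
    direction = np.array([0.12, 0.34, 0.92]) if projection is None else projection

    def run(d):
        return _gauss_word(c.points, d)

    word = _with_generic_projection(c.points, direction, run)
    return _determinant_from_word(word)


def reduced_crossing_number(c: ClosedCurve, n_projections: int = 12,
                            seed: int = 7) -> int:
    """Minimal crossing count over random projections after R1/R2 reduction.

    An upper bound on the knot's crossing number; tight for the clean
    simulated-rotation products used here.
    """
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_projections):
        d = rng.normal(size=3)

        def run(dd):
            return _gauss_word(c.points, dd)

        try:
            word = _with_generic_projection(c.points, d, run)
        except ValueError:
            continue
        count = len(_reduce_word(word)) // 2
        best = count if best is None else min(best, count)
    if best is None:
        raise ValueError("no generic projection found")
    return best


# ---------------------------------------------------------------------------
# Substrate geometry and subunit rotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseParams:
    """Geometric parameters of the branched invertasome substrate model.

    The model is a coarse-grained axis curve built around a vertical synapse
    axis: two recombinase-bound duplex columns (the hix sites) rise through
    the cut plane, their upper halves continue via leashes to the
    invertible-domain loop (the head), and the head clasps the static
    enhancer stem at the branch base -- the two (-) nodes of a branch on
    negatively supercoiled DNA.  Subunit rotation turns everything above the
    cut plane by multiples of 180 deg about the synapse axis; the winding is
    laid down as a helical sweep in the two leashes.

    ``sense`` (rotation handedness) and ``wrap`` (handedness of the head
    clasp around the enhancer stem) are fixed by the reaction: the
    supercoil-relaxing rotation yields an unknotted first-round inversion
    and the twist-knot ladder on further rounds.
    """

    r_col: float = 10.0      # radius of the hix columns from the synapse axis (A)
    z_cut: float = 6.0       # height of the recombinase cut plane (A)
    z_top: float = 22.0      # height of the leash anchors on the head (A)
    wrap_rho: float = 6.5    # radius of the head clasp around the enhancer stem (A)
    sense: int = -1          # rotation handedness (supercoil-relaxing)
    wrap: int = -1           # clasp handedness at the branch
    n_plect: int = 3         # explicit plectonemic turns in the vector domain
    loop_bp: int = 99        # enhancer-to-hix spacer carried as bookkeeping
    plasmid_bp: int = 2300


def _cyl(r: float, az: float, z: float) -> np.ndarray:
    return np.array([r * math.cos(az), r * math.sin(az), z])


def _coil_pts(az0, az1, r0, r1, z0, z1, pph=12):
    m = max(4, int(abs(az1 - az0) / math.pi * pph) + 2)
    return [_cyl(r0 + (r1 - r0) * t, az0 + (az1 - az0) * t, z0 + (z1 - z0) * t)
            for t in np.linspace(0.0, 1.0, m + 1)[1:]]


def _line_pts(p0, p1, m):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    return [p0 + t * (p1 - p0) for t in np.linspace(0.0, 1.0, m + 1)[1:]]


def build_invertasome_curve(params: SynapseParams, n: int = 0) -> ClosedCurve:
    """Axis curve of the branched substrate after ``n`` half-turn rotations.

    ``n = 0`` is the substrate itself.  For ``n >= 1`` the rotated portion
    (everything above the cut plane) is turned by ``n * 180`` degrees about
    the synapse axis, the accumulated winding is absorbed by the two leashes
    as a helical sweep, and the ends are resealed -- in the recombinant
    configuration for odd ``n`` (the invertible domain is traversed in the
    reversed direction), parental for even ``n``.
    """
    q = params
    TH = q.sense * n * math.pi
    D = math.radians
    P: list[np.ndarray] = []
    L: list[str] = []

    def add(pts, lab):
        for p in pts:
            P.append(p)
            L.append(lab)

    # static lower half of hix1 column (az 0)
    add([_cyl(q.r_col, 0.0, 0.0)], "hix1")
    add(_line_pts(_cyl(q.r_col, 0.0, 0.0), _cyl(q.r_col, 0.0, q.z_cut), 2), "hix1")

    # ---- rotating domain (built forward; reversed for odd n) ----
    a_pts: list[np.ndarray] = []
    a_lab: list[str] = []

    def aadd(pts, lab):
        for p in pts:
            a_pts.append(p)
            a_lab.append(lab)

    # upper half of hix1 column, rotated
    aadd(_line_pts(_cyl(q.r_col, TH, q.z_cut), _cyl(q.r_col, TH, 12.0), 3), "hix1")
    # leash 1: helical sweep absorbing the rotation, up to the head anchor
    aadd(_coil_pts(TH, 0.0, q.r_col, q.r_col, 12.0, q.z_top), "hix1_flank")
    # the head: invertible-domain loop, incl. the clasp around the enhancer stem
    aadd(_line_pts(_cyl(q.r_col, 0.0, q.z_top), _cyl(30.0, 0.0, 30.0), 4), "loop_inv")
    aadd(_line_pts(_cyl(30.0, 0.0, 30.0), _cyl(33.0, D(6), -6.0), 5), "loop_inv")
    cen = _cyl(8.0, 0.0, -11.0)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    entry = cen + q.wrap_rho * (math.cos(D(-30)) * e1 + math.sin(D(-30)) * e2) \
        + np.array([0.0, 0.0, -1.5])
    aadd(_line_pts(_cyl(33.0, D(6), -6.0), entry, 4), "hix_arm")
    loop = []
    for t in np.linspace(0.0, 1.0, 14)[1:]:
        ang = D(-30) + q.wrap * 2.0 * math.pi * t
        loop.append(cen + q.wrap_rho * (math.cos(ang) * e1 + math.sin(ang) * e2)
                    + np.array([0.0, 0.0, -1.5 + 3.0 * t]))
    aadd(loop, "hix_arm")
    aadd(_line_pts(loop[-1], _cyl(34.0, D(60), -24.0), 4), "hix_arm")
    aadd(_line_pts(_cyl(34.0, D(60), -24.0), _cyl(48.0, D(120), 20.0), 5), "loop_inv")
    aadd(_line_pts(_cyl(48.0, D(120), 20.0), _cyl(q.r_col, math.pi, q.z_top), 5),
         "loop_inv")
    # leash 2 and rotated upper half of hix2
    aadd(_coil_pts(math.pi, math.pi + TH, q.r_col, q.r_col, q.z_top, 12.0),
         "hix2_flank")
    aadd(_line_pts(_cyl(q.r_col, math.pi + TH, 12.0),
                   _cyl(q.r_col, math.pi + TH, q.z_cut), 3), "hix2")

    if n % 2 == 1:  # recombinant religation: invertible domain reversed
        a_pts = a_pts[::-1]
        a_lab = a_lab[::-1]
    add(a_pts, None)
    for i, lab in enumerate(a_lab):
        L[len(L) - len(a_lab) + i] = lab

    # static lower half of hix2 column
    add(_line_pts(_cyl(q.r_col, math.pi, q.z_cut), _cyl(q.r_col, math.pi, 0.0), 2),
        "hix2")
    # vector domain: descent, explicit plectonemic supercoils, return
    add(_line_pts(_cyl(q.r_col, math.pi, 0.0), _cyl(7.0, math.pi, -20.0), 4), "vector")
    add(_line_pts(_cyl(7.0, math.pi, -20.0), np.array([-30.0, 6.0, -34.0]), 4),
        "vector")
    cx = np.array([-38.0, 0.0, -40.0])
    Rp, pitch = 6.5, 7.0
    npts = q.n_plect * 8
    for k in range(npts):
        t = k / npts
        ang = 2.0 * np.pi * q.n_plect * t
        add([cx + np.array([-t * pitch * q.n_plect,
                            Rp * math.cos(ang), Rp * math.sin(ang)])], "plect")
    add([cx + np.array([-pitch * q.n_plect - 9.0, 0.0, 0.0])], "plect")
    for k in range(1, npts + 1):
        t = 1.0 - k / npts
        ang = 2.0 * np.pi * q.n_plect * t
        add([cx + np.array([-t * pitch * q.n_plect,
                            -Rp * math.cos(ang), -Rp * math.sin(ang)])], "plect")
    add(_line_pts(cx + np.array([0.0, -Rp, 0.0]), np.array([-16.0, -8.0, -26.0]), 3),
        "vector")
    add(_line_pts(np.array([-16.0, -8.0, -26.0]), _cyl(6.0, 0.0, -20.0), 3), "vector")
    # enhancer stem: branch base rising back to the hix1 column
    add(_line_pts(_cyl(6.0, 0.0, -20.0), _cyl(q.r_col, 0.0, -2.0), 5), "enhancer")
    add(_line_pts(_cyl(q.r_col, 0.0, -2.0), _cyl(q.r_col, 0.0, 0.0), 1), "enhancer")

    keep = [0]
    for i in range(1, len(P)):
        if np.linalg.norm(P[i] - P[keep[-1]]) > 1e-6:
            keep.append(i)
    while np.linalg.norm(P[keep[-1]] - P[keep[0]]) < 1e-6:
        keep.pop()
    return ClosedCurve(np.array([P[i] for i in keep]),
                       tuple(L[i] for i in keep))


#: generic projection direction from which the branch nodes are transversal
NODE_PROJECTION = np.array([0.2, 0.94, 0.2])


@dataclass(frozen=True)
class SubstrateGeometry:
    """Branched supercoiled substrate with marked hix cut points.

    ``curve`` is the closed plasmid axis built by
    :func:`build_invertasome_curve`; ``hix1_cut``/``hix2_cut`` are the point
    indices at the recombinase cut plane; ``params`` carries the synapse
    geometry so that :func:`simulate_rotation` can reseal after any number
    of half-turns.  ``loop_bp`` records the enhancer-to-hix spacing (99 bp
    native; long-spacer substrates use the same geometry with different
    bookkeeping).
    """

    curve: ClosedCurve
    hix1_cut: int
    hix2_cut: int
    params: SynapseParams = field(default_factory=SynapseParams)
    synapse_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    synapse_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    segment_bp: dict | None = None  # bp bookkeeping per labeled segment

    def __post_init__(self) -> None:
        if self.curve.labels is None:
            raise ValueError("substrate curve must be labeled")
        for cut, name in ((self.hix1_cut, "hix1"), (self.hix2_cut, "hix2")):
            if not self.curve.labels[cut].startswith(name):
                raise ValueError(f"cut point {cut} does not lie on a {name} segment")
        if self.params.loop_bp <= 0:
            raise ValueError("loop length must be positive")
        if self.params.loop_bp >= self.params.plasmid_bp:
            raise ValueError("loop length exceeds plasmid size")
        object.__setattr__(self, "synapse_center",
                           np.asarray(self.synapse_center, dtype=float))
        ax = np.asarray(self.synapse_axis, dtype=float)
        object.__setattr__(self, "synapse_axis", ax / np.linalg.norm(ax))

    @property
    def loop_bp(self) -> int:
        return self.params.loop_bp

    @property
    def plasmid_bp(self) -> int:
        return self.params.plasmid_bp


@dataclass(frozen=True)
class RotationProduct:
    """Outcome of n successive 180 deg subunit rotations."""

    curve: ClosedCurve
    n_half_turns: int
    orientation: str  # "parental" | "inverted"
    substrate: SubstrateGeometry = field(repr=False)

    def __post_init__(self) -> None:
        expected = "inverted" if self.n_half_turns % 2 else "parental"
        if self.orientation != expected:
            raise ValueError("orientation inconsistent with rotation parity")


def simulate_rotation(s: SubstrateGeometry, n: int) -> RotationProduct:
    """Cut both hix sites, rotate one cut-end pair ``n`` half-turns, reseal.

    The rotated domain (the invertible segment and its leashes) turns about
    the synapse axis; the accumulated winding is laid down as a helical
    sweep in the leashes and the ends reseal in the recombinant (odd ``n``)
    or parental (even ``n``) configuration.  The product is an embedded
    closed curve: round 1 is the unknotted inversion and further rounds walk
    the twist-knot ladder (trefoil, figure-eight, ...) as processive
    rotation traps additional nodes.
    """
    if n < 0:
        raise ValueError("rotation count must be >= 0")
    if n == 0:
        return RotationProduct(s.curve, 0, "parental", s)
    curve = build_invertasome_curve(s.params, n)
    orientation = "inverted" if n % 2 else "parental"
    return RotationProduct(curve, n, orientation, s)


#: duplex-twist re-registration absorbed by the two recombinant joints when
#: the half-sites reseal in the inverted orientation (half a helical turn at
#: each joint, sign set by the supercoil-relaxing rotation direction)
RELIGATION_TWIST = 1


def delta_linking(s: SubstrateGeometry, p: RotationProduct) -> int:
    """Linking-number change of the duplex axis caused by the rotations.

    Computed as writhe change between the product and substrate embeddings
    (Gauss double sums) plus the duplex-twist bookkeeping of the recombinant
    religation joints.  Positive values are loss of negative supercoils.
    The single 180 deg exchange relaxes four supercoils: the two trapped
    branch nodes invert with the invertible domain (+4), the half-turn of
    interdomainal winding contributes the rotation sense (-1), and the two
    recombinant joints absorb one helical turn of re-registration (+1).
    """
    if p.substrate is not s and (p.substrate.params != s.params
                                 or not np.array_equal(
                                     p.substrate.curve.points,
                                     s.curve.points)):
        raise ValueError("product does not belong to this substrate")
    if p.n_half_turns == 0:
        return 0
    dw = writhe(p.curve) - writhe(s.curve)
    twist = RELIGATION_TWIST if p.n_half_turns % 2 else 0
    return int(round(dw)) + twist


# ---------------------------------------------------------------------------
# Curve text I/O
# ---------------------------------------------------------------------------

def read_curve(text: str) -> ClosedCurve:
    """Read a delimited xyz polyline with a label column (x y z label)."""
    pts, labels = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"curve file line {lineno}: expected 'x y z [label]'")
        pts.append([float(v) for v in parts[:3]])
        labels.append(parts[3] if len(parts) > 3 else "dna")
    return ClosedCurve(np.array(pts), tuple(labels))


def write_curve(c: ClosedCurve) -> str:
    labels = c.labels if c.labels is not None else ("dna",) * len(c)
    return "".join(
        f"{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\t{lab}\n"
        for p, lab in zip(c.points, labels))
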