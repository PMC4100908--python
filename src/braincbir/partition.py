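"""Learned spatial partitions of the ROI frame, and the spatial-pyramid baseline.

The ROI bounding box is identified with the unit square [0,1]² (x to the
right, y downward).  A partition is an ordered sequence of straight cuts in
normal form x·cosθ + y·sinθ = r, each applied to one current leaf region;
points with x·cosθ + y·sinθ ≤ r fall on side A (boundary included), the rest
on side B.  Cuts are chosen greedily: the k-th cut splits the leaf of maximal
area, picking the line that maximizes

    Σ_images D_SKL(h_A, h_B)  −  λ · N · |S_A − S_B|

where h_A, h_B are the L1-normalized average soft-code histograms of the two
sides, D_SKL is the symmetrized Kullback–Leibler divergence, S_A, S_B are the
geometric sub-areas, and λ (default 1/S of the region being cut) trades
divergence against area balance — a wildly unbalanced split can have large
divergence but carries no useful layout information.  Each cut is optimized by
a coarse grid initializer followed by alternating coordinate descent on θ and
r with halving step sizes; accepted steps never decrease the objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .bovw import EncodedROI, pool
from .errors import NoFeasibleCutError


@dataclass(frozen=True)
class CutLine:
    """Line x·cosθ + y·sinθ = r with θ in [0, π)."""

    theta: float
    r: float


def canonical_cut(cut: CutLine) -> CutLine:
    """Wrap θ into [0, π); (θ+π, −r) describes the same line."""
    theta, r = cut.theta % (2 * math.pi), cut.r
    if theta >= math.pi:
        theta -= math.pi
        r = -r
    return CutLine(theta, r)


def side_of_line(points: np.ndarray, cut: CutLine) -> np.ndarray:
    """Boolean side labels for unit-square points: True = side A (proj ≤ r)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    proj = pts[:, 0] * math.cos(cut.theta) + pts[:, 1] * math.sin(cut.theta)
    return proj <= cut.r


def _halfplane_polygon(cut: CutLine, side_a: bool, bound: float = 10.0) -> Polygon:
    n = np.array([math.cos(cut.theta), math.sin(cut.theta)])
    t = np.array([-math.sin(cut.theta), math.cos(cut.theta)])
    p0 = cut.r * n
    sgn = -1.0 if side_a else 1.0
    corners = [
        p0 - bound * t,
        p0 + bound * t,
        p0 + bound * t + sgn * 2 * bound * n,
        p0 - bound * t + sgn * 2 * bound * n,
    ]
    return Polygon(corners)


def clip_halfplane(poly: Polygon, cut: CutLine, side_a: bool) -> Polygon:
    """Intersect a convex polygon with one side of a cut line."""
    return poly.intersection(_halfplane_polygon(cut, side_a))


def skl_divergence(h1: np.ndarray, h2: np.ndarray, eps: float = 1e-10) -> float:
    """Symmetrized KL divergence of two nonnegative histograms.

    ``eps`` is added to every bin before renormalization, so histograms with
    disjoint supports get a finite divergence.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("histograms must have equal length")
    if h1.sum() <= 0 or h2.sum() <= 0:
        raise ValueError("histograms must have positive mass")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    p = h1 + eps
    p = p / p.sum()
    q = h2 + eps
    q = q / q.sum()
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


@dataclass(frozen=True)
class PartitionConfig:
    k: int = 9
    lam: float | None = None  # None → 1 / area of the region being cut
    eps: float = 1e-10
    theta_step0: float = math.pi / 36
    r_step0: float = 0.02
    theta_tol: float = math.pi / 1800
    r_tol: float = 1e-4
    t_max: int = 1000
    grid_thetas: int = 8
    grid_offsets: int = 9
    min_leaf_area: float = 0.02

    def __post_init__(self):
        if self.k < 0 or self.eps <= 0 or (self.lam is not None and self.lam < 0):
            raise ValueError("invalid partition configuration")


@dataclass
class PartitionTree:
    """Ordered cuts of the unit square and the resulting leaf polygons.

    Splitting leaf ``target`` leaves the A-side polygon at index ``target``
    and appends the B-side polygon; point assignment replays the same rule, so
    geometric areas and patch memberships always agree.
    """

    cuts: list[tuple[int, CutLine]] = field(default_factory=list)
    leaves: list[Polygon] = field(
        default_factory=lambda: [Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])]
    )

    @classmethod
    def unit_square(cls) -> "PartitionTree":
        return cls()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def areas(self) -> np.ndarray:
        return np.array([leaf.area for leaf in self.leaves])

    def split(self, target: int, cut: CutLine) -> None:
        poly = self.leaves[target]
        a = clip_halfplane(poly, cut, side_a=True)
        b = clip_halfplane(poly, cut, side_a=False)
        if a.is_empty or b.is_empty or a.area <= 0 or b.area <= 0:
            raise NoFeasibleCutError("cut does not intersect the target region")
        self.leaves[target] = a
        self.leaves.append(b)
        self.cuts.append((target, cut))

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Leaf index for each unit-square point (boundary points to side A)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        labels = np.zeros(pts.shape[0], dtype=int)
        n_regions = 1
        for target, cut in self.cuts:
            mask = (labels == target) & ~side_of_line(pts, cut)
            labels[mask] = n_regions
            n_regions += 1
        return labels

    def membership(self, points: np.ndarray) -> list[tuple[int, np.ndarray]]:
        return [(self.n_leaves, self.assign(points))]

    def to_json(self, path: str | Path | None = None, config_echo: dict | None = None):
        payload = {
            "cuts": [
                {"target_region_id": t, "theta": c.theta, "r": c.r}
                for t, c in self.cuts
            ],
            "leaves": [list(leaf.exterior.coords) for leaf in self.leaves],
            "areas": self.areas.tolist(),
            "config": config_echo or {},
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "PartitionTree":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        tree = cls(
            cuts=[
                (c["target_region_id"], CutLine(c["theta"], c["r"]))
                for c in source["cuts"]
            ],
            leaves=[Polygon(coords) for coords in source["leaves"]],
        )
        return tree


@dataclass(frozen=True)
class SpatialPyramid:
    """Uniform 2ˡ×2ˡ grids for levels 0..levels-1 (1+4+16 cells at 3 levels)."""

    levels: int = 3

    @property
    def n_regions(self) -> int:
        return sum(4**l for l in range(self.levels))

    def membership(self, points: np.ndarray) -> list[tuple[int, np.ndarray]]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = []
        for l in range(self.levels):
            g = 2**l
            ix = np.clip((pts[:, 0] * g).astype(int), 0, g - 1)
            iy = np.clip((pts[:, 1] * g).astype(int), 0, g - 1)
            out.append((g * g, iy * g + ix))
        return out

    def cell_areas(self) -> list[np.ndarray]:
        return [np.full(4**l, 4.0 ** (-l)) for l in range(self.levels)]


def spatial_pyramid_partition(levels: int) -> SpatialPyramid:
    if levels < 1:
        raise ValueError("levels must be >= 1")
    return SpatialPyramid(levels)


# ---------------------------------------------------------------------------
# histograms and the cut objective


def _mean_histogram(codes: np.ndarray, V: int) -> np.ndarray:
    """Average-pooled, L1-normalized soft codes; uniform when empty."""
    if codes.shape[0] == 0:
        return np.full(V, 1.0 / V)
    h = codes.mean(axis=0)
    s = h.sum()
    return h / s if s > 0 else np.full(V, 1.0 / V)


def region_histograms(
    encoded: EncodedROI, tree: PartitionTree
) -> tuple[np.ndarray, np.ndarray]:
    """Per-leaf probability histograms (rows) plus an empty-leaf flag vector."""
    labels = tree.assign(encoded.points)
    V = encoded.codes.shape[1]
    hists = np.empty((tree.n_leaves, V))
    empty = np.zeros(tree.n_leaves, dtype=bool)
    for i in range(tree.n_leaves):
        block = encoded.codes[labels == i]
        empty[i] = block.shape[0] == 0
        hists[i] = _mean_histogram(block, V)
    return hists, empty


def cut_objective(
    cut: CutLine,
    region: Polygon,
    subsets: list[tuple[np.ndarray, np.ndarray]],
    lam: float,
    eps: float = 1e-10,
    min_leaf_area: float = 0.02,
) -> float:
    """Objective of one candidate cut of ``region``.

    ``subsets`` holds, per training image, the (points, codes) already
    restricted to the region.  Returns -inf when either geometric side is
    smaller than ``min_leaf_area``.
    """
    a_poly = clip_halfplane(region, cut, side_a=True)
    b_poly = clip_halfplane(region, cut, side_a=False)
    sa, sb = a_poly.area, b_poly.area
    if sa < min_leaf_area or sb < min_leaf_area:
        return -math.inf
    total = 0.0
    for pts, codes in subsets:
        mask = side_of_line(pts, cut)
        V = codes.shape[1]
        ha = _mean_histogram(codes[mask], V)
        hb = _mean_histogram(codes[~mask], V)
        total += skl_divergence(ha, hb, eps)
    return total - lam * len(subsets) * abs(sa - sb)


def optimize_cut(
    region: Polygon,
    subsets: list[tuple[np.ndarray, np.ndarray]],
    config: PartitionConfig = PartitionConfig(),
    lam: float | None = None,
) -> tuple[CutLine, list[float]]:
    """Best line cut of one region: coarse grid init + coordinate descent.

    Returns the cut and the history of accepted objective values (which is
    non-decreasing by construction).
    """
    if region.area < 2 * config.min_leaf_area:
        raise NoFeasibleCutError("region too small to admit a balanced cut")
    if lam is None:
        lam = config.lam if config.lam is not None else 1.0 / region.area

    def obj(theta, r):
        return cut_objective(
            CutLine(theta, r), region, subsets, lam, config.eps, config.min_leaf_area
        )

    verts = np.asarray(region.exterior.coords)
    best = (-math.inf, 0.0, 0.0)
    for i in range(config.grid_thetas):
        theta = i * math.pi / config.grid_thetas
        proj = verts[:, 0] * math.cos(theta) + verts[:, 1] * math.sin(theta)
        offsets = np.linspace(proj.min(), proj.max(), config.grid_offsets + 2)[1:-1]
        for r in offsets:
            v = obj(theta, float(r))
            if v > best[0]:
                best = (v, theta, float(r))
    if not math.isfinite(best[0]):
        raise NoFeasibleCutError("no grid initializer admits both sides")

    value, theta, r = best
    history = [value]
    dth, dr = config.theta_step0, config.r_step0
    for _ in range(config.t_max):
        # θ sweep holding r
        cands = [(obj(theta + dth, r), theta + dth), (obj(theta - dth, r), theta - dth)]
        cands.sort(key=lambda c: -c[0])
        if cands[0][0] > value:
            value, theta = cands[0]
        else:
            dth *= 0.5
        # r sweep holding θ
        cands = [(obj(theta, r + dr), r + dr), (obj(theta, r - dr), r - dr)]
        cands.sort(key=lambda c: -c[0])
        if cands[0][0] > value:
            value, r = cands[0]
        else:
            dr *= 0.5
        history.append(value)
        if dth < config.theta_tol and dr < config.r_tol:
            break
    cut = canonical_cut(CutLine(theta, r))
    return cut, history


def learn_partition(
    encoded_records: list[EncodedROI],
    config: PartitionConfig = PartitionConfig(),
) -> PartitionTree:
    """Greedy k-cut partition of the unit square ROI frame.

    Each cut targets the current maximum-area leaf (``argmax`` ties resolve to
    the earliest-created leaf) and is optimized against all training images'
    patches falling in that leaf.
    """
    tree = PartitionTree.unit_square()
    for _ in range(config.k):
        areas = tree.areas
        target = int(np.argmax(areas))
        subsets = []
        for enc in encoded_records:
            labels = tree.assign(enc.points)
            mask = labels == target
            subsets.append((enc.points[mask], enc.codes[mask]))
        lam = config.lam if config.lam is not None else 1.0 / areas[target]
        cut, _ = optimize_cut(tree.leaves[target], subsets, config, lam=lam)
        tree.split(target, cut)
    return tree


def extract_feature(
    encoded: EncodedROI,
    partition: PartitionTree | SpatialPyramid,
    p: float | str = "inf",
) -> np.ndarray:
    """Per-region pooled codes concatenated in region order (length m·V)."""
    blocks = []
    for m, labels in partition.membership(encoded.points):
        blocks.append(pool(encoded.codes, labels, m, p))
    return np.concatenate(blocks)
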