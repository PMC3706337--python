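"""Stage 1 — salient interest-region extraction.

Bright-on-dark maximally stable extremal regions are computed on the
max-tree of the image, with an image-adaptive stability threshold schedule
and iterative contrast enhancement driven by the detected regions
themselves.  The resulting component forest is collapsed to a depth-2
hierarchy (single / lower / upper), and nested pairs whose union looks
like one nucleus are merged with a trained linear classifier.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import regionprops
from skimage.morphology import max_tree

logger = logging.getLogger(__name__)

__all__ = [
    "MserParams",
    "InterestRegion",
    "RegionHierarchy",
    "NoRegionsFoundError",
    "detect_mser",
    "adaptive_mser",
    "enhance_contrast",
    "merge_nested_regions",
    "classify_hierarchy",
    "run_initial_segmentation",
    "merge_features",
]


class NoRegionsFoundError(RuntimeError):
    """Raised when the iterative detection finds no interest region."""


@dataclass(frozen=True)
class MserParams:
    """Stability / size constraints plus the adaptive-schedule constants."""

    v1: float = 0.7
    v2: float = 0.4
    delta_v: float = 0.1
    delta: int = 5
    min_area: int = 30
    max_area: int | None = None  # None -> 25% of image area
    min_diversity: float = 0.2
    split_min_gap: int = 25
    C: float = 128.0
    max_variation: float = 0.7

    def __post_init__(self) -> None:
        if not (self.v2 <= self.max_variation <= self.v1):
            raise ValueError("require v2 <= max_variation <= v1")
        if self.delta_v <= 0:
            raise ValueError("delta_v must be > 0")
        if self.max_area is not None and not self.min_area < self.max_area:
            raise ValueError("require min_area < max_area")
        if not 1 <= self.C <= 255:
            raise ValueError("C must be in [1, 255]")

    def resolve_max_area(self, shape) -> int:
        if self.max_area is not None:
            return self.max_area
        return int(0.25 * shape[0] * shape[1])


@dataclass
class InterestRegion:
    """A connected salient region, stored as flat pixel indices."""

    id: int
    pixels: np.ndarray  # flat indices into the image
    shape: tuple[int, int]
    level: str  # 'single' | 'lower' | 'upper'
    parent_id: int | None = None
    variation: float = 0.0

    @property
    def area(self) -> int:
        return int(self.pixels.size)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, bool)
        m.ravel()[self.pixels] = True
        return m

    @property
    def coords(self) -> np.ndarray:
        return np.stack(np.unravel_index(self.pixels, self.shape), axis=1)

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.unravel_index(self.pixels, self.shape)
        return float(rr.mean()), float(cc.mean())


@dataclass
class RegionHierarchy:
    regions: list[InterestRegion]
    image_ref: str = ""
    shape: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.regions)

    def by_id(self, rid: int) -> InterestRegion:
        return next(r for r in self.regions if r.id == rid)

    def singles(self) -> list[InterestRegion]:
        return [r for r in self.regions if r.level == "single"]

    def lowers(self) -> list[InterestRegion]:
        return [r for r in self.regions if r.level == "lower"]

    def uppers(self) -> list[InterestRegion]:
        return [r for r in self.regions if r.level == "upper"]

    def children_of(self, rid: int) -> list[InterestRegion]:
        return [r for r in self.regions if r.parent_id == rid]

    def has_two_levels(self) -> bool:
        return any(r.level == "upper" for r in self.regions)

    def validate(self) -> None:
        """Assert structural invariants (depth <= 2, nesting, disjoint sibs)."""
        ids = {r.id for r in self.regions}
        for r in self.regions:
            if r.level == "upper":
                parent = self.by_id(r.parent_id)
                assert parent.level == "lower"
                assert set(r.pixels).issubset(set(parent.pixels))
            else:
                assert r.parent_id is None
        for low in self.lowers():
            kids = self.children_of(low.id)
            assert kids, "lower region must have upper children"
            seen: set[int] = set()
            for k in kids:
                ks = set(k.pixels.tolist())
                assert not (ks & seen), "sibling uppers must be disjoint"
                seen |= ks
        for s in self.singles():
            assert not self.children_of(s.id)
        assert len(ids) == len(self.regions)


# ------------------------------------------------------------------ tree core


@njit(cache=True)
def _subtree_area(parent, order):
    area = np.ones(parent.size, np.int64)
    for k in range(order.size - 1, 0, -1):
        p = order[k]
        q = parent[p]
        if q != p:
            area[q] += area[p]
    return area


@njit(cache=True)
def _variations(parent, val, area, nodes, delta):
    out = np.empty(nodes.size, np.float64)
    for i in range(nodes.size):
        c = nodes[i]
        v = val[c]
        a = c
        while True:
            p = parent[a]
            if p == a or val[p] < v - delta:
                break
            a = p
        out[i] = (area[a] - area[c]) / area[c]
    return out


@njit(cache=True)
def _nearest_kept(parent, val, kept, order):
    nk = np.full(parent.size, -1, np.int64)
    for k in range(order.size):
        p = order[k]
        q = parent[p]
        if p == q:  # root
            nk[p] = p if kept[p] else -1
        elif val[p] != val[q]:  # canonical, q is canonical parent
            nk[p] = p if kept[p] else nk[q]
        else:  # non-canonical member of q's component
            nk[p] = nk[q]
    return nk


class _TreeStats:
    """Max-tree of one image plus per-canonical-node area and variation."""

    def __init__(self, image: np.ndarray, delta: int):
        parent, order = max_tree(image, connectivity=1)
        parent = parent.ravel().astype(np.int64)
        val = image.ravel().astype(np.int64)
        self.parent = parent
        self.order = order.astype(np.int64)
        self.val = val
        self.area = _subtree_area(parent, self.order)
        root = self.order[0]
        canonical = (val != val[parent]) | (np.arange(val.size) == root)
        self.canonical_nodes = np.flatnonzero(canonical)
        self.variation = np.full(val.size, np.inf)
        self.variation[self.canonical_nodes] = _variations(
            parent, val, self.area, self.canonical_nodes, delta
        )
        self.root = int(root)


_STATS_CACHE: dict[tuple, _TreeStats] = {}


def _tree_stats(image: np.ndarray, delta: int) -> _TreeStats:
    key = (image.shape, int(delta), hashlib.sha1(image.tobytes()).hexdigest())
    if key not in _STATS_CACHE:
        if len(_STATS_CACHE) > 8:
            _STATS_CACHE.clear()
        _STATS_CACHE[key] = _TreeStats(np.ascontiguousarray(image), delta)
    return _STATS_CACHE[key]


def _is_ancestor(anc_link: dict[int, int], node: int, other: int) -> bool:
    """True if `other` is an ancestor of `node` in the kept-node forest."""
    a = anc_link.get(node, -1)
    while a != -1:
        if a == other:
            return True
        a = anc_link.get(a, -1)
    return False


def detect_mser(
    image: np.ndarray, max_variation: float, params: MserParams
) -> RegionHierarchy:
    """Bright-on-dark MSER detection collapsed to a <=2-level hierarchy."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    stats = _tree_stats(image, params.delta)
    max_area = params.resolve_max_area(image.shape)

    nodes = stats.canonical_nodes
    sel = (
        (stats.area[nodes] >= params.min_area)
        & (stats.area[nodes] <= max_area)
        & (stats.variation[nodes] <= max_variation)
    )
    cand = nodes[sel]
    if cand.size == 0:
        return RegionHierarchy([], shape=tuple(image.shape))

    kept_mask = np.zeros(stats.val.size, bool)
    kept_mask[cand] = True
    nk = _nearest_kept(stats.parent, stats.val, kept_mask, stats.order)
    anc = {int(c): int(nk[stats.parent[c]]) if stats.parent[c] != c else -1
           for c in cand}

    # prune nested near-duplicates: keep the most stable of any nested pair
    # whose relative area difference is below min_diversity
    removed: set[int] = set()
    for c in sorted(cand.tolist(), key=lambda c: stats.area[c]):
        a = anc[c]
        while a != -1 and a in removed:
            a = anc[a]
        if a == -1:
            continue
        if (stats.area[a] - stats.area[c]) / stats.area[a] < params.min_diversity:
            if stats.variation[c] <= stats.variation[a]:
                removed.add(a)
            else:
                removed.add(c)
    final_cand = [c for c in cand.tolist() if c not in removed]

    # rebuild ancestor links over the pruned set
    kept_mask[:] = False
    kept_mask[final_cand] = True
    nk = _nearest_kept(stats.parent, stats.val, kept_mask, stats.order)
    anc = {int(c): int(nk[stats.parent[c]]) if stats.parent[c] != c else -1
           for c in final_cand}

    roots = [c for c in final_cand if anc[c] == -1]
    desc: dict[int, list[int]] = {r: [] for r in roots}
    for c in final_cand:
        if anc[c] == -1:
            continue
        top = c
        while anc[top] != -1:
            top = anc[top]
        desc[top].append(c)

    # collapse to two levels: per root keep the root plus a pairwise-disjoint
    # subset of its descendants, preferring the finest disjoint decomposition
    # (most regions; this is what splits touching nuclei) and breaking ties
    # toward the most stable node of each branch
    children: dict[int, list[int]] = {c: [] for c in final_cand}
    for c in final_cand:
        if anc[c] != -1:
            children[anc[c]].append(c)

    def _best(c: int) -> tuple[int, float, list[int]]:
        """(count, total variation, picks) of the best disjoint selection in
        the candidate subtree rooted at c (including c itself)."""
        own = (1, float(stats.variation[c]), [c])
        if not children[c]:
            return own
        parts = [_best(k) for k in children[c]]
        cnt = sum(p[0] for p in parts)
        tot = sum(p[1] for p in parts)
        picks = [x for p in parts for x in p[2]]
        coverage = sum(stats.area[x] for x in picks) / stats.area[c]
        gap = min(stats.val[x] for x in picks) - stats.val[c]
        if cnt > own[0] and (coverage >= 0.5 or gap >= params.split_min_gap):
            # genuine multi-object decomposition: the children either cover
            # the parent (touching nuclei) or stand far above it in
            # intensity (nuclei inside an elevated background component);
            # shallow low-coverage splits are texture cores and are absorbed
            return (cnt, tot, picks)
        # otherwise keep the outermost node of the branch: inner nodes are
        # texture cores that under-represent the object
        return own

    chosen: dict[int, list[int]] = {}
    for r in roots:
        picked: list[int] = []
        for k in children[r]:
            picked.extend(_best(k)[2])
        chosen[r] = picked

    final_nodes = roots + [d for r in roots for d in chosen[r]]
    kept_mask[:] = False
    kept_mask[final_nodes] = True
    nk = _nearest_kept(stats.parent, stats.val, kept_mask, stats.order)
    groups: dict[int, np.ndarray] = {}
    order_by_nk = np.argsort(nk, kind="stable")
    sorted_nk = nk[order_by_nk]
    bounds = np.searchsorted(sorted_nk, np.array(final_nodes))
    bounds_hi = np.searchsorted(sorted_nk, np.array(final_nodes), side="right")
    for node, lo, hi in zip(final_nodes, bounds, bounds_hi):
        groups[node] = order_by_nk[lo:hi]

    regions: list[InterestRegion] = []
    next_id = 0
    shape = tuple(image.shape)
    for r in roots:
        uppers = chosen[r]
        if uppers:
            lower_pixels = np.concatenate(
                [groups[r]] + [groups[u] for u in uppers]
            )
            rid = next_id
            regions.append(
                InterestRegion(rid, np.sort(lower_pixels), shape, "lower",
                               variation=float(stats.variation[r]))
            )
            next_id += 1
            for u in uppers:
                regions.append(
                    InterestRegion(next_id, np.sort(groups[u]), shape, "upper",
                                   parent_id=rid,
                                   variation=float(stats.variation[u]))
                )
                next_id += 1
        else:
            regions.append(
                InterestRegion(next_id, np.sort(groups[r]), shape, "single",
                               variation=float(stats.variation[r]))
            )
            next_id += 1
    return RegionHierarchy(regions, shape=shape)


def adaptive_mser(
    image: np.ndarray, params: MserParams
) -> tuple[RegionHierarchy, float]:
    """Run detection with the stability threshold lowered from v1 by delta_v
    steps until reaching v2 or until the hierarchy gains a second level."""
    v = params.v1
    hierarchy = detect_mser(image, v, params)
    while v - params.delta_v >= params.v2 - 1e-12 and not hierarchy.has_two_levels():
        v = round(v - params.delta_v, 10)
        hierarchy = detect_mser(image, v, params)
    return hierarchy, v


def enhance_contrast(
    image: np.ndarray, regions: RegionHierarchy, C: float
) -> np.ndarray:
    """Rescale the image by C / (0.5 * (region min + region mean)), clipped
    to the 8-bit range."""
    if not regions.regions:
        raise ValueError("enhance_contrast requires at least one detected region")
    # pool over the putative nuclei (single/upper level); lower-level regions
    # are mostly elevated background whose bulk would drag the mean down and
    # blow up the scale factor across iterations
    pool_regions = [r for r in regions.regions if r.level in ("single", "upper")]
    if not pool_regions:
        pool_regions = regions.regions
    pooled = np.unique(np.concatenate([r.pixels for r in pool_regions]))
    vals = image.ravel()[pooled].astype(np.float64)
    r0 = vals.min()
    r2 = vals.mean()
    factor = C / (0.5 * (r0 + r2))
    out = np.clip(np.rint(image.astype(np.float64) * factor), 0, 255)
    return out.astype(np.uint8)


# --------------------------------------------------------------- merge step


def merge_features(mask: np.ndarray) -> np.ndarray:
    """Shape/size feature vector of a binary region: area, axis ratio,
    solidity, best-fit-ellipse residual fraction."""
    props = regionprops(mask.astype(np.uint8))[0]
    area = props.area
    minor = max(props.axis_minor_length, 1.0)
    ax_ratio = props.axis_major_length / minor
    solidity = props.solidity
    r0, c0 = props.centroid
    a = max(props.axis_major_length / 2.0, 0.5)
    b = max(props.axis_minor_length / 2.0, 0.5)
    ell = np.zeros_like(mask, bool)
    rr, cc = draw_ellipse(r0, c0, a, b, shape=mask.shape,
                          rotation=-props.orientation)
    ell[rr, cc] = True
    residual = np.count_nonzero(ell ^ mask) / max(area, 1)
    # log area: size matters multiplicatively (a 4x-too-big round blob is
    # as wrong as a 4x-too-small one)
    return np.array([np.log(area), ax_ratio, solidity, residual], dtype=np.float64)


def merge_nested_regions(
    hierarchy: RegionHierarchy, image: np.ndarray, merge_model
) -> RegionHierarchy:
    """Collapse (lower, upper) pairs whose combined area the classifier
    accepts as a single nucleus; clusters with several uppers are kept."""
    out: list[InterestRegion] = []
    for low in hierarchy.lowers():
        kids = hierarchy.children_of(low.id)
        if len(kids) == 1 and merge_model is not None:
            feats = merge_features(low.mask())
            if merge_model.predict(feats[None, :])[0]:
                out.append(replace(low, level="single", parent_id=None))
                continue
        out.append(low)
        out.extend(kids)
    out.extend(hierarchy.singles())
    out.sort(key=lambda r: r.id)
    return RegionHierarchy(out, image_ref=hierarchy.image_ref,
                           shape=hierarchy.shape)


def classify_hierarchy(
    hierarchy: RegionHierarchy,
) -> tuple[list[InterestRegion], list[InterestRegion]]:
    """Partition into (nuclei, clusters): singles vs lowers with children."""
    nuclei = hierarchy.singles()
    clusters = [r for r in hierarchy.lowers() if hierarchy.children_of(r.id)]
    return nuclei, clusters


def run_initial_segmentation(
    image: np.ndarray,
    params: MserParams,
    merge_model=None,
    max_iter: int = 10,
    record: dict | None = None,
) -> tuple[RegionHierarchy, np.ndarray]:
    """Alternate adaptive detection and contrast enhancement until the
    region count stabilizes, then merge nested pairs.

    Returns the final hierarchy and the working (enhanced) image it was
    detected on.
    """
    cur = np.asarray(image)
    prev_count = None
    hierarchy = RegionHierarchy([], shape=tuple(cur.shape))
    counts: list[int] = []
    used_vs: list[float] = []
    for _ in range(max_iter):
        hierarchy, used_v = adaptive_mser(cur, params)
        counts.append(len(hierarchy))
        used_vs.append(used_v)
        if len(hierarchy) == prev_count or len(hierarchy) == 0:
            break
        prev_count = len(hierarchy)
        # rescale the *original* image with statistics of the current
        # region set: compounding the enhancement geometrically saturates
        # the 8-bit range and destroys the structure it is meant to reveal
        enhanced = enhance_contrast(image, hierarchy, params.C)
        if np.array_equal(enhanced, cur):
            break
        cur = enhanced
    else:
        # iteration cap hit right after an enhancement: re-detect once so the
        # returned hierarchy is consistent with the returned working image
        hierarchy, used_v = adaptive_mser(cur, params)
        counts.append(len(hierarchy))
        used_vs.append(used_v)
    if record is not None:
        record["region_counts"] = counts
        record["used_max_variations"] = used_vs
    if len(hierarchy) == 0:
        raise NoRegionsFoundError("no interest regions found within iteration cap")
    logger.debug("initial segmentation counts per iteration: %s", counts)
    hierarchy = merge_nested_regions(hierarchy, cur, merge_model)
    return hierarchy, cur
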