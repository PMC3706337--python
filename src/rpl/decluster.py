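"""Stage 2 — candidate identification and validation inside clusters.

Candidates are the upper regions of each cluster plus connected components
of foreground-classified pixels (128-dim upright gradient descriptors fed
to the trained polynomial classifier).  Under-segmented candidates are
completed to their minimum-volume enclosing ellipse, described by a
bag-of-features appearance histogram, and validated against the distance
profiles of reference regions with a kernel-density probability estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d, uniform_filter

from .initial_segmentation import InterestRegion, RegionHierarchy, classify_hierarchy

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationParams",
    "CandidateRegion",
    "DetectedRegion",
    "AppearanceHistogram",
    "DistanceProfile",
    "ReferenceSet",
    "dense_descriptor",
    "dense_descriptor_grid",
    "patch_features",
    "appearance_histogram",
    "diffusion_distance",
    "reference_probability",
    "validate_candidate",
    "identify_candidates",
    "complete_ellipse",
    "mvee",
    "decluster_process",
]

N_INTENSITY_BINS = 64
N_WORDS = 12


@dataclass(frozen=True)
class ValidationParams:
    alpha1: float = 0.6
    alpha2: float = 0.4
    patch_size: int = 8
    min_candidate_area: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.alpha2 <= 1 and 0 < self.alpha1 <= 1):
            raise ValueError("alpha1 and alpha2 must be in (0, 1]")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")


@dataclass
class AppearanceHistogram:
    """Size-normalized intensity and feature-word frequencies of a region."""

    intensity_hist: np.ndarray  # (64,)
    word_hist: np.ndarray  # (12,)
    normalizer: int

    def __post_init__(self) -> None:
        assert self.intensity_hist.shape == (N_INTENSITY_BINS,)
        assert self.word_hist.shape == (N_WORDS,)
        assert (self.intensity_hist >= 0).all() and (self.word_hist >= 0).all()


@dataclass
class CandidateRegion:
    pixels: np.ndarray  # flat indices
    shape: tuple[int, int]
    source: str  # 'upper_region' | 'pixel_classification'
    cluster_id: int
    region_id: int | None = None  # id in the stage-1 hierarchy, if any
    ellipse_completed: bool = False
    appearance: AppearanceHistogram | None = None
    Q: float | None = None
    label: str | None = None  # 'F' | 'B'

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, bool)
        m.ravel()[self.pixels] = True
        return m

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.unravel_index(self.pixels, self.shape)
        return float(rr.mean()), float(cc.mean())


@dataclass
class DetectedRegion:
    """Stage-2 output region with provenance."""

    pixels: np.ndarray
    shape: tuple[int, int]
    provenance: str  # 'single' | 'upper_region' | 'pixel_classification'
    Q: float | None = None

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, bool)
        m.ravel()[self.pixels] = True
        return m


# ----------------------------------------------------------- dense descriptor

_N_ORI = 8
_N_CELLS = 4


def dense_descriptor_grid(
    image: np.ndarray, patch_size: int = 8, low_contrast_floor: float = 5.0
) -> np.ndarray:
    """Upright fixed-scale 128-dim gradient descriptor at every pixel.

    4x4 spatial cells of orientation histograms (8 bins, linear orientation
    interpolation), pooled with box filters over a window tied to
    patch_size, then L2-normalized with the standard 0.2 clipping.
    Returns float32 array (H, W, 128).
    """
    im = np.asarray(image, dtype=np.float64)
    h, w = im.shape
    gy, gx = np.gradient(im)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % (2 * np.pi)

    # linear soft assignment into 8 orientation channels
    pos = ang / (2 * np.pi) * _N_ORI
    lo = np.floor(pos).astype(int) % _N_ORI
    hi = (lo + 1) % _N_ORI
    w_hi = pos - np.floor(pos)
    channels = np.zeros((_N_ORI, h, w))
    for o in range(_N_ORI):
        channels[o] += np.where(lo == o, mag * (1 - w_hi), 0.0)
        channels[o] += np.where(hi == o, mag * w_hi, 0.0)

    cell = max(2, patch_size // _N_CELLS)
    pooled = np.empty_like(channels)
    for o in range(_N_ORI):
        pooled[o] = uniform_filter(channels[o], size=cell, mode="reflect")

    desc = np.empty((h, w, _N_CELLS * _N_CELLS * _N_ORI), dtype=np.float32)
    offsets = [int(round((i - (_N_CELLS - 1) / 2.0) * cell)) for i in range(_N_CELLS)]
    k = 0
    for oy in offsets:
        for ox in offsets:
            for o in range(_N_ORI):
                shifted = np.roll(pooled[o], (-oy, -ox), axis=(0, 1))
                desc[:, :, k] = shifted
                k += 1
    # normalize / clip / renormalize per the standard descriptor contract;
    # windows with almost no gradient energy stay zero (flat-window rule),
    # otherwise normalization would amplify pure sensor noise into
    # texture-like descriptors
    norm = np.linalg.norm(desc, axis=2, keepdims=True)
    low = norm < low_contrast_floor
    np.divide(desc, norm, out=desc, where=norm > 1e-12)
    np.clip(desc, 0.0, 0.2, out=desc)
    norm = np.linalg.norm(desc, axis=2, keepdims=True)
    np.divide(desc, norm, out=desc, where=norm > 1e-12)
    desc[low[:, :, 0]] = 0.0
    return desc


def dense_descriptor(
    image: np.ndarray, pixel: tuple[int, int], patch_size: int = 8
) -> np.ndarray:
    """Descriptor of the local patch centered at one pixel."""
    r, c = pixel
    h, w = image.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("pixel outside image bounds")
    return dense_descriptor_grid(image, patch_size)[r, c]


# ------------------------------------------------------------- patch features


def patch_features(image: np.ndarray, patch_size: int = 8):
    """Texture features of the non-overlapping patch grid.

    Each patch yields [min, max, mean, std] plus the 64-bin histogram of
    absolute pairwise pixel intensity differences (as fractions of the pair
    count).  Returns (features (n_patches, 68), patches_per_row).
    """
    im = np.asarray(image, dtype=np.float64)
    h, w = im.shape
    ps = patch_size
    ph = math.ceil(h / ps)
    pw = math.ceil(w / ps)
    padded = np.pad(im, ((0, ph * ps - h), (0, pw * ps - w)), mode="reflect")
    blocks = (
        padded.reshape(ph, ps, pw, ps).transpose(0, 2, 1, 3).reshape(ph * pw, ps * ps)
    )
    mins = blocks.min(axis=1)
    maxs = blocks.max(axis=1)
    means = blocks.mean(axis=1)
    stds = blocks.std(axis=1)
    iu = np.triu_indices(ps * ps, k=1)
    diffs = np.abs(blocks[:, :, None] - blocks[:, None, :])[:, iu[0], iu[1]]
    bins = np.minimum((diffs / 4.0).astype(np.int64), N_INTENSITY_BINS - 1)
    n = blocks.shape[0]
    offset = np.arange(n)[:, None] * N_INTENSITY_BINS
    hist = np.bincount(
        (bins + offset).ravel(), minlength=n * N_INTENSITY_BINS
    ).reshape(n, N_INTENSITY_BINS) / iu[0].size
    feats = np.column_stack([mins, maxs, means, stds, hist])
    return feats, pw


def appearance_histogram(
    region_pixels: np.ndarray,
    image: np.ndarray,
    codebook,
    patch_size: int = 8,
    patch_cache=None,
) -> AppearanceHistogram:
    """Bag-of-features appearance of a pixel set.

    64-bin intensity histogram over the region plus the occurrence
    histogram of the feature words of the patches it overlaps, each
    normalized by the region size.
    """
    region_pixels = np.asarray(region_pixels)
    size = region_pixels.size
    if size == 0:
        raise ValueError("empty region")
    vals = image.ravel()[region_pixels].astype(np.int64)
    ihist = np.bincount(
        np.minimum(vals // 4, N_INTENSITY_BINS - 1), minlength=N_INTENSITY_BINS
    ).astype(np.float64)

    if patch_cache is None:
        patch_cache = patch_features(image, patch_size)
    feats, pw = patch_cache
    rr, cc = np.unravel_index(region_pixels, image.shape)
    pixel_patches = (rr // patch_size) * pw + (cc // patch_size)
    patch_ids, inverse, counts = np.unique(
        pixel_patches, return_inverse=True, return_counts=True
    )
    words = codebook.assign(feats[patch_ids])
    # every pixel contributes the word of its patch, so the word histogram
    # is a percentage of the region size just like the intensity histogram
    whist = np.bincount(
        words, weights=counts.astype(np.float64), minlength=N_WORDS
    )
    return AppearanceHistogram(ihist / size, whist / size, size)


# ---------------------------------------------------------- diffusion distance


def _pyramid_l1(diff: np.ndarray) -> float:
    total = np.abs(diff).sum()
    d = np.asarray(diff, dtype=np.float64)
    while d.size > 1:
        d = gaussian_filter1d(d, sigma=1.0, mode="constant")
        if d.size % 2:
            d = np.append(d, 0.0)
        d = 0.5 * (d[0::2] + d[1::2])  # alias-free downsampling
        total += np.abs(d).sum()
    return float(total)


def diffusion_distance(f1: AppearanceHistogram, f2: AppearanceHistogram) -> float:
    """Cross-bin histogram distance: L1 norms of the difference histogram
    summed over a Gaussian smooth-and-downsample pyramid, block-wise over
    the intensity and word histograms."""
    if (
        f1.intensity_hist.shape != f2.intensity_hist.shape
        or f1.word_hist.shape != f2.word_hist.shape
    ):
        raise ValueError("histogram layouts do not match")
    return _pyramid_l1(f1.intensity_hist - f2.intensity_hist) + _pyramid_l1(
        f1.word_hist - f2.word_hist
    )


# ------------------------------------------------------------- KDE validation


@dataclass
class DistanceProfile:
    """Distances from one reference to all others, with its KDE bandwidth."""

    reference_id: int
    distances: np.ndarray
    bandwidth: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=np.float64)
        if d.size < 1:
            raise ValueError("profile needs at least one distance")
        if (d < 0).any():
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "distances", d)
        if d.size > 1:
            sigma = d.std(ddof=1)
            iqr = np.subtract(*np.percentile(d, [75, 25]))
            if iqr > 0:
                sigma = min(sigma, iqr / 1.34)  # robust normal-reference rule
        else:
            sigma = 0.0
        h = 1.06 * sigma * d.size ** (-1 / 5)
        floor = 1e-6 * (1.0 + d.mean())
        object.__setattr__(self, "bandwidth", max(h, floor))

    def density(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        h = self.bandwidth
        z = (t[..., None] - self.distances) / h
        return np.exp(-0.5 * z**2).sum(axis=-1) / (
            self.distances.size * h * math.sqrt(2 * math.pi)
        )


def reference_probability(delta_kx: float, profile: DistanceProfile) -> float:
    """Density of delta_kx under the profile KDE, normalized by the maximum
    density over the profile's own sample points, clipped to [0, 1]."""
    p0 = float(profile.density(np.array(delta_kx)))
    pmax = float(profile.density(profile.distances).max())
    if pmax <= 0:
        return 0.0
    return float(np.clip(p0 / pmax, 0.0, 1.0))


class ReferenceSet:
    """Reference regions (stage-1 singles and uppers) with their appearance
    histograms, pairwise distances and per-reference profiles."""

    def __init__(self, regions, histograms, shape):
        self.regions = list(regions)
        self.histograms = list(histograms)
        self.shape = shape
        K = len(self.regions)
        self.D = np.zeros((K, K))
        for i in range(K):
            for j in range(i + 1, K):
                d = diffusion_distance(self.histograms[i], self.histograms[j])
                self.D[i, j] = self.D[j, i] = d
        self.profiles = []
        for k in range(K):
            others = np.delete(self.D[k], k)
            self.profiles.append(
                DistanceProfile(reference_id=k, distances=others)
                if others.size
                else None
            )
        self.centroids = [r.centroid for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def quadrant(self, centroid) -> tuple[bool, bool]:
        h, w = self.shape
        return (centroid[0] < h / 2, centroid[1] < w / 2)

    def indices_near(self, centroid, exclude_region_id=None) -> list[int]:
        """Same-quadrant references; falls back to the whole image when the
        quadrant holds fewer than two."""
        q = self.quadrant(centroid)
        sel = [
            k
            for k in range(len(self))
            if self.quadrant(self.centroids[k]) == q
            and self.regions[k].id != exclude_region_id
        ]
        if len(sel) < 2:
            sel = [
                k
                for k in range(len(self))
                if self.regions[k].id != exclude_region_id
            ]
        return sel

    def probability(self, hist: AppearanceHistogram, indices) -> float:
        """Mean profile probability over the chosen references."""
        ps = []
        for k in indices:
            prof = self.profiles[k]
            if prof is None:
                continue
            d = diffusion_distance(self.histograms[k], hist)
            ps.append(reference_probability(d, prof))
        if not ps:
            raise ValueError("no usable reference profiles")
        return float(np.mean(ps))


def validate_candidate(
    candidate: CandidateRegion,
    references: ReferenceSet,
    co_candidates,
    params: ValidationParams,
) -> tuple[float | None, str]:
    """Label one candidate given its probability and those of the other
    candidates in the same cluster (all Q values precomputed)."""
    if candidate.Q is None:
        raise ValueError("candidate.Q must be computed first")
    others = [c.Q for c in co_candidates if c is not candidate and c.Q is not None]
    # the absolute floor alpha2 always applies; the relative test against the
    # other candidates of the cluster applies when there are any
    ok = candidate.Q > params.alpha2
    if others:
        ok = ok and candidate.Q > params.alpha1 * max(others)
    return candidate.Q, "F" if ok else "B"


# ------------------------------------------------------ candidates & ellipses


def identify_candidates(
    cluster: InterestRegion,
    image: np.ndarray,
    pixel_model,
    enclosed_uppers,
    desc_grid: np.ndarray | None = None,
    min_candidate_area: int = 15,
) -> list[CandidateRegion]:
    """Upper regions plus connected components of foreground-classified
    pixels that do not overlap an upper; pairwise non-overlapping."""
    if pixel_model is None or not getattr(pixel_model, "trained", False):
        raise ValueError("identify_candidates requires a trained pixel model")
    shape = tuple(image.shape)
    out = [
        CandidateRegion(
            pixels=u.pixels, shape=shape, source="upper_region",
            cluster_id=cluster.id, region_id=u.id,
        )
        for u in enclosed_uppers
    ]
    if desc_grid is None:
        desc_grid = dense_descriptor_grid(image)
    flat_desc = desc_grid.reshape(-1, desc_grid.shape[-1])
    pred = pixel_model.predict(flat_desc[cluster.pixels])

    fmask = np.zeros(shape, bool)
    fmask.ravel()[cluster.pixels[pred]] = True
    upper_mask = np.zeros(shape, bool)
    for u in enclosed_uppers:
        upper_mask.ravel()[u.pixels] = True
    labels, n = ndimage.label(fmask, structure=np.ones((3, 3), bool))
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if (comp & upper_mask).any():
            continue
        if comp.sum() < min_candidate_area:
            continue
        out.append(
            CandidateRegion(
                pixels=np.flatnonzero(comp.ravel()), shape=shape,
                source="pixel_classification", cluster_id=cluster.id,
            )
        )
    return out


def mvee(points: np.ndarray, tol: float = 1e-3, max_iter: int = 1000):
    """Minimum-volume enclosing ellipsoid (Khachiyan's algorithm).

    Returns (center, A) with the ellipse {x : (x-c)^T A (x-c) <= 1}.
    """
    P = np.asarray(points, dtype=np.float64)
    n, d = P.shape
    Qm = np.column_stack([P, np.ones(n)]).T
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Qm @ np.diag(u) @ Qm.T
        M = np.einsum("ij,ji->i", Qm.T, np.linalg.solve(X, Qm))
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1) * (M[j] - 1.0))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    c = P.T @ u
    A = np.linalg.inv(P.T @ np.diag(u) @ P - np.outer(c, c)) / d
    # guarantee containment despite the finite tolerance
    q = np.einsum("ij,jk,ik->i", P - c, A, P - c)
    qmax = q.max()
    if qmax > 1.0:
        A = A / qmax
    return c, A


def complete_ellipse(
    candidate: CandidateRegion, cluster: InterestRegion
) -> CandidateRegion:
    """Replace a pixel-classification candidate with the rasterized
    minimum-volume enclosing ellipse of its pixels, intersected with its
    cluster."""
    coords = np.stack(np.unravel_index(candidate.pixels, candidate.shape), axis=1)
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] < 3 or np.linalg.matrix_rank(centered) < 2:
        candidate.ellipse_completed = False
        return candidate
    try:
        from scipy.spatial import ConvexHull, QhullError

        hull = coords[ConvexHull(coords).vertices]
    except QhullError:
        candidate.ellipse_completed = False
        return candidate
    c, A = mvee(hull)

    rr, cc = np.unravel_index(cluster.pixels, candidate.shape)
    pts = np.stack([rr, cc], axis=1).astype(np.float64) - c
    inside = np.einsum("ij,jk,ik->i", pts, A, pts) <= 1.0 + 1e-9
    new_pixels = np.union1d(cluster.pixels[inside], candidate.pixels)
    # stay inside the cluster: original pixels are cluster members already
    candidate.pixels = np.intersect1d(new_pixels, cluster.pixels)
    candidate.ellipse_completed = True
    return candidate


# --------------------------------------------------------------- stage driver


def build_reference_set(
    hierarchy: RegionHierarchy, image: np.ndarray, codebook,
    patch_size: int = 8, patch_cache=None,
) -> ReferenceSet:
    refs = hierarchy.singles() + hierarchy.uppers()
    hists = [
        appearance_histogram(r.pixels, image, codebook, patch_size, patch_cache)
        for r in refs
    ]
    return ReferenceSet(refs, hists, tuple(image.shape))


def decluster_process(
    image: np.ndarray,
    hierarchy: RegionHierarchy,
    models,
    params: ValidationParams,
    record: dict | None = None,
) -> list[DetectedRegion]:
    """Run candidate identification + validation over every cluster.

    Returns the stage-1 singles (kept, and used as references) plus every
    validated candidate.
    """
    shape = tuple(image.shape)
    patch_cache = patch_features(image, params.patch_size)
    nuclei, clusters = classify_hierarchy(hierarchy)
    out = [
        DetectedRegion(pixels=r.pixels, shape=shape, provenance="single")
        for r in nuclei
    ]
    if not clusters:
        return out

    refs = build_reference_set(
        hierarchy, image, models.codebook, params.patch_size, patch_cache
    )
    desc_grid = dense_descriptor_grid(image)
    qlog = []
    for cluster in clusters:
        uppers = hierarchy.children_of(cluster.id)
        cands = identify_candidates(
            cluster, image, models.pixel, uppers, desc_grid,
            params.min_candidate_area,
        )
        for cand in cands:
            if cand.source == "pixel_classification":
                complete_ellipse(cand, cluster)
        for cand in cands:
            cand.appearance = appearance_histogram(
                cand.pixels, image, models.codebook, params.patch_size, patch_cache
            )
            sel = refs.indices_near(cand.centroid, exclude_region_id=cand.region_id)
            if len(sel) < 2:
                logger.warning(
                    "fewer than 2 references for candidate in cluster %d; "
                    "accepting by provenance", cluster.id,
                )
                cand.Q = None
                cand.label = "F" if cand.source == "upper_region" else "B"
                continue
            cand.Q = refs.probability(cand.appearance, sel)
        for cand in cands:
            if cand.Q is None:
                continue
            _, cand.label = validate_candidate(cand, refs, cands, params)
        accepted = [c for c in cands if c.label == "F"]
        _resolve_overlaps(accepted)
        qlog.extend((c.source, c.Q, c.label) for c in cands)
        out.extend(
            DetectedRegion(pixels=c.pixels, shape=shape, provenance=c.source, Q=c.Q)
            for c in accepted
            if c.pixels.size
        )
    if record is not None:
        record["candidate_Q"] = qlog
    return out


def _resolve_overlaps(candidates: list[CandidateRegion]) -> None:
    """Assign pixels contested after ellipse completion to the candidate
    with the higher Q (ties: larger region)."""
    if len(candidates) < 2:
        return
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -(candidates[i].Q if candidates[i].Q is not None else 1.0),
            -candidates[i].pixels.size,
        ),
    )
    taken = np.zeros(0, dtype=np.int64)
    for i in order:
        cand = candidates[i]
        cand.pixels = np.setdiff1d(cand.pixels, taken)
        taken = np.union1d(taken, cand.pixels)
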