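"""Detection and segmentation metrics with instance matching.

Detection counts use the Jaccard >= 0.5 true-positive rule; contour metrics
(NSD, one-sided Hausdorff) measure distances to the matched reference
nucleus contour with an exact Euclidean distance transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "MetricsReport",
    "overlap_ratio",
    "match_instances",
    "dice",
    "nsd",
    "hausdorff",
    "evaluate",
    "boundary",
]


@dataclass
class MatchResult:
    TP: int
    FN: int
    FP: int
    matches: list[tuple[int, int, float]]  # (detected id, truth id, overlap ratio)

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def accuracy(self) -> float:
        den = self.TP + self.FN + self.FP
        return self.TP / den if den else 0.0


@dataclass
class MetricsReport:
    R: float
    P: float
    A: float
    dice: float
    nsd: float
    hd: float
    match: MatchResult
    per_object: list[tuple[float, float, float]] = field(default_factory=list)


def overlap_ratio(detected: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index of two boolean masks; 0 if the union is empty."""
    detected = np.asarray(detected, bool)
    truth = np.asarray(truth, bool)
    union = np.count_nonzero(detected | truth)
    if union == 0:
        logger.debug("overlap_ratio of two empty masks -> 0 by convention")
        return 0.0
    inter = np.count_nonzero(detected & truth)
    return inter / union


def match_instances(detected: np.ndarray, truth: np.ndarray) -> MatchResult:
    """One-to-one instance matching at overlap ratio >= 0.5.

    A Jaccard >= 0.5 pair is necessarily unique for both participants, so a
    greedy scan over co-occurring label pairs is exact.
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.shape != truth.shape:
        raise ValueError("detected and truth masks must have the same shape")
    d_ids, d_area = np.unique(detected[detected > 0], return_counts=True)
    t_ids, t_area = np.unique(truth[truth > 0], return_counts=True)
    d_area = dict(zip(d_ids.tolist(), d_area.tolist()))
    t_area = dict(zip(t_ids.tolist(), t_area.tolist()))

    both = (detected > 0) & (truth > 0)
    pairs, counts = np.unique(
        np.stack([detected[both], truth[both]]), axis=1, return_counts=True
    )
    matches = []
    for (d, t), inter in zip(pairs.T.tolist(), counts.tolist()):
        union = d_area[d] + t_area[t] - inter
        ratio = inter / union
        if ratio >= 0.5:
            matches.append((d, t, ratio))
    tp = len(matches)
    fn = len(t_ids) - tp
    fp = len(d_ids) - tp
    return MatchResult(TP=tp, FN=fn, FP=fp, matches=matches)


def dice(F: np.ndarray, M: np.ndarray) -> float:
    """2|F∩M| / (|F|+|M|); 1 when both masks are empty."""
    F = np.asarray(F, bool)
    M = np.asarray(M, bool)
    s = np.count_nonzero(F) + np.count_nonzero(M)
    if s == 0:
        logger.debug("dice of two empty masks -> 1 by convention")
        return 1.0
    return 2.0 * np.count_nonzero(F & M) / s


def boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with a 4-neighbor outside the mask."""
    mask = np.asarray(mask, bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def _dist_to_contour(M: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of every pixel to the contour of M."""
    bnd = boundary(M)
    if not bnd.any():
        raise ValueError("reference mask has no boundary (empty mask)")
    return ndimage.distance_transform_edt(~bnd)


def nsd(F: np.ndarray, M: np.ndarray) -> float:
    """Normalized sum of distances to the reference contour.

    sum_{u in F xor M} D(u) / sum_{u in F union M} D(u) with D the distance
    to the contour of M.  0 when F == M.
    """
    F = np.asarray(F, bool)
    M = np.asarray(M, bool)
    if not M.any():
        raise ValueError("nsd requires a nonempty reference mask")
    sym = F ^ M
    if not sym.any():
        return 0.0
    D = _dist_to_contour(M)
    den = D[F | M].sum()
    if den == 0:
        return 1.0
    return float(D[sym].sum() / den)


def hausdorff(F: np.ndarray, M: np.ndarray) -> float:
    """One-sided Hausdorff: max over the contour of F of the distance to
    the contour of M."""
    F = np.asarray(F, bool)
    M = np.asarray(M, bool)
    if not F.any() or not M.any():
        raise ValueError("hausdorff requires nonempty masks")
    D = _dist_to_contour(M)
    return float(D[boundary(F)].max())


def evaluate(detected: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Aggregate report: R/P/A from instance matching, pooled-foreground
    Dice, NSD/HD averaged over matched objects."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.shape != truth.shape:
        raise ValueError("detected and truth masks must have the same shape")
    m = match_instances(detected, truth)
    pooled = dice(detected > 0, truth > 0)
    per_object = []
    for d, t, _ in m.matches:
        F = detected == d
        M = truth == t
        per_object.append((dice(F, M), nsd(F, M), hausdorff(F, M)))
    nsd_mean = float(np.mean([o[1] for o in per_object])) if per_object else 0.0
    hd_mean = float(np.mean([o[2] for o in per_object])) if per_object else 0.0
    return MetricsReport(
        R=m.recall, P=m.precision, A=m.accuracy,
        dice=pooled, nsd=nsd_mean, hd=hd_mean,
        match=m, per_object=per_object,
    )
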