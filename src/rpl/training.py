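"""Learned components: merge classifier, pixel classifier, patch codebook.

Labels are derived automatically from instance ground truth: a nested pair
is a positive merge example when its union matches one true nucleus at
Jaccard >= 0.5; pixels are foreground when inside a true nucleus.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import overlap_ratio
from .initial_segmentation import merge_features

logger = logging.getLogger(__name__)

MODEL_BUNDLE_VERSION = 1

__all__ = [
    "MergeClassifier",
    "PixelClassifier",
    "Codebook",
    "TrainedModels",
    "train_merge_classifier",
    "train_pixel_classifier",
    "build_codebook",
]


class MergeClassifier:
    """Linear decision over (area, axis ratio, solidity, ellipse residual)."""

    def __init__(self) -> None:
        self._scaler = StandardScaler()
        self._svm = SVC(kernel="linear", C=1.0, class_weight="balanced")
        self.trained = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MergeClassifier":
        if len(np.unique(y)) < 2:
            raise ValueError("merge training set must contain both classes")
        self._svm.fit(self._scaler.fit_transform(X), y)
        self.trained = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("MergeClassifier is not trained")
        return self._svm.predict(self._scaler.transform(X)).astype(bool)


class PixelClassifier:
    """Polynomial-kernel decision over 128-dim local descriptors."""

    def __init__(self) -> None:
        self._svm = SVC(kernel="poly", degree=3, C=1.0, gamma="scale", coef0=0.0)
        self.trained = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PixelClassifier":
        if len(np.unique(y)) < 2:
            raise ValueError("pixel training sample must contain both classes")
        self._svm.fit(X, y)
        self.trained = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("PixelClassifier is not trained")
        return self._svm.predict(X).astype(bool)


class Codebook:
    """12 k-means centers over standardized patch features."""

    def __init__(self, n_words: int = 12, seed: int = 0) -> None:
        self.n_words = n_words
        self.seed = seed
        self._scaler = StandardScaler()
        self._kmeans: KMeans | None = None

    @property
    def centers(self) -> np.ndarray:
        if self._kmeans is None:
            raise RuntimeError("Codebook is not built")
        return self._kmeans.cluster_centers_

    def fit(self, features: np.ndarray) -> "Codebook":
        uniq = np.unique(features, axis=0)
        if uniq.shape[0] < self.n_words:
            raise ValueError(
                f"need >= {self.n_words} distinct patch features, got {uniq.shape[0]}"
            )
        Z = self._scaler.fit_transform(features)
        self._kmeans = KMeans(
            n_clusters=self.n_words, random_state=self.seed, n_init=10
        ).fit(Z)
        return self

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Nearest-center word index for each feature row."""
        if self._kmeans is None:
            raise RuntimeError("Codebook is not built")
        Z = self._scaler.transform(np.atleast_2d(features))
        return self._kmeans.predict(Z)


@dataclass
class TrainedModels:
    merge: MergeClassifier
    pixel: PixelClassifier
    codebook: Codebook
    patch_size: int = 8
    version: int = MODEL_BUNDLE_VERSION

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "TrainedModels":
        with open(path, "rb") as fh:
            models = pickle.load(fh)
        if getattr(models, "version", None) != MODEL_BUNDLE_VERSION:
            raise ValueError(
                f"model bundle version {getattr(models, 'version', None)!r} "
                f"does not match {MODEL_BUNDLE_VERSION}"
            )
        return models


def train_merge_classifier(nested_pairs, truths) -> MergeClassifier:
    """Fit the merge classifier from (lower, upper, image_index) pairs.

    The combined area of a nested pair is the lower region (the upper is
    contained in it); it is a positive example iff it matches some true
    nucleus at Jaccard >= 0.5.
    """
    X, y = [], []
    for lower, upper, img_idx in nested_pairs:
        mask = lower.mask()
        truth = truths[img_idx]
        labels = np.unique(truth[mask])
        labels = labels[labels > 0]
        pos = any(overlap_ratio(mask, truth == t) >= 0.5 for t in labels)
        X.append(merge_features(mask))
        y.append(pos)
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("no nested pairs supplied")
    logger.info("merge training: %d pairs, %d positive", len(y), int(y.sum()))
    return MergeClassifier().fit(X, y)


def train_pixel_classifier(
    images, truths, sample_rate: float = 0.02, seed: int = 0
) -> PixelClassifier:
    """Fit the pixel F/B classifier on descriptors of a class-balanced
    random sample of pixels (F = inside a true nucleus)."""
    from .decluster import dense_descriptor_grid

    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for image, truth in zip(images, truths):
        desc = dense_descriptor_grid(image)
        fg = np.flatnonzero((truth > 0).ravel())
        bg = np.flatnonzero((truth == 0).ravel())
        n = max(1, int(round(sample_rate * truth.size / 2)))
        if sample_rate >= 1.0:
            fg_take, bg_take = fg, bg
        else:
            fg_take = rng.choice(fg, size=min(n, fg.size), replace=False)
            bg_take = rng.choice(bg, size=min(n, bg.size), replace=False)
        flat = desc.reshape(-1, desc.shape[-1])
        Xs.append(flat[fg_take])
        ys.append(np.ones(fg_take.size, bool))
        Xs.append(flat[bg_take])
        ys.append(np.zeros(bg_take.size, bool))
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    logger.info("pixel training: %d samples, %d foreground", len(y), int(y.sum()))
    return PixelClassifier().fit(X, y)


def build_codebook(images, patch_size: int = 8, seed: int = 0) -> Codebook:
    """k-means codebook over the patch features of all training images."""
    from .decluster import patch_features

    feats = np.concatenate([patch_features(im, patch_size)[0] for im in images])
    return Codebook(n_words=12, seed=seed).fit(feats)
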