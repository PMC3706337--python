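import math

import numpy as np
import pytest
from scipy.stats import norm, wasserstein_distance

from rpl.decluster import (
    AppearanceHistogram,
    CandidateRegion,
    DistanceProfile,
    ReferenceSet,
    ValidationParams,
    appearance_histogram,
    build_reference_set,
    complete_ellipse,
    decluster_process,
    dense_descriptor,
    dense_descriptor_grid,
    diffusion_distance,
    identify_candidates,
    mvee,
    patch_features,
    reference_probability,
    validate_candidate,
)
from rpl.initial_segmentation import InterestRegion, RegionHierarchy


def _hist(intensity=None, word=None):
    i = np.zeros(64) if intensity is None else np.asarray(intensity, float)
    w = np.zeros(12) if word is None else np.asarray(word, float)
    return AppearanceHistogram(i, w, normalizer=100)


class TestValidationParams:
    def test_defaults(self):
        p = ValidationParams()
        assert p.alpha1 == 0.6 and p.alpha2 == 0.4 and p.patch_size == 8

    def test_invalid(self):
        with pytest.raises(ValueError):
            ValidationParams(alpha1=0.0)
        with pytest.raises(ValueError):
            ValidationParams(patch_size=1)


class TestDenseDescriptor:
    def test_constant_patch_zero(self):
        im = np.full((32, 32), 77, np.uint8)
        d = dense_descriptor(im, (16, 16))
        assert np.allclose(d, 0.0)

    def test_translation_covariance(self, rng):
        im = rng.integers(0, 255, size=(40, 40)).astype(np.uint8)
        shifted = np.roll(im, (0, 4), axis=(0, 1))
        g1 = dense_descriptor_grid(im)
        g2 = dense_descriptor_grid(shifted)
        # compare interior pixels away from the wrap-around columns
        assert np.allclose(g1[10:30, 10:30], g2[10:30, 14:34], atol=1e-5)

    def test_norm_and_clip_contract(self, rng):
        im = rng.integers(0, 255, size=(40, 40)).astype(np.uint8)
        grid = dense_descriptor_grid(im)
        for _ in range(10):
            r, c = rng.integers(5, 35, size=2)
            d = grid[r, c]
            n = np.linalg.norm(d)
            assert n == pytest.approx(1.0, abs=1e-5) or n == 0.0
            # entries were clipped at 0.2 before the final renormalization,
            # which bounds any single entry well below 1
            assert d.max() <= 0.5

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            dense_descriptor(np.zeros((8, 8), np.uint8), (10, 2))


class TestPatchFeatures:
    def test_constant_image(self):
        feats, pw = patch_features(np.full((16, 16), 50, np.uint8), 8)
        assert feats.shape == (4, 68)
        assert np.allclose(feats[:, 0], 50)  # min
        assert np.allclose(feats[:, 3], 0)  # std
        # all pairwise-difference mass in the zero bin
        assert np.allclose(feats[:, 4], 1.0)
        assert np.allclose(feats[:, 5:], 0.0)

    def test_feature_layout(self, rng):
        im = rng.integers(0, 255, size=(24, 24)).astype(np.uint8)
        feats, pw = patch_features(im, 8)
        assert pw == 3
        block = im[:8, :8].astype(float)
        assert feats[0, 0] == block.min()
        assert feats[0, 1] == block.max()
        assert feats[0, 2] == pytest.approx(block.mean())
        assert feats[0, 3] == pytest.approx(block.std())
        assert feats[0, 4:].sum() == pytest.approx(1.0)


class _IdentityCodebook:
    """Maps a patch feature to a word by its mean intensity bucket."""

    n_words = 12

    def assign(self, features):
        return (np.atleast_2d(features)[:, 2] // 22).astype(int).clip(0, 11)


class TestAppearanceHistogram:
    def test_constant_region(self):
        im = np.full((32, 32), 100, np.uint8)
        pix = np.arange(32 * 32)
        f = appearance_histogram(pix, im, _IdentityCodebook(), 8)
        assert f.intensity_hist.sum() == pytest.approx(1.0)
        assert np.count_nonzero(f.intensity_hist) == 1
        assert np.count_nonzero(f.word_hist) == 1
        assert f.word_hist.sum() == pytest.approx(1.0)

    def test_translation_by_patch_multiple(self, rng):
        motif = rng.integers(0, 255, size=(8, 8)).astype(np.uint8)
        im = np.tile(motif, (6, 6))
        rr, cc = np.mgrid[8:24, 8:24]
        pix1 = np.ravel_multi_index((rr.ravel(), cc.ravel()), im.shape)
        pix2 = np.ravel_multi_index((rr.ravel(), (cc + 16).ravel()), im.shape)
        f1 = appearance_histogram(pix1, im, _IdentityCodebook(), 8)
        f2 = appearance_histogram(pix2, im, _IdentityCodebook(), 8)
        assert np.allclose(f1.intensity_hist, f2.intensity_hist)
        assert np.allclose(f1.word_hist, f2.word_hist)

    def test_duplication_invariance(self, rng):
        motif = rng.integers(0, 255, size=(8, 8)).astype(np.uint8)
        im = np.tile(motif, (4, 8))
        rr, cc = np.mgrid[0:8, 0:16]
        pix = np.ravel_multi_index((rr.ravel(), cc.ravel()), im.shape)
        rr2, cc2 = np.mgrid[0:8, 0:32]
        pix2 = np.ravel_multi_index((rr2.ravel(), cc2.ravel()), im.shape)
        f1 = appearance_histogram(pix, im, _IdentityCodebook(), 8)
        f2 = appearance_histogram(pix2, im, _IdentityCodebook(), 8)
        assert np.allclose(f1.intensity_hist, f2.intensity_hist)
        assert np.allclose(f1.word_hist, f2.word_hist)


class TestDiffusionDistance:
    def test_identity(self):
        f = _hist(np.random.default_rng(0).random(64), np.ones(12))
        assert diffusion_distance(f, f) == 0.0

    def test_symmetry(self, rng):
        f1 = _hist(rng.random(64), rng.random(12))
        f2 = _hist(rng.random(64), rng.random(12))
        assert diffusion_distance(f1, f2) == pytest.approx(
            diffusion_distance(f2, f1)
        )

    def test_nonnegative_zero_iff_equal(self, rng):
        f1 = _hist(rng.random(64), rng.random(12))
        f2 = _hist(rng.random(64), rng.random(12))
        assert diffusion_distance(f1, f2) > 0

    def test_cross_bin_ordering(self):
        base = np.zeros(64)
        base[10] = 1.0
        ref = _hist(base)
        prev = -1.0
        emd_prev = -1.0
        for j in range(10, 50):
            other = np.zeros(64)
            other[j] = 1.0
            d = diffusion_distance(ref, _hist(other))
            emd = wasserstein_distance(np.arange(64), np.arange(64), base, other)
            assert d >= prev - 1e-9
            assert emd >= emd_prev - 1e-9
            prev, emd_prev = d, emd

    def test_layout_mismatch(self):
        f1 = _hist()
        f2 = AppearanceHistogram(np.zeros(64), np.zeros(12), 10)
        f2.word_hist = np.zeros(13)
        with pytest.raises(ValueError):
            diffusion_distance(f1, f2)


class TestReferenceProbability:
    def test_peak_is_one(self):
        prof = DistanceProfile(reference_id=0, distances=np.array([2.0, 2.0, 2.0]))
        assert reference_probability(2.0, prof) == pytest.approx(1.0)

    def test_tail_to_zero(self):
        prof = DistanceProfile(reference_id=0, distances=np.array([1.0, 1.5, 2.0]))
        assert reference_probability(1e6, prof) == pytest.approx(0.0, abs=1e-12)

    def test_grid_oracle_simple_profile(self):
        d = np.array([1.0, 2.0, 3.0])
        prof = DistanceProfile(reference_id=0, distances=d)
        h = prof.bandwidth
        sigma = min(d.std(ddof=1), np.subtract(*np.percentile(d, [75, 25])) / 1.34)
        assert h == pytest.approx(1.06 * sigma * 3 ** (-1 / 5))
        p0 = lambda t: norm.pdf((t - d) / h).sum() / (3 * h)
        expected = min(p0(2.0) / max(p0(v) for v in d), 1.0)
        assert reference_probability(2.0, prof) == pytest.approx(expected, abs=1e-9)

    def test_grid_oracle_random(self, rng):
        for _ in range(100):
            K = int(rng.integers(2, 25))
            d = rng.gamma(2.0, 1.0, size=K)
            prof = DistanceProfile(reference_id=0, distances=d)
            x = float(rng.gamma(2.0, 1.5))
            h = prof.bandwidth
            p0 = lambda t: norm.pdf((t - d) / h).sum() / (K * h)
            expected = min(p0(x) / max(p0(v) for v in d), 1.0)
            assert reference_probability(x, prof) == pytest.approx(
                expected, abs=1e-9
            )

    def test_probability_in_unit_interval(self, rng):
        for _ in range(50):
            d = rng.gamma(2.0, 1.0, size=int(rng.integers(1, 10)))
            prof = DistanceProfile(reference_id=0, distances=d)
            p = reference_probability(float(rng.gamma(2.0, 1.0)), prof)
            assert 0.0 <= p <= 1.0

    def test_degenerate_all_equal(self):
        prof = DistanceProfile(reference_id=0, distances=np.full(5, 3.0))
        assert prof.bandwidth > 0
        assert reference_probability(3.0, prof) == pytest.approx(1.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            DistanceProfile(reference_id=0, distances=np.array([]))


class TestValidateRule:
    def _cand(self, Q, cluster=0):
        c = CandidateRegion(
            pixels=np.array([0]), shape=(8, 8), source="upper_region",
            cluster_id=cluster,
        )
        c.Q = Q
        return c

    def test_relative_accept(self):
        cand = self._cand(0.9)
        co = [cand, self._cand(1.0)]
        q, label = validate_candidate(cand, None, co, ValidationParams())
        assert label == "F"  # 0.9 > 0.6 * 1.0 and 0.9 > 0.4

    def test_alone_reject(self):
        cand = self._cand(0.3)
        q, label = validate_candidate(cand, None, [cand], ValidationParams())
        assert label == "B"  # 0.3 <= alpha2 = 0.4

    def test_alone_accept(self):
        cand = self._cand(0.5)
        _, label = validate_candidate(cand, None, [cand], ValidationParams())
        assert label == "F"

    def test_relative_reject(self):
        cand = self._cand(0.5)
        co = [cand, self._cand(0.95)]
        _, label = validate_candidate(cand, None, co, ValidationParams())
        assert label == "B"  # 0.5 <= 0.6 * 0.95

    def test_requires_Q(self):
        cand = self._cand(None)
        with pytest.raises(ValueError):
            validate_candidate(cand, None, [cand], ValidationParams())


class _StubPixelModel:
    def __init__(self, fg=False):
        self.trained = True
        self.fg = fg

    def predict(self, X):
        return np.full(len(X), self.fg, bool)


class TestIdentifyCandidates:
    def _cluster(self, shape=(32, 32)):
        rr, cc = np.mgrid[4:28, 4:28]
        pix = np.ravel_multi_index((rr.ravel(), cc.ravel()), shape)
        cluster = InterestRegion(0, pix, shape, "lower")
        u1 = InterestRegion(1, pix[:40], shape, "upper", parent_id=0)
        u2 = InterestRegion(2, pix[60:100], shape, "upper", parent_id=0)
        return cluster, [u1, u2]

    def test_uppers_only(self):
        cluster, uppers = self._cluster()
        im = np.zeros((32, 32), np.uint8)
        cands = identify_candidates(cluster, im, _StubPixelModel(fg=False), uppers)
        assert len(cands) == 2
        assert all(c.source == "upper_region" for c in cands)

    def test_all_background_no_uppers(self):
        cluster, _ = self._cluster()
        im = np.zeros((32, 32), np.uint8)
        cands = identify_candidates(cluster, im, _StubPixelModel(fg=False), [])
        assert cands == []

    def test_untrained_model_rejected(self):
        cluster, uppers = self._cluster()
        with pytest.raises(ValueError):
            identify_candidates(cluster, np.zeros((32, 32), np.uint8), None, uppers)

    def test_fg_components_not_overlapping_uppers(self):
        cluster, uppers = self._cluster()
        im = np.zeros((32, 32), np.uint8)
        cands = identify_candidates(cluster, im, _StubPixelModel(fg=True), uppers)
        pc = [c for c in cands if c.source == "pixel_classification"]
        upper_pix = set(np.concatenate([u.pixels for u in uppers]).tolist())
        for c in pc:
            assert not (set(c.pixels.tolist()) & upper_pix)


def _khachiyan_oracle(points, tol=1e-7):
    """Independent MVEE implementation (dual form, no hull reduction)."""
    P = np.asarray(points, float)
    n, d = P.shape
    Q = np.vstack([P.T, np.ones(n)])
    u = np.full(n, 1.0 / n)
    err = 1.0
    while err > tol:
        X = Q @ np.diag(u) @ Q.T
        M = np.diag(Q.T @ np.linalg.inv(X) @ Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1) * (M[j] - 1.0))
        nu = (1 - step) * u
        nu[j] += step
        err = np.linalg.norm(nu - u)
        u = nu
    c = P.T @ u
    A = np.linalg.inv(P.T @ np.diag(u) @ P - np.outer(c, c)) / d
    return c, A


class TestMVEE:
    def test_square_contains_all_points(self):
        pts = np.array([[r, c] for r in range(4) for c in range(4)], float)
        c, A = mvee(pts)
        q = np.einsum("ij,jk,ik->i", pts - c, A, pts - c)
        assert (q <= 1.0 + 1e-6).all()

    def test_square_area_near_oracle(self):
        pts = np.array([[0, 0], [0, 3], [3, 0], [3, 3]], float)
        c, A = mvee(pts, tol=1e-7)
        co, Ao = _khachiyan_oracle(pts)
        area = np.pi / math.sqrt(np.linalg.det(A))
        area_o = np.pi / math.sqrt(np.linalg.det(Ao))
        assert area == pytest.approx(area_o, rel=1e-2)
        # the MVEE of a square's corners is its circumscribed circle
        assert area_o == pytest.approx(np.pi * (3 * math.sqrt(2) / 2) ** 2, rel=1e-2)


class TestCompleteEllipse:
    def _cluster_covering(self, shape):
        pix = np.arange(shape[0] * shape[1])
        return InterestRegion(0, pix, shape, "lower")

    def test_filled_ellipse_fixed_point(self):
        shape = (40, 40)
        rr, cc = np.mgrid[:40, :40]
        ell = ((rr - 20) / 10.0) ** 2 + ((cc - 20) / 6.0) ** 2 <= 1
        cand = CandidateRegion(
            pixels=np.flatnonzero(ell.ravel()), shape=shape,
            source="pixel_classification", cluster_id=0,
        )
        before = set(cand.pixels.tolist())
        out = complete_ellipse(cand, self._cluster_covering(shape))
        assert out.ellipse_completed
        added = set(out.pixels.tolist()) - before
        # fixed point within rasterization tolerance: additions hug the rim
        assert len(added) <= 0.2 * len(before)
        assert before <= set(out.pixels.tolist())

    def test_half_moon_stays_in_cluster(self):
        shape = (40, 40)
        rr, cc = np.mgrid[:40, :40]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
        half = disk & (cc <= 20)
        cluster_pix = np.flatnonzero(((rr < 30)).ravel())
        cluster = InterestRegion(0, cluster_pix, shape, "lower")
        cand = CandidateRegion(
            pixels=np.intersect1d(np.flatnonzero(half.ravel()), cluster_pix),
            shape=shape, source="pixel_classification", cluster_id=0,
        )
        out = complete_ellipse(cand, cluster)
        assert set(out.pixels.tolist()) <= set(cluster_pix.tolist())

    def test_degenerate_unchanged(self):
        shape = (20, 20)
        cand = CandidateRegion(
            pixels=np.array([0, 1]), shape=shape,
            source="pixel_classification", cluster_id=0,
        )
        cluster = InterestRegion(0, np.arange(400), shape, "lower")
        out = complete_ellipse(cand, cluster)
        assert not out.ellipse_completed
        assert np.array_equal(out.pixels, [0, 1])


class TestReferenceSetAndProcess:
    def test_permutation_invariance(self, rng):
        hists = [_hist(rng.random(64), rng.random(12)) for _ in range(6)]
        regions = [
            InterestRegion(i, np.array([i * 20 + j for j in range(4)]), (40, 40),
                           "single")
            for i in range(6)
        ]
        refs = ReferenceSet(regions, hists, (40, 40))
        target = _hist(rng.random(64), rng.random(12))
        sel = [0, 2, 4]
        p1 = refs.probability(target, sel)
        p2 = refs.probability(target, list(reversed(sel)))
        assert p1 == pytest.approx(p2)
        assert 0.0 <= p1 <= 1.0

    def test_pass_through_singles_only(self, trained_models):
        shape = (64, 64)
        regions = [
            InterestRegion(0, np.arange(100), shape, "single"),
            InterestRegion(1, np.arange(200, 300), shape, "single"),
        ]
        h = RegionHierarchy(regions, shape=shape)
        im = np.full(shape, 90, np.uint8)
        out = decluster_process(im, h, trained_models, ValidationParams())
        assert len(out) == 2
        assert all(d.provenance == "single" for d in out)

    def test_quadrant_fallback(self, rng):
        # all references in one quadrant; candidate in another quadrant
        hists = [_hist(rng.random(64), rng.random(12)) for _ in range(4)]
        regions = [
            InterestRegion(i, np.array([i]), (100, 100), "single")
            for i in range(4)
        ]  # centroids all in the top-left quadrant
        refs = ReferenceSet(regions, hists, (100, 100))
        sel = refs.indices_near((90.0, 90.0))
        assert len(sel) == 4
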