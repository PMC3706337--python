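"""Deterministic synthetic fluorescence-microscopy fixtures.

Generates 8-bit grayscale images of elliptical nuclei with controllable
intensity inhomogeneity (per-nucleus mean, radial falloff, speckle), an
intensity-varying background, bright nucleus-like distractor blobs, and
exact instance ground truth.  Every stage of the localization pipeline is
testable against these fixtures without any external dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "generate_suite",
    "save_fixture",
    "load_spec",
    "save_spec",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic image.

    All intensities are on the 8-bit scale [0, 255].
    """

    image_size: tuple[int, int] = (256, 256)
    n_nuclei: int = 10
    nucleus_axes_range: tuple[float, float] = (6.0, 11.0)
    nucleus_mean_intensity_range: tuple[float, float] = (130.0, 180.0)
    intra_nucleus_gradient: float = 0.45
    background_base: float = 25.0
    n_bright_blobs: int = 0
    blob_intensity_range: tuple[float, float] = (225.0, 252.0)
    touching_fraction: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0
    # multiplicative speckle amplitude inside nuclei (texture cue for the
    # pixel classifier); 0 disables and keeps mean intensities exact
    speckle: float = 0.0
    # distractor blobs sit on a dim halo so they nest as two-level regions
    blob_halo: bool = True
    background_variation: float = 5.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size must be at least 16x16")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.nucleus_axes_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_axes_range must satisfy 0 < min <= max")
        for name in ("nucleus_mean_intensity_range", "blob_intensity_range"):
            a, b = getattr(self, name)
            if not (0 <= a <= b <= 255):
                raise ValueError(f"{name} must lie within [0, 255]")
        if not 0 <= self.intra_nucleus_gradient <= 1:
            raise ValueError("intra_nucleus_gradient must be in [0, 1]")
        if not 0 <= self.background_base <= 255:
            raise ValueError("background_base must be in [0, 255]")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.speckle < 0:
            raise ValueError("noise_sd and speckle must be >= 0")
        if self.n_bright_blobs < 0:
            raise ValueError("n_bright_blobs must be >= 0")


@dataclass
class Fixture:
    """A generated image with its exact ground truth."""

    image: np.ndarray  # uint8, (H, W)
    truth: np.ndarray  # int32 instance labels, 0 = background
    distractor_mask: np.ndarray  # bool, bright background blobs
    spec: FixtureSpec

    def __post_init__(self) -> None:
        assert self.image.shape == self.truth.shape == self.distractor_mask.shape
        assert not (self.distractor_mask & (self.truth > 0)).any()


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask plus the normalized elliptical radius field."""
    h, w = shape
    r0, c0 = center
    rr, cc = np.mgrid[0:h, 0:w]
    dr, dc = rr - r0, cc - c0
    ct, st = np.cos(theta), np.sin(theta)
    x = dr * ct + dc * st
    y = -dr * st + dc * ct
    rho2 = (x / a) ** 2 + (y / b) ** 2
    return rho2 <= 1.0, rho2


def _place_centers(spec: FixtureSpec, axes: np.ndarray, rng: np.random.Generator):
    """Place nucleus centers; a touching_fraction of them adjacent to a
    previously placed nucleus (center distance = sum of semi-minor axes + 1)."""
    h, w = spec.image_size
    n = spec.n_nuclei
    n_touch = int(round(spec.touching_fraction * n)) if n > 1 else 0
    centers: list[tuple[float, float]] = []
    max_attempts = 2000
    for i in range(n):
        a, b = axes[i]
        pad = max(a, b) + 2
        placed = False
        touch = i > 0 and i >= n - n_touch
        for _ in range(max_attempts):
            if touch:
                j = int(rng.integers(len(centers)))
                ang = rng.uniform(0, 2 * np.pi)
                d = min(axes[j]) + min(a, b) + 1.0
                r0 = centers[j][0] + d * np.cos(ang)
                c0 = centers[j][1] + d * np.sin(ang)
                if not (pad <= r0 < h - pad and pad <= c0 < w - pad):
                    continue
                min_dist_ok = all(
                    np.hypot(r0 - rj, c0 - cj) >= (d - 0.5 if (rj, cj) == centers[j]
                                                   else min(a, b))
                    for rj, cj in centers
                )
            else:
                r0 = rng.uniform(pad, h - pad)
                c0 = rng.uniform(pad, w - pad)
                min_dist_ok = all(
                    np.hypot(r0 - rj, c0 - cj) >= max(a, b) + max(axes[k]) + 3
                    for k, (rj, cj) in enumerate(centers)
                )
            if min_dist_ok:
                centers.append((r0, c0))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{n} within {max_attempts} attempts; "
                "reduce n_nuclei or nucleus_axes_range"
            )
    return centers


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Render one synthetic image per the spec; bitwise-deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    shape = (h, w)

    # smooth intensity-varying background
    img = np.full(shape, spec.background_base, dtype=np.float64)
    if spec.background_variation > 0:
        coarse = rng.normal(0.0, spec.background_variation, size=(5, 5))
        from scipy.ndimage import zoom

        fieldv = zoom(coarse, (h / 5, w / 5), order=3)[:h, :w]
        img += fieldv

    lo, hi = spec.nucleus_axes_range
    axes = rng.uniform(lo, hi, size=(spec.n_nuclei, 2))
    thetas = rng.uniform(0, np.pi, size=spec.n_nuclei)
    means = rng.uniform(*spec.nucleus_mean_intensity_range, size=spec.n_nuclei)
    centers = _place_centers(spec, axes, rng)

    truth = np.zeros(shape, dtype=np.int32)
    # per-pixel rho2 of the owning nucleus, for contested-pixel resolution
    best_rho = np.full(shape, np.inf)
    g = spec.intra_nucleus_gradient
    for i in range(spec.n_nuclei):
        a, b = axes[i]
        mask, rho2 = _ellipse_mask(shape, centers[i], a, b, thetas[i])
        # radial falloff with unit disk-average: scale so the spatial mean
        # over the ellipse equals the drawn mean exactly when g > 0 too
        profile = 1.0 - g * rho2
        profile = profile / max(profile[mask].mean(), 1e-9)
        vals = means[i] * profile
        if spec.speckle > 0:
            tex = rng.normal(1.0, spec.speckle, size=shape)
            vals = vals * tex
        claim = mask & (rho2 < best_rho)
        img[claim] = vals[claim]
        truth[claim] = i + 1
        best_rho[claim] = rho2[claim]

    distractor = np.zeros(shape, dtype=bool)
    blo, bhi = spec.blob_intensity_range
    for _ in range(spec.n_bright_blobs):
        rad = rng.uniform(0.6 * lo, 0.9 * hi)
        for _ in range(2000):
            r0 = rng.uniform(2.5 * rad, h - 2.5 * rad)
            c0 = rng.uniform(2.5 * rad, w - 2.5 * rad)
            bmask, brho2 = _ellipse_mask(shape, (r0, c0), 2.4 * rad, 2.4 * rad, 0.0)
            if not (bmask & (truth > 0)).any() and not (bmask & distractor).any():
                break
        else:
            raise RuntimeError("could not place bright blob without overlap")
        inten = rng.uniform(blo, bhi)
        if spec.blob_halo:
            # dim plateau under the blob -> MSER nests blob inside halo
            halo = bmask & ~ (brho2 <= (1 / 2.4) ** 2)
            img[halo] = np.maximum(img[halo], 0.38 * inten)
        core = brho2 <= (1 / 2.4) ** 2
        img[core] = inten
        distractor |= core

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Fixture(image=img8, truth=truth, distractor_mask=distractor, spec=spec)


def generate_suite(n_images: int, spec: FixtureSpec, seed: int) -> list[Fixture]:
    """n_images fixtures with per-image seeds derived from (seed, index)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    child = np.random.SeedSequence(seed).generate_state(n_images)
    out = []
    for i in range(n_images):
        s = dataclasses.replace(spec, seed=int(child[i]))
        out.append(generate_fixture(s))
    return out


# ---------------------------------------------------------------- I/O


def save_fixture(fix: Fixture, image_path: str, truth_path: str | None = None) -> None:
    """Image as 8-bit PNG/TIFF; truth as 16-bit instance-label TIFF."""
    if image_path.endswith((".tif", ".tiff")):
        tifffile.imwrite(image_path, fix.image)
    else:
        iio.imwrite(image_path, fix.image)
    if truth_path is not None:
        tifffile.imwrite(truth_path, fix.truth.astype(np.uint16))


def save_spec(spec: FixtureSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh)


def load_spec(path: str) -> FixtureSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("image_size", "nucleus_axes_range", "nucleus_mean_intensity_range",
                "blob_intensity_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return FixtureSpec(**raw)
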