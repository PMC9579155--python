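"""Seeded synthetic data emulating the two inputs of the CAD pipeline.

Two generators make every downstream stage testable without CT data:

* :func:`gen_images` draws 64x64 8-bit patches — bright elliptical blobs on
  a dark background for nodule-like positives, and elongated bright streaks
  for vessel-like negatives — with additive Gaussian noise.
* :func:`gen_feature_pair` draws two feature blocks that share latent
  factors with planted canonical correlations and an optional
  class-separating mean shift, mimicking what two deep extractors produce
  for the same samples.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from skimage import draw, morphology

from .fusion import FeatureBlock
from .preprocess import NEGATIVE, POSITIVE, ROI_SIZE, RoiImage

__all__ = ["ImageGenSpec", "FeatureGenSpec", "gen_images", "gen_feature_pair"]


@dataclass
class ImageGenSpec:
    """Geometry and noise of the toy nodule/vessel image generator.

    Radii, lengths and widths are in pixels on a 64x64 canvas; ``noise_sd``
    is the additive Gaussian noise in 8-bit intensity units.
    """

    n_pos: int = 10
    n_neg: int = 10
    blob_radius: tuple[float, float] = (6.0, 12.0)
    streak_length: tuple[float, float] = (20.0, 40.0)
    streak_width: tuple[int, int] = (2, 4)
    noise_sd: float = 8.0
    background: int = 30
    foreground: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be nonnegative")
        if self.blob_radius[1] >= ROI_SIZE // 2:
            raise ValueError("blob radius must fit inside the canvas")
        if self.streak_length[1] >= ROI_SIZE * 1.5:
            raise ValueError("streak length too large for the canvas")


def _finish(canvas: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def gen_images(spec: ImageGenSpec) -> list[RoiImage]:
    """Generate nodule-like positives and vessel-like negatives."""
    rng = np.random.default_rng(spec.seed)
    out: list[RoiImage] = []
    c = ROI_SIZE // 2
    for i in range(spec.n_pos):
        canvas = np.full((ROI_SIZE, ROI_SIZE), float(spec.background))
        r1 = rng.uniform(*spec.blob_radius)
        r2 = rng.uniform(*spec.blob_radius)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(c, c, r1, r2, shape=canvas.shape, rotation=rot)
        canvas[rr, cc] = spec.foreground
        out.append(RoiImage(pixels=_finish(canvas, spec.noise_sd, rng),
                            label=POSITIVE, source_id=f"pos{i:04d}"))
    for i in range(spec.n_neg):
        canvas = np.full((ROI_SIZE, ROI_SIZE), float(spec.background))
        length = rng.uniform(*spec.streak_length)
        width = int(rng.integers(spec.streak_width[0], spec.streak_width[1] + 1))
        angle = rng.uniform(0, np.pi)
        r0 = c + rng.integers(-10, 11)
        c0 = c + rng.integers(-10, 11)
        dr, dc = length / 2 * np.sin(angle), length / 2 * np.cos(angle)
        rr, cc = draw.line(int(np.clip(r0 - dr, 0, ROI_SIZE - 1)),
                           int(np.clip(c0 - dc, 0, ROI_SIZE - 1)),
                           int(np.clip(r0 + dr, 0, ROI_SIZE - 1)),
                           int(np.clip(c0 + dc, 0, ROI_SIZE - 1)))
        line = np.zeros(canvas.shape, bool)
        line[rr, cc] = True
        streak = morphology.dilation(line, morphology.disk(max(width // 2, 1)))
        canvas[streak] = spec.foreground * 0.9
        out.append(RoiImage(pixels=_finish(canvas, spec.noise_sd, rng),
                            label=NEGATIVE, source_id=f"neg{i:04d}"))
    return out


@dataclass
class FeatureGenSpec:
    """Paired feature blocks with planted canonical correlations.

    ``s`` shared latent factors have target correlations ``rho`` (descending,
    in (0,1)) between the two views; ``delta`` is the class mean separation
    in latent standard-deviation units (0 disables the class signal);
    ``noise_sd`` is isotropic feature noise added after the orthonormal
    loadings.  Defaults mirror the scale of the fused deep-feature study:
    two 98-dimensional blocks over ~1100 samples with three strong shared
    factors.
    """

    n: int = 1140
    p: int = 98
    q: int = 98
    s: int = 3
    rho: tuple[float, ...] = (0.9, 0.7, 0.5)
    delta: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s > min(self.p, self.q):
            raise ValueError("shared latent count must be <= min(p, q)")
        if len(self.rho) != self.s:
            raise ValueError("need one target correlation per shared latent")
        if any(not 0 < r < 1 for r in self.rho):
            raise ValueError("target correlations must lie in (0, 1)")
        if list(self.rho) != sorted(self.rho, reverse=True):
            raise ValueError("target correlations must be descending")


def _random_orthonormal(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """rows x cols matrix with orthonormal rows (rows <= cols)."""
    a = rng.normal(size=(cols, rows))
    q, _ = linalg.qr(a, mode="economic")
    return q.T


def gen_feature_pair(spec: FeatureGenSpec) -> tuple[FeatureBlock, FeatureBlock, np.ndarray]:
    """Draw (M, N, labels) with planted cross-view correlation structure.

    Shared latents h ~ N(0, I_s); view M scores z_m = h, view N scores
    z_n = rho*h + sqrt(1 - rho^2)*eps, so corr(z_m, z_n) = rho per factor.
    The class signal (labels balanced, -1/+1) adds the same mean shift
    ``delta/2 * y`` to every latent score of *both* views, so each view
    carries the full class separation and fusing them genuinely helps.
    Latents map to features through random orthonormal loadings plus
    isotropic noise, so with delta = 0 the population canonical correlations
    approximate ``rho``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.ones(spec.n, dtype=int)
    labels[: spec.n // 2] = -1
    rng.shuffle(labels)

    h = rng.normal(size=(spec.n, spec.s))
    eps = rng.normal(size=(spec.n, spec.s))
    rho = np.asarray(spec.rho)
    shift = (spec.delta / 2.0) * labels[:, None]
    z_m = h + shift
    z_n = rho * h + np.sqrt(1.0 - rho**2) * eps + shift

    a = _random_orthonormal(spec.s, spec.p, rng)
    b = _random_orthonormal(spec.s, spec.q, rng)
    m = z_m @ a + spec.noise_sd * rng.normal(size=(spec.n, spec.p))
    n = z_n @ b + spec.noise_sd * rng.normal(size=(spec.n, spec.q))
    return (FeatureBlock(matrix=m, provenance="synthetic-view-m"),
            FeatureBlock(matrix=n, provenance="synthetic-view-n"),
            labels)
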