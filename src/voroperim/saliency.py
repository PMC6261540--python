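"""Saliency maps: which parts of a visual field drive the classifier score.

Three maps, all 61x61 like the voronoi image they explain:

* *gradient*: the raw partial derivative of the EG-probability output with
  respect to each input pixel;
* *SmoothGrad*: the average of gradient maps over ``n`` Gaussian-perturbed
  copies of the image, with per-image noise scale
  ``sigma = sigma_r * (VI_max - VI_min)`` — less noisy, easier to read;
* *piece-wise*: the SmoothGrad map averaged within each voronoi region, one
  value per tested location.

Maps are signed as computed and usually min-max normalized to [0, 1]
(0 = no influence, 1 = maximal influence) before display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voronoi import RegionMap, VoronoiImage


@dataclass(frozen=True)
class SaliencyConfig:
    """SmoothGrad settings: ``n`` perturbed samples at noise ratio ``sigma_r``."""

    n: int = 500
    sigma_r: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be >= 0")


@dataclass(frozen=True)
class SaliencyMap:
    values: np.ndarray
    kind: str  # gradient | smoothgrad | piecewise
    normalized: bool = False


def _image_values(vi) -> np.ndarray:
    values = vi.values if isinstance(vi, VoronoiImage) else np.asarray(vi, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D image")
    return values


def gradient_map(model, vi) -> SaliencyMap:
    """Raw signed input-gradient of the model's EG probability.

    ``model`` must expose ``input_gradient(batch)`` returning per-pixel
    derivatives (any differentiable scorer works, not just the package CNN).
    """
    values = _image_values(vi)
    grad = np.asarray(model.input_gradient(values[None, :, :, None]))[0, :, :, 0]
    return SaliencyMap(values=grad, kind="gradient")


def smoothgrad(model, vi, config: SaliencyConfig = SaliencyConfig(), batch: int = 64) -> SaliencyMap:
    """SmoothGrad: mean input-gradient over Gaussian-perturbed images.

    The noise standard deviation is ``sigma_r`` times the image's value
    range, so a constant image gets sigma = 0 and the map degenerates to the
    plain gradient.  Seeded and therefore bit-reproducible.
    """
    values = _image_values(vi)
    sigma = config.sigma_r * (values.max() - values.min())
    if sigma == 0.0:
        base = np.asarray(model.input_gradient(values[None, :, :, None]))[0, :, :, 0]
        return SaliencyMap(values=base, kind="smoothgrad")
    rng = np.random.default_rng(config.seed)
    total = np.zeros_like(values)
    remaining = config.n
    while remaining > 0:
        b = min(batch, remaining)
        noisy = values[None, :, :, None] + rng.normal(0.0, sigma, size=(b, *values.shape, 1))
        grads = np.asarray(model.input_gradient(noisy))
        total += grads.sum(axis=0)[:, :, 0]
        remaining -= b
    return SaliencyMap(values=total / config.n, kind="smoothgrad")


def piecewise_map(smooth: SaliencyMap, region_map: RegionMap) -> SaliencyMap:
    """Average a map within each voronoi region (one value per location)."""
    values = np.asarray(smooth.values, dtype=float)
    if values.shape != region_map.assignment.shape:
        raise ValueError("saliency map and region map dimensions disagree")
    flat = region_map.assignment.ravel()
    sums = np.bincount(flat, weights=values.ravel(), minlength=region_map.n_seeds)
    counts = np.bincount(flat, minlength=region_map.n_seeds)
    means = np.zeros(region_map.n_seeds)
    occupied = counts > 0
    means[occupied] = sums[occupied] / counts[occupied]
    return SaliencyMap(values=means[region_map.assignment], kind="piecewise",
                       normalized=smooth.normalized)


def normalize_map(raw: SaliencyMap) -> SaliencyMap:
    """Min-max rescale to [0, 1]; a constant map becomes all zeros."""
    values = np.asarray(raw.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("saliency map contains non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        scaled = np.zeros_like(values)
    else:
        scaled = (values - lo) / (hi - lo)
    return SaliencyMap(values=scaled, kind=raw.kind, normalized=True)
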