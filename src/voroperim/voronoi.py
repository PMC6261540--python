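"""Rasterizing a visual field into a 61x61 voronoi image.

Every pixel of a fixed 61x61 grid covering [-30, 30] degrees squared at one
degree per pixel is assigned to its nearest test location (seed) in degree
space; the pixel then takes that location's sensitivity-deviation value.
The result is a piece-wise constant image V with V(i, j) = r_{l*} where
l* minimizes the Euclidean distance between pixel (i, j) and seed l — an
image representation of perimetric data that is independent of the test
pattern used, and needs no pre-smoothing before convolutional processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import TestPattern, VisualFieldRecord

GRID_SIZE = 61
_CENTER = 31  # 1-based pixel index of the field origin (0 deg, 0 deg)


def pixel_to_degrees(i, j):
    """Map 1-based image indices (row i, col j) to field degrees (x, y).

    The convention is x = j - 31 (temporal positive) and y = 31 - i
    (superior positive): the origin (0, 0) degrees sits at pixel (31, 31)
    and pixel (1, 1) is the top-left corner (-30, +30).
    """
    i = np.asarray(i)
    j = np.asarray(j)
    return j - _CENTER, _CENTER - i


def grid_coordinates() -> tuple[np.ndarray, np.ndarray]:
    """Degree coordinates (X, Y) of every pixel, each of shape (61, 61)."""
    ii, jj = np.meshgrid(np.arange(1, GRID_SIZE + 1), np.arange(1, GRID_SIZE + 1), indexing="ij")
    x, y = pixel_to_degrees(ii, jj)
    return x.astype(float), y.astype(float)


@dataclass(frozen=True)
class RegionMap:
    """Nearest-seed assignment of every pixel.

    ``assignment[i, j]`` holds the 0-based index of the pattern location
    owning pixel (i+1, j+1); ``region_sizes[l]`` counts its pixels (zero for
    seeds excluded from seeding, e.g. blind-spot locations by default).
    """

    assignment: np.ndarray
    region_sizes: np.ndarray

    @property
    def n_seeds(self) -> int:
        return self.region_sizes.size

    def region_pixels(self, l: int) -> np.ndarray:
        """Boolean mask of the pixels belonging to region ``l``."""
        return self.assignment == l


@dataclass(frozen=True)
class VoronoiImage:
    """A rasterized visual field: 61x61 dB values plus its region structure."""

    values: np.ndarray
    region_map: RegionMap
    source: Optional[VisualFieldRecord] = None


def region_assignment(pattern: TestPattern, include_blind_spot: bool = False) -> RegionMap:
    """Assign every pixel of the 61x61 grid to its nearest pattern location.

    Distances are Euclidean in degree space.  A pixel equidistant from two or
    more seeds goes to the lowest seed index, which makes the assignment
    deterministic and independent of floating-point summation order.  Blind
    spot locations are excluded from seeding by default (their territory
    falls to neighboring seeds); pass ``include_blind_spot=True`` to seed
    them too.  The assignment depends only on seed coordinates, never on
    deviation values.
    """
    mask = np.ones(pattern.L, bool) if include_blind_spot else pattern.usable
    seed_idx = np.flatnonzero(mask)
    if seed_idx.size == 0:
        raise ValueError("pattern has no usable seeds (all locations excluded)")
    X, Y = grid_coordinates()
    dx = X[:, :, None] - pattern.x[seed_idx][None, None, :]
    dy = Y[:, :, None] - pattern.y[seed_idx][None, None, :]
    d2 = dx * dx + dy * dy
    # argmin returns the first (lowest-index) minimizer: the tie rule for free
    nearest = np.argmin(d2, axis=2)
    assignment = seed_idx[nearest]
    sizes = np.bincount(assignment.ravel(), minlength=pattern.L)
    return RegionMap(assignment=assignment, region_sizes=sizes)


def to_voronoi_image(record: VisualFieldRecord, region_map: RegionMap) -> VoronoiImage:
    """Render a record as a voronoi image: V(i, j) = r at the pixel's seed."""
    if record.deviations.size != region_map.n_seeds:
        raise ValueError(
            f"record has {record.deviations.size} deviations but the region map "
            f"was built from a pattern with {region_map.n_seeds} locations"
        )
    values = record.deviations[region_map.assignment]
    return VoronoiImage(values=values, region_map=region_map, source=record)


def save_matrix(image_values: np.ndarray, path) -> None:
    """Write a 61x61 value grid as a tab-separated text matrix."""
    np.savetxt(path, np.asarray(image_values), fmt="%.6g", delimiter="\t")


def save_png(image_values: np.ndarray, path, cmap: str = "RdYlBu", title: str = "") -> None:
    """Render a value grid to a color-mapped PNG for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(image_values), cmap=cmap, extent=(-30.5, 30.5, -30.5, 30.5))
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
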