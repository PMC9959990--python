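"""Improved local-binary-pattern texture descriptor.

Two codes are computed at every pixel from its circular neighbourhood of
``P`` samples at radius ``R`` (bilinear-interpolated, indexed
counter-clockwise from the east neighbour):

* **adaptive magnitude code** — let ``d_p = g_p - g_c`` be the neighbour
  minus centre differences and ``sigma`` their population standard
  deviation; bit ``p`` is set iff ``d_p >= sigma``.  On a perfectly flat
  patch ``sigma = 0`` and every ``d_p = 0``, so all bits are set: constant
  regions map to the full code ``2**P - 1`` by convention, which keeps them
  distinguishable from edges.
* **direction code** — for each opposite-neighbour axis (east-west,
  northeast-southwest, north-south, northwest-southeast for ``P = 8``) the
  bit is set iff the absolute difference across the axis exceeds the same
  ``sigma``.

Both codes depend only on intensity *differences*, so the whole descriptor
is invariant under global gray-level shifts.  The per-image feature vector
is the concatenation of the two normalized code histograms over the masked
interior pixels (pixels within ``R`` of the border are skipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass(frozen=True)
class LbpParams:
    radius: int = 1
    neighbours: int = 8

    def validate(self) -> None:
        if self.neighbours not in (4, 8, 16):
            raise ValueError("neighbours must be one of 4, 8, 16")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def n_axes(self) -> int:
        return self.neighbours // 2

    @property
    def n_bins(self) -> int:
        return 2**self.neighbours + 2**self.n_axes

    def bin_names(self) -> list[str]:
        return [f"lbp_{k}" for k in range(2**self.neighbours)] + [
            f"dir_{k}" for k in range(2**self.n_axes)
        ]


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]


#: differences below this are treated as exact zero (bilinear interpolation
#: noise on 8-bit data is ~1e-13; true differences are >= 1 gray level)
_EPS = 1e-6


def _differences(patch: np.ndarray, center: float) -> tuple[np.ndarray, float]:
    d = np.asarray(patch, dtype=np.float64) - float(center)
    d[np.abs(d) < _EPS] = 0.0
    return d, float(d.std())  # population standard deviation


def adaptive_code(patch, center) -> int:
    """Magnitude code of one neighbourhood sample (see module docstring)."""
    d, sigma = _differences(patch, center)
    bits = d >= sigma
    return int(np.sum(bits * (1 << np.arange(len(d)))))


def direction_code(patch, center) -> int:
    """Axis code: bit per opposite pair, set iff |g_p - g_opposite| > sigma."""
    d, sigma = _differences(patch, center)
    p = len(d)
    if p % 2:
        raise ValueError("direction code needs an even neighbour count")
    half = p // 2
    bits = np.abs(d[:half] - d[half:]) > sigma
    return int(np.sum(bits * (1 << np.arange(half))))


def _neighbour_stack(img: np.ndarray, p: LbpParams) -> np.ndarray:
    """Bilinear neighbour samples for every pixel: shape (P, H, W)."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    stack = np.empty((p.neighbours, h, w), dtype=np.float64)
    for k in range(p.neighbours):
        theta = 2.0 * np.pi * k / p.neighbours  # CCW from east
        dr, dc = -p.radius * np.sin(theta), p.radius * np.cos(theta)
        stack[k] = ndi.map_coordinates(img, [rr + dr, cc + dc], order=1, mode="nearest")
    return stack


def extract_features(img: np.ndarray, mask: np.ndarray,
                     p: LbpParams | None = None) -> FeatureVector:
    """Pooled two-part LBP histogram over the masked interior of an image."""
    p = p or LbpParams()
    p.validate()
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    r = int(np.ceil(p.radius))
    effective = mask.copy()
    effective[:r], effective[-r:] = False, False
    effective[:, :r], effective[:, -r:] = False, False
    if not effective.any():
        raise ValueError("mask has no interior pixels at this radius")

    stack = _neighbour_stack(img, p)
    d = stack - img.astype(np.float64)[None]
    d[np.abs(d) < _EPS] = 0.0
    sigma = d.std(axis=0)

    weights = (1 << np.arange(p.neighbours)).reshape(-1, 1, 1)
    mag = ((d >= sigma[None]) * weights).sum(axis=0)

    half = p.n_axes
    axis_diff = np.abs(d[:half] - d[half:])
    wa = (1 << np.arange(half)).reshape(-1, 1, 1)
    dircode = ((axis_diff > sigma[None]) * wa).sum(axis=0)

    mag_hist = np.bincount(mag[effective].astype(np.int64), minlength=2**p.neighbours)
    dir_hist = np.bincount(dircode[effective].astype(np.int64), minlength=2**half)
    values = np.concatenate([
        mag_hist / mag_hist.sum(),
        dir_hist / dir_hist.sum(),
    ])
    return FeatureVector(values=values, names=p.bin_names())


def extract_feature_matrix(images, masks, p: LbpParams | None = None
                           ) -> tuple[np.ndarray, list[str]]:
    """Stack per-image feature vectors into an (n_images, n_bins) matrix."""
    p = p or LbpParams()
    rows = [extract_features(im, mk, p).values for im, mk in zip(images, masks)]
    return np.vstack(rows), p.bin_names()
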