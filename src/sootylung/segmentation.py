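"""Automatic single-seeded region growing (ASSRG) for lung-lobe segmentation.

The lung lobes are air-filled and hence dark on an 8-bit CT-like slice.
Each half of the image is segmented independently: a single seed is chosen
automatically — the central pixel if it is dark (< ``air_threshold``) and a
strict majority of its 8-neighbours are dark, otherwise candidates expand
outward from the centre in concentric square rings scanned clockwise from
the top-left — and the lobe is the connected set of pixels whose intensity
differs from the *seed* intensity by less than ``grow_threshold``.

Both comparisons are strict (``<``), and growth is anchored to the static
seed intensity rather than a running region mean; both choices are part of
the algorithm's contract and are relied on by the tests.

An Otsu threshold operation is provided as an optional global-thresholding
alternative/pre-check; the default pipeline uses ASSRG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


class NoAirRegion(RuntimeError):
    """No pixel in the (half-)image passes the dark-seed test."""


class DegenerateImage(ValueError):
    """Raised for inputs on which the operation is undefined (e.g. constant)."""


@dataclass(frozen=True)
class Seed:
    location: tuple[int, int]
    intensity: int


@dataclass(frozen=True)
class AssrgParams:
    """Tunables of the seeded growth.

    ``air_threshold`` is the strict dark/air cut (< 40 by convention on
    8-bit data).  ``grow_threshold`` bounds |pixel - seed| for inclusion; it
    is not fixed by the algorithm's description and defaults to 25, which
    separates air from soft tissue on the bundled phantoms.
    """

    air_threshold: int = 40
    dark_majority_fraction: float = 0.5
    grow_threshold: int = 25
    connectivity: int = 8

    def validate(self) -> None:
        if not 0 < self.air_threshold < 255:
            raise ValueError("air_threshold must lie in (0, 255)")
        if self.grow_threshold < 0:
            raise ValueError("grow_threshold must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0.0 <= self.dark_majority_fraction < 1.0:
            raise ValueError("dark_majority_fraction must lie in [0, 1)")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"need a 2-D image of at least 3x3 pixels, got shape {img.shape}")
    return img


def otsu_threshold(img: np.ndarray) -> int:
    """Threshold in [0, 255] maximizing between-class variance (256 bins).

    Ties are broken toward the smallest maximizing threshold.  A pixel is
    assigned to the lower class iff its intensity is <= the threshold.
    """
    img = np.asarray(img)
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256].astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateImage("Otsu threshold undefined on a constant image")
    omega = np.cumsum(hist) / total          # class-0 probability for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def split_lobes(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Split at the midline column into (left, right, (col offsets)).

    For odd widths the left half gets the smaller width.  Views are
    returned; callers must not mutate them.
    """
    img = _check_image(img)
    if img.shape[1] < 6:
        raise ValueError("image too narrow to split into lobes")
    mid = img.shape[1] // 2
    return img[:, :mid], img[:, mid:], (0, mid)


def _ring_offsets(radius: int) -> list[tuple[int, int]]:
    """Concentric square ring at Chebyshev distance ``radius``, clockwise
    from the top-left corner."""
    r = radius
    out: list[tuple[int, int]] = []
    out += [(-r, c) for c in range(-r, r + 1)]            # top row, left -> right
    out += [(rr, r) for rr in range(-r + 1, r + 1)]       # right col, top -> bottom
    out += [(r, c) for c in range(r - 1, -r - 1, -1)]     # bottom row, right -> left
    out += [(rr, -r) for rr in range(r - 1, -r, -1)]      # left col, bottom -> top
    return out


def _is_dark_majority(img: np.ndarray, r: int, c: int, p: AssrgParams) -> bool:
    if img[r, c] >= p.air_threshold:
        return False
    h, w = img.shape
    neigh = [
        img[rr, cc]
        for rr in (r - 1, r, r + 1)
        for cc in (c - 1, c, c + 1)
        if (rr, cc) != (r, c) and 0 <= rr < h and 0 <= cc < w
    ]
    dark = sum(1 for v in neigh if v < p.air_threshold)
    return dark > p.dark_majority_fraction * len(neigh)


def select_seed(lobe: np.ndarray, p: AssrgParams | None = None) -> Seed:
    """Automatic single-seed choice for one lobe half-image."""
    p = p or AssrgParams()
    p.validate()
    lobe = _check_image(lobe)
    h, w = lobe.shape
    cr, cc = h // 2, w // 2
    if _is_dark_majority(lobe, cr, cc, p):
        return Seed((cr, cc), int(lobe[cr, cc]))
    max_radius = max(cr, h - 1 - cr, cc, w - 1 - cc)
    for radius in range(1, max_radius + 1):
        for dr, dc in _ring_offsets(radius):
            r, c = cr + dr, cc + dc
            if 0 <= r < h and 0 <= c < w and _is_dark_majority(lobe, r, c, p):
                return Seed((r, c), int(lobe[r, c]))
    raise NoAirRegion(
        f"no pixel below intensity {p.air_threshold} with a dark neighbourhood majority"
    )


def region_grow(img: np.ndarray, seed: Seed, p: AssrgParams | None = None) -> np.ndarray:
    """Connected region of pixels with |intensity - seed intensity| < threshold.

    The seed pixel itself is always part of the mask; with
    ``grow_threshold=0`` the strict inclusion rule admits nothing else.
    """
    p = p or AssrgParams()
    p.validate()
    img = _check_image(img)
    r, c = seed.location
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"seed location {seed.location} outside image {img.shape}")
    candidate = np.abs(img.astype(np.int64) - int(seed.intensity)) < p.grow_threshold
    mask = np.zeros(img.shape, dtype=bool)
    mask[r, c] = True
    if not candidate[r, c]:
        return mask
    structure = ndi.generate_binary_structure(2, 2 if p.connectivity == 8 else 1)
    labels, _ = ndi.label(candidate, structure=structure)
    return labels == labels[r, c]


def segment_lungs(img: np.ndarray, p: AssrgParams | None = None
                  ) -> tuple[np.ndarray, np.ndarray, dict[str, Seed]]:
    """Run seed selection + growth per half; return full-image masks and seeds.

    Raises :class:`NoAirRegion` (tagged with the failing side) if a half
    contains no dark region.
    """
    p = p or AssrgParams()
    img = _check_image(img)
    left, right, (_, mid) = split_lobes(img)
    masks, seeds = [], {}
    for side, half, col0 in (("left", left, 0), ("right", right, mid)):
        try:
            seed = select_seed(half, p)
        except NoAirRegion as exc:
            raise NoAirRegion(f"{side} side: {exc}") from exc
        half_mask = region_grow(half, seed, p)
        full = np.zeros(img.shape, dtype=bool)
        full[:, col0: col0 + half.shape[1]] = half_mask
        masks.append(full)
        seeds[side] = Seed((seed.location[0], seed.location[1] + col0), seed.intensity)
    return masks[0], masks[1], seeds
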