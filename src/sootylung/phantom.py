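"""Synthetic axial chest-CT phantom generator with per-pixel ground truth.

Each phantom emulates the gross geometry of an axial chest-CT slice on an
8-bit intensity scale: a bright soft-tissue body ellipse, two dark
air-filled lung lobes (mirrored ellipses), and optionally a bright nodule
that is *isolated* (strictly interior to a lobe), *juxtapleural* (drawn over
lobe pixels touching the lobe border, carving a concavity into the dark
region), or *juxtavascular* (attached to a bright vessel strip entering the
lobe).  Additive Gaussian noise is applied after shape rasterization and
clipped to [0, 255].

Ground-truth lobe masks record the *air* region of each lobe — the lobe
ellipse minus any pixels overwritten by bright structures — which is exactly
the region an air-threshold segmentation can recover.

Class semantics on phantoms (a documented convention, not a claim about
real nodule morphology): ``benign`` is a small smooth disc, ``malignant`` a
larger disc with a lobulated margin built from satellite bumps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import imageio as sio

NODULE_KINDS = ("none", "isolated", "juxtapleural", "juxtavascular")


class PhantomSpecError(ValueError):
    """Raised when a :class:`PhantomSpec` violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Intensity ranges are closed 8-bit intervals; one base value per
    structure is drawn uniformly from the interval, then per-pixel Gaussian
    noise of standard deviation ``noise_sd`` is added to the whole image.
    """

    image_size: int = 256
    body_intensity_range: tuple[int, int] = (120, 200)
    air_intensity_range: tuple[int, int] = (5, 35)
    nodule_intensity_range: tuple[int, int] = (90, 180)
    nodule_kind: str = "none"
    nodule_radius_range: tuple[int, int] = (4, 12)
    vessel_width_range: tuple[int, int] = (2, 4)
    noise_sd: float = 2.0
    class_label: str = "normal"

    def validate(self) -> None:
        if self.image_size < 64:
            raise PhantomSpecError("image_size: must be >= 64 pixels")
        for name in ("body_intensity_range", "air_intensity_range", "nodule_intensity_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise PhantomSpecError(f"{name}: interval [{lo}, {hi}] invalid or empty")
        if self.air_intensity_range[1] >= 40:
            raise PhantomSpecError(
                "air_intensity_range: upper bound must stay below the 40-intensity air test"
            )
        if self.nodule_kind not in NODULE_KINDS:
            raise PhantomSpecError(f"nodule_kind: {self.nodule_kind!r} not in {NODULE_KINDS}")
        r_lo, r_hi = self.nodule_radius_range
        if not (1 <= r_lo <= r_hi < self.image_size // 4):
            raise PhantomSpecError("nodule_radius_range: must be non-empty and inside image bounds")
        w_lo, w_hi = self.vessel_width_range
        if not (1 <= w_lo <= w_hi):
            raise PhantomSpecError("vessel_width_range: must be a non-empty positive interval")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd: must be >= 0")
        if self.class_label not in sio.CLASS_LABELS:
            raise PhantomSpecError(f"class_label: {self.class_label!r} not in {sio.CLASS_LABELS}")
        if (self.class_label == "normal") != (self.nodule_kind == "none"):
            raise PhantomSpecError(
                "class_label: 'normal' iff nodule_kind 'none' (label/nodule consistency)"
            )


@dataclass
class PhantomSample:
    """One generated slice with its ground truth."""

    image: np.ndarray
    left_lobe_mask: np.ndarray
    right_lobe_mask: np.ndarray
    nodule_mask: np.ndarray
    label: str
    seed: int

    def lobe_mask(self) -> np.ndarray:
        return self.left_lobe_mask | self.right_lobe_mask


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _lobulated_disc(shape: tuple[int, int], center: tuple[float, float], radius: float,
                    rng: np.random.Generator,
                    bump_direction: float | None = None) -> np.ndarray:
    """Main disc plus 3-5 satellite bumps on its perimeter (irregular margin).

    With ``bump_direction`` set, bumps are confined to the half-perimeter
    facing that direction (used for pleura-attached nodules, whose wall side
    is flattened and whose irregular margin faces the parenchyma).
    """
    mask = _disc(shape, center, radius)
    if bump_direction is None:
        angles = rng.uniform(0.0, 2 * np.pi, size=rng.integers(3, 6))
    else:
        angles = bump_direction + rng.uniform(-np.pi / 2, np.pi / 2,
                                              size=rng.integers(3, 6))
    for ang in angles:
        bump_r = radius * rng.uniform(0.35, 0.55)
        bc = (center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang))
        mask |= _disc(shape, bc, bump_r)
    return mask


def _geometry(n: int) -> dict:
    """Body/lobe ellipse parameters, scaled from the 256-px reference layout."""
    s = n / 256.0
    return {
        "body_c": (n / 2.0, n / 2.0),
        "body_semi": (112 * s, 100 * s),
        "lobe_c": [(132 * s, 78 * s), (132 * s, (256 - 78) * s)],
        "lobe_semi": (72 * s, 38 * s),
    }


def _nodule_radius(spec: PhantomSpec, rng: np.random.Generator) -> float:
    r_lo, r_hi = spec.nodule_radius_range
    span = r_hi - r_lo
    if spec.class_label == "malignant":
        return float(rng.uniform(r_lo + 0.6 * span, r_hi))
    return float(rng.uniform(r_lo, r_lo + 0.4 * span))


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomSample:
    """Rasterize one phantom slice deterministically for ``(spec, seed)``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.image_size
    shape = (n, n)
    geo = _geometry(n)

    air_base = rng.uniform(*spec.air_intensity_range)
    body_base = rng.uniform(*spec.body_intensity_range)
    nodule_base = rng.uniform(max(spec.nodule_intensity_range[0], 90),
                              spec.nodule_intensity_range[1])
    vessel_base = rng.uniform(max(spec.nodule_intensity_range[0], 90),
                              spec.nodule_intensity_range[1])

    body = _ellipse(shape, geo["body_c"], geo["body_semi"])
    lobes = [_ellipse(shape, c, geo["lobe_semi"]) for c in geo["lobe_c"]]

    img = np.full(shape, air_base, dtype=np.float64)
    img[body] = body_base
    for lb in lobes:
        img[lb] = air_base

    nodule_mask = np.zeros(shape, dtype=bool)
    bright = np.zeros(shape, dtype=bool)  # vessel + nodule pixels (non-air)

    if spec.nodule_kind != "none":
        side = int(rng.integers(0, 2))
        lc, (sr, sc) = geo["lobe_c"][side], geo["lobe_semi"]
        radius = _nodule_radius(spec, rng)
        rng_shape = np.random.default_rng(rng.integers(0, 2**31))

        if spec.nodule_kind == "isolated":
            # strictly interior: centre on a shrunken ellipse so the nodule
            # (with lobulation slack) keeps a >=2 px margin to the lobe border
            margin = radius * (1.6 if spec.class_label == "malignant" else 1.0) + 2
            ang = rng.uniform(0.0, 2 * np.pi)
            t = rng.uniform(0.0, 1.0) ** 0.5
            center = (lc[0] + t * (sr - margin) * np.sin(ang),
                      lc[1] + t * (sc - margin) * np.cos(ang))
        elif spec.nodule_kind == "juxtapleural":
            # centre on the lobe boundary, in the lateral (chest-wall) sector
            # where the pleura is flat -> carves a bite of depth ~radius
            base = np.pi if side == 0 else 0.0
            ang = base + rng.uniform(-np.pi / 3, np.pi / 3)
            center = (lc[0] + sr * np.sin(ang), lc[1] + sc * np.cos(ang))
        else:  # juxtavascular: vessel strip from the medial border to the nodule
            w = int(rng.integers(spec.vessel_width_range[0], spec.vessel_width_range[1] + 1))
            row = lc[0] + rng.uniform(-0.3, 0.3) * sr
            # medial edge column of the lobe ellipse at this row
            half = sc * np.sqrt(max(0.0, 1 - ((row - lc[0]) / sr) ** 2))
            medial = lc[1] + half if side == 0 else lc[1] - half
            tip = lc[1] + rng.uniform(-0.15, 0.15) * sc
            c0, c1 = sorted((medial, tip))
            vessel = np.zeros(shape, dtype=bool)
            r0 = int(round(row - w / 2))
            vessel[max(r0, 0): r0 + w, int(np.floor(c0)): int(np.ceil(c1)) + 1] = True
            vessel &= lobes[side]
            img[vessel] = vessel_base
            bright |= vessel
            center = (row, tip)
            # keep the nodule itself clear of the lobe border
            radius = min(radius, float(sr) - 4, float(sc) - 4)

        if spec.class_label == "malignant":
            toward_centre = None
            if spec.nodule_kind == "juxtapleural":
                toward_centre = float(np.arctan2(lc[0] - center[0], lc[1] - center[1]))
            disc = _lobulated_disc(shape, center, radius, rng_shape, toward_centre)
        else:
            disc = _disc(shape, center, radius)
        nodule_mask = disc & lobes[side]
        img[disc & body] = nodule_base
        bright |= disc

    left_mask = lobes[0] & ~bright
    right_mask = lobes[1] & ~bright

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return PhantomSample(
        image=image,
        left_lobe_mask=left_mask,
        right_lobe_mask=right_mask,
        nodule_mask=nodule_mask,
        label=spec.class_label,
        seed=int(seed),
    )


def spec_for_class(label: str, kind: str | None = None, **overrides) -> PhantomSpec:
    """Convenience constructor pairing a class label with a consistent kind.

    ``normal`` forces ``nodule_kind='none'``; for the two nodule classes the
    kind defaults to ``isolated`` when not given.
    """
    if label == "normal":
        kind = "none"
    elif kind is None or kind == "none":
        kind = "isolated"
    return replace(PhantomSpec(), class_label=label, nodule_kind=kind, **overrides)


def _derive_seed(master_seed: int, index: int) -> int:
    """Counter-based per-sample seed derivation (parallel-safe, < 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


#: nodule kinds cycled through for the benign/malignant classes of a dataset
_DATASET_KINDS = ("isolated", "juxtapleural", "juxtavascular")


def generate_dataset(n_per_class: int, out_dir: str | Path, seed: int,
                     spec_overrides: dict | None = None) -> Path:
    """Write a balanced phantom dataset and return the manifest path.

    For the ``benign`` and ``malignant`` classes the nodule kind cycles
    deterministically through isolated / juxtapleural / juxtavascular.
    Per-sample seeds are derived from the master seed by a counter so the
    dataset reproduces bit-identically.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    overrides = dict(spec_overrides or {})

    rows = []
    index = 0
    for label in sio.CLASS_LABELS:
        for j in range(n_per_class):
            kind = "none" if label == "normal" else _DATASET_KINDS[j % len(_DATASET_KINDS)]
            spec = spec_for_class(label, kind, **overrides)
            sample_seed = _derive_seed(seed, index)
            sample = generate_phantom(spec, sample_seed)
            stem = f"{label}_{j:04d}"
            img_rel = f"images/{stem}.png"
            rels = {
                "lobe_left": f"masks/{stem}_lobe_left.png",
                "lobe_right": f"masks/{stem}_lobe_right.png",
                "nodule": f"masks/{stem}_nodule.png",
            }
            sio.save_image(sample.image, out_dir / img_rel)
            sio.save_mask(sample.left_lobe_mask, out_dir / rels["lobe_left"])
            sio.save_mask(sample.right_lobe_mask, out_dir / rels["lobe_right"])
            sio.save_mask(sample.nodule_mask, out_dir / rels["nodule"])
            rows.append({"path": img_rel, "label": label, **rels, "seed": sample_seed})
            index += 1
    return sio.write_manifest(rows, out_dir / "manifest.csv")
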