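"""Image, mask, and manifest I/O with the package-wide coordinate convention.

Every module in this package uses 0-based ``(row, col)`` indexing with row 0
at the top of the image.  Grayscale images are 2-D ``uint8`` arrays
(``GrayImage``); masks are 2-D boolean arrays of the same shape
(``BinaryMask``) and are persisted as 8-bit PNGs holding only the values
0 and 255.  Dataset manifests are CSV files with the header
``path,label,lobe_left,lobe_right,nodule,seed``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: The fixed three-class label vocabulary (the source data's "standard"
#: class is called "normal" here).
CLASS_LABELS = ("normal", "benign", "malignant")

MANIFEST_COLUMNS = ("path", "label", "lobe_left", "lobe_right", "nodule", "seed")


class FormatError(ValueError):
    """Raised when a file cannot be interpreted in the expected dialect."""


def _validate_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise FormatError(f"expected 8-bit intensities, got dtype {arr.dtype}")
    return arr


def load_image(path: str | Path, to_gray: bool = False) -> np.ndarray:
    """Load an 8-bit grayscale image (PNG/TIFF) or a single-frame DICOM slice.

    Parameters
    ----------
    path:
        File to read.  ``.dcm`` files are read through :mod:`pydicom` and
        min-max rescaled to 8-bit; everything else goes through Pillow.
    to_gray:
        If true, RGB(A) inputs are luminance-converted instead of rejected.

    Returns
    -------
    numpy.ndarray
        ``uint8`` array of shape ``(height, width)``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _load_dicom(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # truncated/garbage files must not crash callers
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if img.mode not in ("L", "I;16", "I"):
        if not to_gray:
            raise FormatError(
                f"{path} has mode {img.mode}; pass to_gray=True for luminance conversion"
            )
        img = img.convert("L")
    arr = np.asarray(img)
    if arr.dtype != np.uint8:  # 16-bit TIFF: min-max rescale to the 8-bit pipeline range
        arr = _rescale_to_uint8(arr.astype(np.float64))
    return _validate_gray(arr)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
    except Exception as exc:
        raise FormatError(f"cannot read DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"DICOM {path} is not a single 2-D frame (shape {arr.shape})")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return _rescale_to_uint8(arr * slope + intercept)


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a ``GrayImage`` as an 8-bit grayscale PNG."""
    img = _validate_gray(np.asarray(img))
    Image.fromarray(img, mode="L").save(str(path))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a ``BinaryMask`` as an 8-bit PNG with values 0/255."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise FormatError(f"mask must be boolean, got dtype {mask.dtype}")
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(str(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Load a ``BinaryMask``; only the strict 0/255 dialect is accepted."""
    arr = load_image(path)
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 255))):
        bad = [int(v) for v in values if v not in (0, 255)]
        raise FormatError(f"mask {path} contains non-0/255 values {bad}")
    return arr == 255


def check_pair(img: np.ndarray, mask: np.ndarray) -> None:
    """Validate that a mask is shape-aligned with its image."""
    if img.shape != mask.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")


def write_manifest(rows: Sequence[dict], path: str | Path) -> Path:
    """Write a dataset manifest CSV with the canonical column order."""
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)
    return Path(path)


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest.

    Labels must come from :data:`CLASS_LABELS`; referenced image paths are
    resolved relative to the manifest's directory and must exist when
    ``check_paths`` is true.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"path": str, "label": str})
    missing_cols = set(("path", "label")) - set(df.columns)
    if missing_cols:
        raise FormatError(f"manifest {path} lacks columns {sorted(missing_cols)}")
    bad_labels = set(df["label"]) - set(CLASS_LABELS)
    if bad_labels:
        raise FormatError(f"manifest {path} has unknown labels {sorted(bad_labels)}")
    base = path.parent
    df["path"] = [str((base / p)) if not Path(p).is_absolute() else p for p in df["path"]]
    for col in ("lobe_left", "lobe_right", "nodule"):
        if col in df.columns:
            df[col] = [
                str(base / p) if isinstance(p, str) and not Path(p).is_absolute() else p
                for p in df[col]
            ]
    if check_paths:
        for p in df["path"]:
            if not Path(p).exists():
                raise FormatError(f"manifest references missing file {p}")
    return df


def features_to_csv(matrix: np.ndarray, names: Sequence[str], path: str | Path) -> None:
    """Persist a feature matrix as CSV with feature names in the header."""
    pd.DataFrame(np.asarray(matrix), columns=list(names)).to_csv(path, index=False)


def features_from_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=np.float64), list(df.columns)
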