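"""Reading images (DICOM / PNG / TIFF) and score tables.

Images are decoded to native integer intensities: DICOM pixel data gets
the rescale slope/intercept applied and is rounded; multi-channel PNG or
TIFF is collapsed with the standard luminance weights (with a logged
warning).  No rescaling of the dynamic range happens by default, because
the extremum thresholds are defined in intensity units; an optional
min-max rescale to 8-bit is available for cross-bit-depth comparability.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .nms_extrema import GrayscaleImage

logger = logging.getLogger("enmiqa")

__all__ = ["read_image", "write_image", "write_scores", "read_scores", "join_scores_mos"]

_LUMA = np.array([0.299, 0.587, 0.114])

SCORES_COLUMNS = ["image_id", "S", "neighborhood", "score"]


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom", ".ima"):
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames > 1:
        raise ValueError(
            f"{path}: multi-frame DICOM ({n_frames} frames); extract a single "
            "frame before scoring"
        )
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    return slope * arr + intercept


def read_image(path, rescale_to_8bit: bool = False) -> GrayscaleImage:
    """Decode a single-frame DICOM, PNG, or TIFF into a GrayscaleImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if _is_dicom(path):
        arr = _read_dicom(path)
    else:
        arr = np.asarray(iio.imread(path))
        if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
            raise ValueError(
                f"{path}: floating-point intensities; convert to integers first "
                "(thresholds are defined in integer intensity units)"
            )
        if arr.ndim == 3:
            if arr.shape[2] in (3, 4):
                logger.warning(
                    "%s: multi-channel image collapsed to luminance (0.299R+0.587G+0.114B)",
                    path,
                )
                arr = np.round(arr[:, :, :3].astype(np.float64) @ _LUMA)
            else:
                raise ValueError(f"{path}: unsupported channel layout {arr.shape}")
        arr = arr.astype(np.float64)
    arr = np.round(arr)
    lo = arr.min()
    if lo < 0:
        logger.warning(
            "%s: negative intensities after rescale; shifted up by %d "
            "(the extremum test depends only on intensity differences)",
            path,
            int(-lo),
        )
        arr = arr - lo
    if rescale_to_8bit:
        rng = arr.max() - arr.min()
        arr = np.zeros_like(arr) if rng == 0 else np.round((arr - arr.min()) / rng * 255)
    return GrayscaleImage(pixels=arr.astype(np.int64), source_id=path.name)


def write_image(path, image: GrayscaleImage, bit_depth: int = 8) -> None:
    """Write PNG (8-bit) or TIFF (8/16-bit)."""
    path = Path(path)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    hi = 2**bit_depth - 1
    px = image.pixels
    if px.max() > hi:
        raise ValueError(f"intensities exceed {bit_depth}-bit range")
    if path.suffix.lower() == ".png" and bit_depth != 8:
        raise ValueError("PNG output is 8-bit; use TIFF for 16-bit")
    iio.imwrite(path, px.astype(dtype))


def write_scores(path, rows: list) -> None:
    """Write objective scores as CSV (image_id, S, neighborhood, score)."""
    df = pd.DataFrame(rows, columns=SCORES_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCORES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: scores CSV missing columns {sorted(missing)}")
    return df


def join_scores_mos(scores: pd.DataFrame, mos: pd.DataFrame):
    """Strict inner join of objective scores with MOS on image_id.

    Raises if any image id appears on one side only or is duplicated.
    """
    for name, df, col in (("scores", scores, "score"), ("mos", mos, "mos")):
        if "image_id" not in df.columns or col not in df.columns:
            raise ValueError(f"{name} table must have columns image_id and {col}")
        dup = df["image_id"].duplicated()
        if dup.any():
            raise ValueError(f"duplicate image_id in {name}: {df['image_id'][dup].tolist()}")
    s_ids = set(scores["image_id"])
    m_ids = set(mos["image_id"])
    if s_ids != m_ids:
        raise ValueError(
            f"unmatched image ids; only in scores: {sorted(s_ids - m_ids)}, "
            f"only in mos: {sorted(m_ids - s_ids)}"
        )
    merged = scores.merge(mos[["image_id", "mos"]], on="image_id").sort_values("image_id")
    return merged.reset_index(drop=True)
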