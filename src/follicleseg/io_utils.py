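"""Image, mask and metric-table I/O.

Conventions used throughout the package:

* arrays are indexed ``(row, col)``, 0-based, row 0 at the top;
* images on disk are 8-bit PNG or JPG, in memory ``uint8`` H x W arrays;
* masks on disk are single-channel PNG with 0 = background, 255 = follicle;
  in memory they are boolean arrays (True = follicle);
* all artifact outputs are PNG so binary masks survive a round trip exactly.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .preprocess import to_grayscale


class FormatError(ValueError):
    """Raised for undecodable or unsupported image layouts."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPG as an 8-bit grayscale image.

    Single-channel input passes through; 3-channel (or RGBA, alpha dropped)
    input is converted by luma weighting.
    """
    arr = iio.imread(Path(path))
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit image data, got dtype {arr.dtype}")
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return to_grayscale(arr[..., :3])
    raise FormatError(f"{path}: unsupported channel layout {arr.shape}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; pixels > 127 are foreground (follicle)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    return arr > 127


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale image losslessly (PNG recommended)."""
    img = np.asarray(img)
    if img.ndim != 2 or img.dtype != np.uint8:
        raise FormatError(f"write_image: expected 2-D uint8 array, got {img.dtype} {img.shape}")
    iio.imwrite(Path(path), img)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 0/255 single-channel PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != bool:
        raise FormatError(f"write_mask: expected 2-D boolean array, got {mask.dtype} {mask.shape}")
    iio.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def write_metrics_csv(
    reports: Mapping[str, Sequence] | Sequence,
    path: str | Path,
) -> None:
    """Serialize per-image metric reports to CSV.

    ``reports`` is either a sequence of :class:`~follicleseg.metrics.MetricReport`
    (single method) or a mapping of method name to such sequences (one column
    group per method, Table-style layout).  Data rows are followed by ``mean``
    and ``sd`` rows.  An empty input produces a header-only CSV.
    """
    from .metrics import METRIC_NAMES, summarize

    path = Path(path)
    if isinstance(reports, Mapping):
        empty = all(len(v) == 0 for v in reports.values())
        if empty:
            cols = ["image"] + [
                f"{m}_{name}" for m in METRIC_NAMES for name in reports
            ]
            path.write_text(",".join(cols) + "\n", encoding="utf-8")
            return
    elif len(reports) == 0:
        path.write_text(",".join(("image", *METRIC_NAMES)) + "\n", encoding="utf-8")
        return
    df = summarize(reports)
    df.to_csv(path, index=False, float_format="%.4f")
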