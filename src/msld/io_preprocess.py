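"""Image loading, green-channel inversion, and field-of-view masks.

Fundus photographs carry the highest vessel/background contrast in the green
channel; vessels are dark there, so the working image for detection is the
*inverted* green channel (vessels bright).  Metrics and responses are
restricted to the circular field of view (FOV): DRIVE ships FOV mask files,
STARE does not, so a red-channel threshold fallback is provided.

All intensities are normalized to [0, 1] (8-/16-bit inputs divided by their
full-scale value).  Coordinates are 0-based (row, col), row 0 at top.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

MIN_SIZE = 32  # smaller frames cannot host the 15x15 detector window


@dataclass(frozen=True)
class FovMask:
    """Boolean field-of-view mask; True = inside the FOV."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        inside = np.asarray(self.inside, dtype=bool)
        if inside.ndim != 2:
            raise ValueError("FOV mask must be a 2-D boolean array")
        if not inside.any():
            raise ValueError("FOV mask is empty (no inside pixels)")
        object.__setattr__(self, "inside", inside)

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.inside.shape

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "FovMask":
        return cls(np.ones(shape, dtype=bool))


def _normalize(raw: np.ndarray) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    arr = raw.astype(np.float64)
    if arr.max() > 1.0:  # unannotated integer-valued input
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | Path) -> np.ndarray:
    """Load a raster image as an H x W x 3 float array in [0, 1].

    Grayscale files are replicated to three channels; an alpha channel, if
    present, is dropped.  Frames smaller than 32 x 32 are rejected.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding failures vary by plugin
        raise OSError(f"cannot read image file: {path}") from exc
    arr = _normalize(np.asarray(raw))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported image layout {raw.shape} in {path}")
    h, w = arr.shape[:2]
    if h < MIN_SIZE or w < MIN_SIZE:
        raise ValueError(
            f"image {path} is {h}x{w}; at least {MIN_SIZE}x{MIN_SIZE} required"
        )
    return arr


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; any nonzero pixel counts as True."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return np.asarray(raw) > 0


def save_response(path: str | Path, values: np.ndarray) -> None:
    """Write a real-valued response map as a 32-bit float TIFF."""
    iio.imwrite(Path(path), np.asarray(values, dtype=np.float32), extension=".tiff")


def inverted_green(img: np.ndarray) -> np.ndarray:
    """Return the inverted green channel I_igc = 1 - G (vessels bright)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return 1.0 - img[:, :, 1]


def fov_mask(
    img: np.ndarray,
    mode: str = "threshold",
    path: str | Path | None = None,
    tau: float = 0.1,
) -> FovMask:
    """Obtain a field-of-view mask for ``img``.

    mode='file' reads a binary mask image from ``path``; mode='threshold'
    marks pixels whose red channel is >= ``tau``, keeps the largest connected
    component and fills its holes (the usual recipe when, as for STARE, no
    official FOV mask exists); mode='full' marks every pixel.
    """
    h, w = img.shape[:2]
    if mode == "full":
        return FovMask.full((h, w))
    if mode == "file":
        if path is None:
            raise ValueError("mode='file' requires a mask path")
        inside = load_mask(path)
        if inside.shape != (h, w):
            raise ValueError(
                f"FOV mask shape {inside.shape} does not match image {(h, w)}"
            )
        return FovMask(inside)
    if mode == "threshold":
        red = np.asarray(img, dtype=np.float64)[:, :, 0]
        rough = red >= tau
        if not rough.any():
            raise ValueError(
                "FOV threshold produced an empty mask; use mode='full'"
            )
        labels, n = ndimage.label(rough)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = labels == (1 + int(np.argmax(sizes)))
        return FovMask(ndimage.binary_fill_holes(keep))
    raise ValueError(f"unknown FOV mode: {mode!r}")
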