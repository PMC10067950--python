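"""Geometry and intensity preprocessing of mastoid AP views.

Pipeline: read the DICOM AP view (rescale slope/intercept applied,
MONOCHROME1 inverted so brighter always means denser), crop each ear as a
180 mm x 120 mm box — the right ear centred at 0.5 x height and 0.25 x
width of the frame, the left ear at the mirror-symmetric point — flip the
left crop into right-ear orientation, resize both to 384 x 256, min-max
normalize each to [0, 1], and stack them vertically (right on top) into the
768 x 256 paired input.  The two network streams consume the two halves.

Coordinate convention: 0-based row/column indices, rows increase downward,
columns run patient-right to patient-left; a flip is a reversal of column
order.  The left crop box is the exact column mirror of the right box, so
reflecting the view left-right and re-cropping swaps the two crops
pixel-for-pixel.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pydicom
from skimage.transform import resize as _sk_resize

__all__ = [
    "Photometric",
    "Side",
    "APView",
    "EarCrop",
    "PairedInput",
    "GeometryError",
    "read_ap_view",
    "crop_ears",
    "compose_pair",
    "CROP_HEIGHT_MM",
    "CROP_WIDTH_MM",
    "TARGET_SHAPE",
]

CROP_HEIGHT_MM = 180.0
CROP_WIDTH_MM = 120.0
TARGET_SHAPE = (384, 256)  # rows x cols per ear after resize


class GeometryError(ValueError):
    """A crop box falls outside the image beyond the clamp tolerance."""


class Photometric(enum.Enum):
    MONOCHROME1 = "monochrome1"
    MONOCHROME2 = "monochrome2"


class Side(enum.Enum):
    RIGHT = "right"
    LEFT = "left"


@dataclass(frozen=True)
class APView:
    """A mastoid AP radiograph with physical pixel spacing.

    ``pixels`` rows run superior to inferior; columns run patient-right to
    patient-left (standard AP display).  Intensities are post-rescale, with
    higher values brighter (denser).
    """

    pixels: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    photometric: Photometric = Photometric.MONOCHROME2

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("AP view pixels must be a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("AP view contains non-finite intensities")
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class EarCrop:
    pixels: np.ndarray
    side: Side
    origin_row: int
    origin_col: int
    row_spacing_mm: float
    col_spacing_mm: float

    @property
    def extent_mm(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return h * self.row_spacing_mm, w * self.col_spacing_mm


@dataclass(frozen=True)
class PairedInput:
    """Oriented two-ear network input; both halves are 384x256 in [0, 1]
    with the left ear flipped into right-ear orientation."""

    right_image: np.ndarray
    left_image: np.ndarray

    def __post_init__(self) -> None:
        for name in ("right_image", "left_image"):
            img = np.asarray(getattr(self, name), dtype=np.float32)
            object.__setattr__(self, name, img)
            if img.min() < 0 or img.max() > 1 + 1e-6:
                raise ValueError(f"{name} values must lie in [0, 1]")

    @property
    def concatenated(self) -> np.ndarray:
        """Vertical concatenation, right ear on top."""
        return np.concatenate([self.right_image, self.left_image], axis=0)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def read_ap_view(path, fallback_spacing_mm: float | None = None) -> APView:
    """Read a single-frame grayscale DICOM into an :class:`APView`.

    Rescale slope/intercept are applied; MONOCHROME1 data is inverted so
    that higher values are brighter (normal air cells dark, sclerosis
    bright).  Pixel spacing comes from PixelSpacing (or
    ImagerPixelSpacing); if absent, ``fallback_spacing_mm`` is required.
    """
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")).upper()
    if photometric == "MONOCHROME1":
        arr = arr.min() + arr.max() - arr
        photo = Photometric.MONOCHROME1
    else:
        photo = Photometric.MONOCHROME2
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is not None:
        row_sp, col_sp = float(spacing[0]), float(spacing[1])
    elif fallback_spacing_mm is not None:
        row_sp = col_sp = float(fallback_spacing_mm)
    else:
        raise ValueError(
            f"{path}: no PixelSpacing in DICOM metadata and no fallback spacing configured"
        )
    return APView(arr, row_sp, col_sp, photo)


def _clamped_range(start: int, size: int, limit: int, tol_frac: float) -> int:
    """Clamp [start, start+size) into [0, limit); allow overhang up to
    ``tol_frac`` of the box."""
    overhang = max(-start, 0) + max(start + size - limit, 0)
    if overhang > tol_frac * size:
        raise GeometryError(
            f"crop box of {size} px overhangs the image ({limit} px) by {overhang} px, "
            f"more than the {tol_frac:.0%} clamp tolerance"
        )
    return min(max(start, 0), limit - size)


def crop_ears(view: APView, clamp_tolerance: float = 0.10) -> tuple[EarCrop, EarCrop]:
    """Crop the two 180 mm x 120 mm ear boxes from an AP view.

    The right-ear box is centred at (0.5 H, 0.25 W) in pixels; the left-ear
    box is its exact mirror about the vertical midline.  Boxes overhanging
    the frame by at most ``clamp_tolerance`` of their size are shifted
    inside; larger overhang raises :class:`GeometryError`.
    """
    h_px, w_px = view.shape
    box_h = _round_half_up(CROP_HEIGHT_MM / view.row_spacing_mm)
    box_w = _round_half_up(CROP_WIDTH_MM / view.col_spacing_mm)
    if box_h > h_px * (1 + clamp_tolerance) or box_w > w_px * (1 + clamp_tolerance):
        raise GeometryError(
            f"image {view.shape} px cannot contain a {box_h}x{box_w} px crop"
        )
    row0 = _round_half_up(0.5 * h_px - box_h / 2)
    col0_r = _round_half_up(0.25 * w_px - box_w / 2)
    row0 = _clamped_range(row0, box_h, h_px, clamp_tolerance)
    col0_r = _clamped_range(col0_r, box_w, w_px, clamp_tolerance)
    # the symmetric point: the left box is the column mirror of the right box
    col0_l = w_px - (col0_r + box_w)
    col0_l = _clamped_range(col0_l, box_w, w_px, clamp_tolerance)
    right = EarCrop(
        view.pixels[row0 : row0 + box_h, col0_r : col0_r + box_w].copy(),
        Side.RIGHT, row0, col0_r, view.row_spacing_mm, view.col_spacing_mm,
    )
    left = EarCrop(
        view.pixels[row0 : row0 + box_h, col0_l : col0_l + box_w].copy(),
        Side.LEFT, row0, col0_l, view.row_spacing_mm, view.col_spacing_mm,
    )
    return right, left


def _normalize01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        warnings.warn("degenerate crop with zero intensity range; normalized to zeros",
                      stacklevel=3)
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def compose_pair(
    right: EarCrop, left: EarCrop, target_shape: tuple[int, int] = TARGET_SHAPE
) -> PairedInput:
    """Flip the left crop into right-ear orientation, resize both crops
    (bilinear) to ``target_shape``, min-max normalize each to [0, 1]."""
    if right.side is not Side.RIGHT or left.side is not Side.LEFT:
        raise ValueError("compose_pair expects (right, left) crops in that order")
    left_flipped = left.pixels[:, ::-1]
    r = _sk_resize(right.pixels, target_shape, order=1, anti_aliasing=False,
                   preserve_range=True)
    l = _sk_resize(left_flipped, target_shape, order=1, anti_aliasing=False,
                   preserve_range=True)
    return PairedInput(_normalize01(r), _normalize01(l))
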