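"""Gel band / strip spot quantification and binding-ratio arithmetic.

Integrated intensities are background-subtracted pixel sums over
rectangular or disc ROIs, with the background estimated either from the
median of a border ring around the ROI ("local-median") or from a
rolling-ball fit over the whole image ("rolling-ball:<radius>").

The sedimentation bound fraction corrects the unbound lane for its
loading dilution d:  ratio = B / (B + d * U).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.restoration import rolling_ball

from cytocurv.exceptions import ParameterError

__all__ = [
    "RectROI",
    "DiscROI",
    "DensitometryRecord",
    "BindingResult",
    "integrate_roi",
    "binding_ratio",
    "relative_spot_intensities",
]

_RING_WIDTH = 3  # px, border ring for the local-median background


@dataclass(frozen=True)
class RectROI:
    """Half-open rectangle [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def validate(self, shape: tuple[int, int]) -> None:
        ok = (
            0 <= self.row_start < self.row_stop <= shape[0]
            and 0 <= self.col_start < self.col_stop <= shape[1]
        )
        if not ok:
            raise ParameterError(f"ROI {self} outside image of shape {shape}")

    def to_dict(self) -> dict:
        return {
            "kind": "rect",
            "row_start": self.row_start,
            "row_stop": self.row_stop,
            "col_start": self.col_start,
            "col_stop": self.col_stop,
        }


@dataclass(frozen=True)
class DiscROI:
    """Disc of given radius (px) centred at (row, col)."""

    row: float
    col: float
    radius: float

    def validate(self, shape: tuple[int, int]) -> None:
        ok = (
            self.radius > 0
            and self.row - self.radius >= -0.5
            and self.col - self.radius >= -0.5
            and self.row + self.radius <= shape[0] - 0.5
            and self.col + self.radius <= shape[1] - 0.5
        )
        if not ok:
            raise ParameterError(f"ROI {self} outside image of shape {shape}")

    def to_dict(self) -> dict:
        return {"kind": "disc", "row": self.row, "col": self.col, "radius": self.radius}


def roi_from_dict(d: dict) -> RectROI | DiscROI:
    kind = d.get("kind", "rect")
    if kind == "rect":
        return RectROI(d["row_start"], d["row_stop"], d["col_start"], d["col_stop"])
    if kind == "disc":
        return DiscROI(d["row"], d["col"], d["radius"])
    raise ParameterError(f"unknown ROI kind {kind!r}")


@dataclass(frozen=True)
class DensitometryRecord:
    """Integrated, background-subtracted intensity of one band or spot."""

    label: str
    roi: RectROI | DiscROI
    integrated_intensity: float
    background: float
    background_model: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.integrated_intensity < 0:
            raise ValueError("integrated intensity must be >= 0 (clamped)")


@dataclass(frozen=True)
class BindingResult:
    """Dilution-corrected bound fraction for one bead diameter."""

    diameter_nm: float
    B: float
    U: float
    d_dil: float
    ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError("binding ratio must lie in [0, 1]")


def _roi_masks(image: np.ndarray, roi) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (roi_pixels, ring_pixels) for a ROI on ``image``."""
    h, w = image.shape
    if isinstance(roi, RectROI):
        inner = np.zeros((h, w), dtype=bool)
        inner[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop] = True
        outer = np.zeros((h, w), dtype=bool)
        outer[
            max(roi.row_start - _RING_WIDTH, 0) : min(roi.row_stop + _RING_WIDTH, h),
            max(roi.col_start - _RING_WIDTH, 0) : min(roi.col_stop + _RING_WIDTH, w),
        ] = True
    elif isinstance(roi, DiscROI):
        rr, cc = np.mgrid[0:h, 0:w]
        d2 = (rr - roi.row) ** 2 + (cc - roi.col) ** 2
        inner = d2 <= roi.radius**2
        outer = d2 <= (roi.radius + _RING_WIDTH) ** 2
    else:
        raise ParameterError(f"unsupported ROI type {type(roi).__name__}")
    return inner, outer & ~inner


def integrate_roi(
    image: np.ndarray,
    roi: RectROI | DiscROI,
    background_model: str = "local-median",
    label: str = "",
) -> DensitometryRecord:
    """Background-subtracted pixel sum over a ROI, clamped at zero.

    Parameters
    ----------
    background_model : {"local-median", "rolling-ball:<radius>"}
        local-median: median of a 3-px border ring around the ROI,
        subtracted as a constant.  rolling-ball: per-pixel background from
        :func:`skimage.restoration.rolling_ball` over the whole image.

    Raises
    ------
    ParameterError
        If the ROI falls outside the image or the model is unknown.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("integrate_roi expects a 2D image")
    roi.validate(img.shape)
    inner, ring = _roi_masks(img, roi)

    if background_model == "local-median":
        bg_value = float(np.median(img[ring])) if ring.any() else 0.0
        net = float(img[inner].sum() - bg_value * inner.sum())
    elif background_model.startswith("rolling-ball:"):
        try:
            radius = float(background_model.split(":", 1)[1])
        except ValueError as exc:
            raise ParameterError(f"bad background model {background_model!r}") from exc
        bg_img = rolling_ball(img, radius=radius)
        bg_value = float(bg_img[inner].mean())
        net = float((img[inner] - bg_img[inner]).sum())
    else:
        raise ParameterError(f"unknown background model {background_model!r}")

    clamped = net < 0
    if clamped:
        warnings.warn(
            f"background exceeds signal in ROI {label!r}; clamped to 0",
            stacklevel=2,
        )
        net = 0.0
    return DensitometryRecord(
        label=label,
        roi=roi,
        integrated_intensity=net,
        background=bg_value,
        background_model=background_model,
        clamped=clamped,
    )


def binding_ratio(B: float, U: float, d_dil: float = 1.0) -> float:
    """Bound fraction B / (B + d * U) with dilution factor d on U.

    Raises
    ------
    ParameterError
        If d < 1, intensities are negative, or B = U = 0 (undefined).
    """
    if d_dil < 1:
        raise ParameterError(f"dilution factor must be >= 1, got {d_dil}")
    if B < 0 or U < 0:
        raise ParameterError("intensities must be non-negative")
    if B == 0 and U == 0:
        raise ParameterError("undefined binding ratio: B = U = 0")
    return B / (B + d_dil * U)


def relative_spot_intensities(
    records: list[DensitometryRecord],
    blank_labels: list[str] | tuple[str, ...] = (),
) -> pd.Series:
    """Blank-subtracted, max-normalized spot intensities.

    The mean intensity of the blank-labelled spots is subtracted from
    every spot (clamped at 0) and the result is scaled so the brightest
    spot equals 1.  If every spot is at or below blank level the output is
    all zeros with a warning.
    """
    blanks = [r.integrated_intensity for r in records if r.label in blank_labels]
    non_blank = [r for r in records if r.label not in blank_labels]
    if not non_blank:
        raise ParameterError("need at least one non-blank spot")
    blank_mean = float(np.mean(blanks)) if blanks else 0.0
    net = np.maximum(
        np.array([r.integrated_intensity for r in non_blank]) - blank_mean, 0.0
    )
    top = net.max()
    if top == 0:
        warnings.warn("all spots at or below blank level", stacklevel=2)
        rel = net
    else:
        rel = net / top
    return pd.Series(rel, index=[r.label for r in non_blank], name="relative_intensity")
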