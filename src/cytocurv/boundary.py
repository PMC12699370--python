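"""Cell segmentation, boundary extraction and boundary intensity sampling.

Workflow: threshold one fluorescence channel into a single-component,
hole-free :class:`CellMask`; trace the 0.5 iso-level of the mask to a
sub-pixel :class:`~cytocurv.geometry.Contour`; then sample each channel's
mean intensity in a small disc around every contour point and normalize
the resulting :class:`IntensityProfile` to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from cytocurv import geometry
from cytocurv.exceptions import ParameterError, SegmentationError

__all__ = [
    "CellMask",
    "IntensityProfile",
    "segment_cell",
    "extract_boundary",
    "sample_boundary_intensity",
    "normalize_profile",
]


@dataclass(frozen=True)
class CellMask:
    """Binary cell mask: exactly one connected component, holes filled."""

    mask: np.ndarray
    pixel_size_um: float
    largest_component: bool = True
    holes_filled: bool = True

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2


@dataclass(frozen=True)
class IntensityProfile:
    """Per-sample boundary fluorescence of one channel.

    ``raw`` is the band-mean intensity; ``normalized`` is filled by
    :func:`normalize_profile` and lies in [0, 1].
    """

    channel_name: str
    raw: np.ndarray
    band_width_um: float
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.normalized is not None:
            if len(self.normalized) != len(self.raw):
                raise ValueError("normalized/raw length mismatch")
            if np.any((self.normalized < 0) | (self.normalized > 1)):
                raise ValueError("normalized values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.raw)


def segment_cell(
    image: np.ndarray,
    method: str = "otsu",
    min_area_um2: float = 10.0,
    pixel_size_um: float = 1.0,
) -> CellMask:
    """Threshold-segment the single cell in a fluorescence image.

    Parameters
    ----------
    image : 2D array
        Single-channel intensity image.
    method : {"otsu", "fixed:<value>"}
        Global Otsu threshold, or a fixed absolute threshold.
    min_area_um2 : float
        Components smaller than this are rejected.
    pixel_size_um : float
        Pixel size used for the area cut and recorded in the mask.

    Raises
    ------
    SegmentationError
        If the image has no contrast or no component survives.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("segment_cell expects a 2D single-channel image")
    if img.max() == img.min():
        raise SegmentationError("image is constant; nothing to segment")

    if method == "otsu":
        thr = threshold_otsu(img)
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")

    fg = img > thr
    labels, n_lab = ndimage.label(fg)
    if n_lab == 0:
        raise SegmentationError("empty foreground after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_lab + 1))
    min_area_px = min_area_um2 / pixel_size_um**2
    sizes[sizes < min_area_px] = 0
    if sizes.max() == 0:
        raise SegmentationError(
            f"no component reaches min_area_um2={min_area_um2}"
        )
    best = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == best)

    edges = (
        mask[0].any(),
        mask[-1].any(),
        mask[:, 0].any(),
        mask[:, -1].any(),
    )
    if all(edges):
        warnings.warn("cell touches all four image borders (cropped cell?)", stacklevel=2)
    return CellMask(mask=mask, pixel_size_um=pixel_size_um)


def extract_boundary(
    mask: CellMask,
    n_samples: int = 1000,
    smooth_sigma_px: float = 2.0,
) -> geometry.Contour:
    """Sub-pixel boundary of a mask at the 0.5 iso-level, resampled.

    The binary mask is Gaussian-smoothed (``smooth_sigma_px``) before
    tracing, which removes pixel-scale staircase jaggedness that would
    otherwise dominate downstream second derivatives; set to 0 to trace
    the raw mask.

    Raises
    ------
    ValueError
        If the mask violates the single-component invariant.
    """
    _, n_lab = ndimage.label(mask.mask)
    if n_lab != 1:
        raise ValueError(f"mask must have exactly one component, found {n_lab}")
    float_mask = mask.mask.astype(float)
    if smooth_sigma_px > 0:
        float_mask = ndimage.gaussian_filter(float_mask, smooth_sigma_px)
    contours = measure.find_contours(float_mask, 0.5)
    if not contours:
        raise SegmentationError("no iso-contour found in mask")
    # longest loop = outer boundary; (row, col) -> (x, y)
    longest = max(contours, key=lambda c: len(c))
    pts = np.column_stack([longest[:, 1], longest[:, 0]])
    return geometry.resample_contour(pts, mask.pixel_size_um, n_samples=n_samples)


def sample_boundary_intensity(
    image: np.ndarray,
    contour: geometry.Contour,
    band_width_um: float = 0.5,
) -> IntensityProfile:
    """Mean intensity in a disc of diameter ``band_width_um`` at each sample.

    A pixel belongs to the disc when its centre lies within
    ``band_width_um / 2`` of the exact (sub-pixel) contour point; if the
    disc is empty (very narrow band) the nearest pixel is used.  Discs
    extending outside the image are clamped with a warning.
    """
    if band_width_um <= 0:
        raise ParameterError("band width must be positive")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    px = contour.pixel_size_um
    r = (band_width_um / 2) / px
    reach = int(np.ceil(r)) + 1
    off = np.arange(-reach, reach + 1)
    off_r, off_c = np.meshgrid(off, off, indexing="ij")
    off_r = off_r.ravel()
    off_c = off_c.ravel()

    raw = np.empty(contour.n_samples)
    clamped = False
    for i, (x_um, y_um) in enumerate(contour.points):
        cx = x_um / px
        cy = y_um / px
        base_r = int(np.floor(cy))
        base_c = int(np.floor(cx))
        rows = base_r + off_r
        cols = base_c + off_c
        sel = (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
        if not sel.any():
            rows = np.array([int(round(cy))])
            cols = np.array([int(round(cx))])
            sel = np.array([True])
        rows = rows[sel]
        cols = cols[sel]
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        if not inside.all():
            clamped = True
            rows = np.clip(rows, 0, h - 1)
            cols = np.clip(cols, 0, w - 1)
        raw[i] = img[rows, cols].mean()
    if clamped:
        warnings.warn("sampling band extended outside the image; clamped", stacklevel=2)
    return IntensityProfile(channel_name="", raw=raw, band_width_um=band_width_um)


def normalize_profile(
    profile: IntensityProfile,
    mode: str = "minmax",
) -> IntensityProfile:
    """Scale a raw profile into [0, 1].

    Modes: ``minmax`` or ``percentile:<p_lo>,<p_hi>`` (clip to the given
    percentiles before min-max scaling).  A constant raw profile yields
    all-0.5 output with a warning.
    """
    raw = np.asarray(profile.raw, dtype=float)
    if mode == "minmax":
        values = raw
    elif mode.startswith("percentile:"):
        try:
            p_lo, p_hi = (float(v) for v in mode.split(":", 1)[1].split(","))
        except ValueError as exc:
            raise ParameterError(f"bad percentile mode {mode!r}") from exc
        if not (0 <= p_lo < p_hi <= 100):
            raise ParameterError(f"bad percentile bounds in {mode!r}")
        lo, hi = np.percentile(raw, [p_lo, p_hi])
        values = np.clip(raw, lo, hi)
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")

    lo = values.min()
    hi = values.max()
    if hi == lo:
        warnings.warn(
            f"constant raw profile for channel {profile.channel_name!r}; "
            "normalized set to 0.5",
            stacklevel=2,
        )
        norm = np.full_like(raw, 0.5)
    else:
        norm = (values - lo) / (hi - lo)
    return replace(profile, normalized=norm)
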