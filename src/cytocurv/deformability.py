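"""Deformation-index cytometry from cross-flow junction video frames.

Each bright-field frame is background-differenced and Otsu-thresholded
inside the junction ROI; the cell's axis-aligned extents along the
declared outflow (H) and inflow (W) axes give the deformation index
DI = H / W.  Per transit (a maximal run of consecutive frames with a
detection) the frame maximizing DI is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from cytocurv.exceptions import ParameterError

__all__ = [
    "DIRecord",
    "DICurve",
    "detect_cell_extents",
    "deformation_index",
    "track_max_deformation",
    "aggregate_di_curve",
]


@dataclass(frozen=True)
class DIRecord:
    """One cell's maximal deformation within a transit."""

    cell_id: int
    frame_index_at_max: int
    H: float
    W: float
    DI: float
    Q: float | None = None
    single_frame: bool = False

    def __post_init__(self) -> None:
        if self.H <= 0 or self.W <= 0:
            raise ValueError("H and W must be positive")
        if not np.isclose(self.DI, self.H / self.W):
            raise ValueError("DI must equal H/W")


@dataclass(frozen=True)
class DICurve:
    """Aggregated DI vs flow rate Q for one condition."""

    table: pd.DataFrame  # columns: Q, mean_DI, sd, n, sd_undefined
    condition: str = ""


def _roi_slices(frame: np.ndarray, roi) -> tuple[slice, slice]:
    if roi is None:
        return slice(0, frame.shape[0]), slice(0, frame.shape[1])
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= frame.shape[0] and 0 <= c0 < c1 <= frame.shape[1]):
        raise ParameterError(f"ROI {roi} outside frame shape {frame.shape}")
    return slice(r0, r1), slice(c0, c1)


def detect_cell_extents(
    frame: np.ndarray,
    roi=None,
    axes: tuple[int, int] = (1, 0),
    background: float | np.ndarray | None = None,
    min_area_px: int = 20,
):
    """Segment the cell in one frame and measure its axis extents.

    Parameters
    ----------
    frame : 2D array
        Bright-field frame (cell darker or brighter than background).
    roi : (row_start, row_stop, col_start, col_stop) or None
        Junction rectangle; None uses the whole frame.
    axes : (inflow_axis, outflow_axis)
        Array axes (0 = rows, 1 = cols).  W is the extent along the inflow
        axis, H along the outflow axis.
    background : scalar, array or None
        Background level; defaults to the ROI median.
    min_area_px : int
        Components smaller than this are treated as noise.

    Returns
    -------
    (H, W, mask) or None
        None is the skip signal: no component, too small, or the
        component touches the ROI edge.
    """
    rs, cs = _roi_slices(frame, roi)
    sub = np.asarray(frame, dtype=float)[rs, cs]
    if background is None:
        background = np.median(sub)
    diff = np.abs(sub - background)
    if diff.max() == diff.min():
        return None
    # robust blank-frame rejection: a real cell must stand well clear of
    # the pixel-noise floor (MAD-based scale of the background difference)
    noise_scale = 1.4826 * float(np.median(np.abs(diff - np.median(diff))))
    if noise_scale > 0 and diff.max() < 8.0 * noise_scale:
        return None
    thr = threshold_otsu(diff)
    fg = diff > thr
    labels, n_lab = ndimage.label(fg)
    if n_lab == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_lab + 1))
    if sizes.max() < min_area_px:
        return None
    comp = labels == (int(np.argmax(sizes)) + 1)
    rows = np.any(comp, axis=1)
    cols = np.any(comp, axis=0)
    if rows[0] or rows[-1] or cols[0] or cols[-1]:
        return None  # touching ROI edge: partial cell
    extents = {
        0: int(np.flatnonzero(rows).max() - np.flatnonzero(rows).min() + 1),
        1: int(np.flatnonzero(cols).max() - np.flatnonzero(cols).min() + 1),
    }
    inflow_axis, outflow_axis = axes
    if {inflow_axis, outflow_axis} != {0, 1}:
        raise ParameterError(f"axes must be a permutation of (0, 1), got {axes}")
    H = extents[outflow_axis]
    W = extents[inflow_axis]
    return float(H), float(W), comp


def deformation_index(H: float, W: float) -> float:
    """DI = H / W.

    Raises
    ------
    ParameterError
        If W is not positive (undefined DI).
    """
    if W <= 0:
        raise ParameterError(f"undefined DI: W must be positive, got {W}")
    return H / W


def track_max_deformation(
    frames,
    roi=None,
    axes: tuple[int, int] = (1, 0),
    Q: float | None = None,
    background: float | np.ndarray | None = None,
    min_area_px: int = 20,
) -> list[DIRecord]:
    """Per-transit maximum DI over an ordered frame sequence.

    A transit is a maximal run of consecutive frames with a detection;
    cells are assumed to pass one at a time.  Single-frame transits are
    accepted but flagged.
    """
    records: list[DIRecord] = []
    transit: list[tuple[int, float, float]] = []  # (frame_idx, H, W)

    def close_transit() -> None:
        if not transit:
            return
        dis = [deformation_index(H, W) for _, H, W in transit]
        best = int(np.argmax(dis))
        frame_idx, H, W = transit[best]
        if len(transit) == 1:
            warnings.warn(
                f"single-frame transit at frame {frame_idx}", stacklevel=3
            )
        records.append(
            DIRecord(
                cell_id=len(records),
                frame_index_at_max=frame_idx,
                H=H,
                W=W,
                DI=dis[best],
                Q=Q,
                single_frame=len(transit) == 1,
            )
        )
        transit.clear()

    for i, frame in enumerate(frames):
        det = detect_cell_extents(
            frame, roi=roi, axes=axes, background=background, min_area_px=min_area_px
        )
        if det is None:
            close_transit()
        else:
            transit.append((i, det[0], det[1]))
    close_transit()
    return records


def aggregate_di_curve(records: list[DIRecord], condition: str = "") -> DICurve:
    """Per-Q mean DI, standard deviation and n, sorted by Q.

    A Q with a single record gets sd 0 and ``sd_undefined`` True.

    Raises
    ------
    ValueError
        If any record lacks a Q label or no records are given.
    """
    if not records:
        raise ValueError("no DI records to aggregate")
    if any(r.Q is None for r in records):
        raise ValueError("all records need a flow-rate label Q")
    df = pd.DataFrame({"Q": [r.Q for r in records], "DI": [r.DI for r in records]})
    rows = []
    for q, grp in df.groupby("Q", sort=True):
        n = len(grp)
        rows.append(
            {
                "Q": q,
                "mean_DI": float(grp["DI"].mean()),
                "sd": float(grp["DI"].std(ddof=1)) if n > 1 else 0.0,
                "n": n,
                "sd_undefined": n < 2,
            }
        )
    return DICurve(table=pd.DataFrame(rows), condition=condition)
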