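"""Closed-contour representation and curvature estimation.

A cell outline is stored as a :class:`Contour`: a closed, counterclockwise
(interior on the left), uniformly arc-length-resampled polygon in physical
micrometre coordinates (image convention: x right, y down, pixel centres at
integer coordinates).  Signed curvature is estimated from periodic
Savitzky-Golay derivatives of the coordinate functions x(s), y(s):

    kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)

with the convention that kappa > 0 where the centre of the osculating
circle lies on the interior (cytoplasmic) side, so a convex circular cell
is uniformly positive and invaginations are negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter
from shapely.geometry import LinearRing

from cytocurv.exceptions import DegenerateContourError, ParameterError

__all__ = [
    "Contour",
    "CurvatureProfile",
    "resample_contour",
    "signed_curvature",
    "smooth_abs_curvature",
    "shoelace_area",
    "contour_profile_frame",
    "read_contour_profile_csv",
]


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area; positive for counterclockwise vertex order."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed cell outline, uniformly resampled in arc length.

    Attributes
    ----------
    points : (n, 2) ndarray
        Vertex coordinates (x, y) in micrometres, counterclockwise, with
        the closing edge implied (last point connects back to the first).
    pixel_size_um : float
        Provenance of the pixel -> micrometre conversion.
    closed : bool
        Always True for cell outlines.
    """

    points: np.ndarray
    pixel_size_um: float
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise DegenerateContourError(
                "contour needs at least 8 (x, y) points, got "
                f"shape {pts.shape}"
            )
        if np.any(np.all(pts == np.roll(pts, -1, axis=0), axis=1)):
            raise DegenerateContourError("consecutive contour points coincide")
        object.__setattr__(self, "points", pts)

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    @property
    def arc_positions(self) -> np.ndarray:
        """Arc-length coordinate of each sample (uniform spacing L/n)."""
        n = self.n_samples
        return self.perimeter * np.arange(n) / n

    @property
    def spacing(self) -> float:
        return self.perimeter / self.n_samples

    @property
    def is_counterclockwise(self) -> bool:
        return shoelace_area(self.points) > 0


@dataclass(frozen=True)
class CurvatureProfile:
    """Per-sample signed curvature along a contour.

    ``kappa_abs_smoothed`` holds the periodic moving average of ``|kappa|``
    over ``smoothing_window_um`` (window 0 means no smoothing applied yet).
    """

    s: np.ndarray
    kappa: np.ndarray
    kappa_abs_smoothed: np.ndarray
    smoothing_window_um: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.s) == len(self.kappa) == len(self.kappa_abs_smoothed)):
            raise ValueError("profile arrays must have equal length")
        if np.any(self.kappa_abs_smoothed < 0):
            raise ValueError("smoothed |kappa| must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.s)

    @property
    def total_turning(self) -> float:
        """Discrete closed-contour integral of kappa ds (2*pi for simple CCW)."""
        ds = np.diff(self.s, append=self.s[-1] + (self.s[1] - self.s[0]))
        return float(np.sum(self.kappa * ds))


def _distinct(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates, including a duplicated closing point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateContourError("points must be an (n, 2) array")
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    if pts.shape[0] and not keep.any():
        keep[0] = True
    return pts[keep]


def resample_contour(
    points: np.ndarray,
    pixel_size_um: float,
    n_samples: int = 1000,
) -> Contour:
    """Resample a raw pixel outline to uniform arc-length spacing in µm.

    Parameters
    ----------
    points : (m, 2) array
        Raw closed polygon vertices in pixel coordinates (x, y).  A
        duplicated closing vertex is tolerated.
    pixel_size_um : float
        Physical pixel size; coordinates are multiplied by this value.
    n_samples : int
        Number of output samples, uniformly spaced along the polygon.

    Returns
    -------
    Contour
        Counterclockwise contour with ``n_samples`` points in micrometres.

    Raises
    ------
    DegenerateContourError
        If fewer than 3 distinct vertices remain.
    ParameterError
        If ``pixel_size_um`` or ``n_samples`` is invalid.
    """
    if pixel_size_um <= 0:
        raise ParameterError(f"pixel_size_um must be positive, got {pixel_size_um}")
    if n_samples < 8:
        raise ParameterError(f"n_samples must be >= 8, got {n_samples}")

    pts = _distinct(points)
    if pts.shape[0] < 3:
        raise DegenerateContourError(
            f"need >= 3 distinct points for a closed outline, got {pts.shape[0]}"
        )

    ring = LinearRing(pts)
    if not ring.is_simple:
        warnings.warn(
            "contour polygon self-intersects; proceeding (touching "
            "protrusions after segmentation can cause this)",
            stacklevel=2,
        )

    pts = pts * pixel_size_um
    if shoelace_area(pts) < 0:
        pts = pts[::-1]

    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise DegenerateContourError("contour has zero perimeter")

    target = total * np.arange(n_samples) / n_samples
    x = np.interp(target, cum, closed[:, 0])
    y = np.interp(target, cum, closed[:, 1])
    return Contour(points=np.column_stack([x, y]), pixel_size_um=pixel_size_um)


def _odd_window(window_um: float, spacing: float, n: int, minimum: int = 5) -> int:
    w = int(round(window_um / spacing))
    w = max(w, minimum)
    if w % 2 == 0:
        w += 1
    # savgol requires window <= n
    if w >= n:
        w = n - 1 if (n - 1) % 2 == 1 else n - 2
    return w


def signed_curvature(
    contour: Contour,
    presmooth_window_um: float = 1.0,
) -> CurvatureProfile:
    """Signed curvature of a uniformly resampled closed contour.

    Coordinates are presmoothed with a periodic Savitzky-Golay filter
    (cubic, window ``presmooth_window_um``); first and second periodic
    derivatives with respect to arc length feed the standard plane-curve
    curvature formula.  Positive kappa: osculating-circle centre on the
    interior side (convex regions of a counterclockwise outline).

    Raises
    ------
    ParameterError
        If the presmooth window is not positive or exceeds half the
        perimeter.
    """
    if presmooth_window_um <= 0:
        raise ParameterError("presmooth window must be positive")
    if presmooth_window_um > contour.perimeter / 2:
        raise ParameterError(
            f"presmooth window {presmooth_window_um} µm exceeds half the "
            f"perimeter ({contour.perimeter / 2:.3g} µm)"
        )
    n = contour.n_samples
    ds = contour.spacing
    w = _odd_window(presmooth_window_um, ds, n)

    x = contour.points[:, 0]
    y = contour.points[:, 1]
    d = {}
    for name, arr in (("x", x), ("y", y)):
        for deriv in (1, 2):
            d[name, deriv] = savgol_filter(
                arr, w, polyorder=3, deriv=deriv, delta=ds, mode="wrap"
            )
    num = d["x", 1] * d["y", 2] - d["y", 1] * d["x", 2]
    den = (d["x", 1] ** 2 + d["y", 1] ** 2) ** 1.5
    kappa = num / den
    return CurvatureProfile(
        s=contour.arc_positions,
        kappa=kappa,
        kappa_abs_smoothed=np.abs(kappa),
        smoothing_window_um=0.0,
    )


def smooth_abs_curvature(
    profile: CurvatureProfile,
    window_um: float = 2.0,
) -> CurvatureProfile:
    """Periodic moving average of |kappa| over ``window_um``.

    The window is converted to ``k = round(window / spacing)`` samples and
    applied as a wrap-around boxcar, so a single spike of height h becomes
    a plateau of height h/k.

    Raises
    ------
    ParameterError
        If ``window_um`` is not positive.
    """
    if window_um <= 0:
        raise ParameterError("smoothing window must be positive")
    ds = float(profile.s[1] - profile.s[0])
    k = max(1, int(round(window_um / ds)))
    smoothed = uniform_filter1d(np.abs(profile.kappa), size=k, mode="wrap")
    return replace(profile, kappa_abs_smoothed=smoothed, smoothing_window_um=window_um)


def contour_profile_frame(
    contour: Contour, profile: CurvatureProfile
) -> pd.DataFrame:
    """Join a contour and its curvature profile into a tidy table."""
    if profile.n_samples != contour.n_samples:
        raise ValueError("contour and profile lengths differ")
    return pd.DataFrame(
        {
            "index": np.arange(contour.n_samples),
            "s_um": profile.s,
            "x_um": contour.points[:, 0],
            "y_um": contour.points[:, 1],
            "kappa_per_um": profile.kappa,
            "kappa_abs_smoothed_per_um": profile.kappa_abs_smoothed,
        }
    )


def read_contour_profile_csv(
    path, pixel_size_um: float = float("nan"), smoothing_window_um: float = float("nan")
) -> tuple[Contour, CurvatureProfile]:
    """Round-trip reader for :func:`contour_profile_frame` CSV output."""
    df = pd.read_csv(path)
    contour = Contour(
        points=df[["x_um", "y_um"]].to_numpy(),
        pixel_size_um=pixel_size_um,
    )
    profile = CurvatureProfile(
        s=df["s_um"].to_numpy(),
        kappa=df["kappa_per_um"].to_numpy(),
        kappa_abs_smoothed=df["kappa_abs_smoothed_per_um"].to_numpy(),
        smoothing_window_um=smoothing_window_um,
    )
    return contour, profile
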