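"""Seeded ground-truth generators for every pipeline stage.

All generators are pure functions of their spec plus seed: rerunning with
the same arguments reproduces byte-identical arrays.

Phantom cells are star-shaped outlines r(theta) = R0 (1 + sum_k a_k
cos(k theta + phi_k)) plus Gaussian protrusion bumps; curvature comes
from the closed-form polar expression

    kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2)

and the spectrin boundary channel follows a logistic curvature response
S = 1 / (1 + exp(steepness * (|kappa| - kappa0))) with actin A = 1 - S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cytocurv.densitometry import DiscROI, RectROI
from cytocurv.exceptions import GenerationError, ParameterError

__all__ = [
    "PhantomCellSpec",
    "PhantomCell",
    "DeformationCohortSpec",
    "GroundTruthTransit",
    "GelImage",
    "StripImage",
    "DEFAULT_STRIP_LAYOUT",
    "make_phantom_cell",
    "make_deformation_video",
    "make_gel_image",
    "make_strip_image",
]


# --------------------------------------------------------------------------
# phantom two-channel cells
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomCellSpec:
    """Parameters of one synthetic two-channel cell image.

    harmonics: list of (k, amplitude, phase) radial modes.
    protrusions: list of (theta0, width_rad, length_um) Gaussian bumps.
    kappa0_per_um: curvature threshold above which the spectrin-like
    channel is excluded from the boundary; response_steepness controls
    how sharp the logistic transition is (µm per unit 1/µm).
    """

    base_radius_um: float = 10.0
    harmonics: tuple[tuple[int, float, float], ...] = ()
    protrusions: tuple[tuple[float, float, float], ...] = ()
    kappa0_per_um: float = 0.2
    response_steepness: float = 25.0
    snr: float = 5.0
    pixel_size_um: float = 0.2
    band_width_um: float = 0.6
    fill_fraction: float = 0.35
    boundary_amplitude: float = 100.0
    margin_um: float = 4.0
    n_theta: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if self.base_radius_um <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("radius and pixel size must be positive")


@dataclass(frozen=True)
class PhantomCell:
    """A generated phantom plus its analytic ground truth."""

    images: dict[str, np.ndarray]  # keys: "spectrin", "actin"
    points_um: np.ndarray  # dense ground-truth outline (n_theta, 2)
    s_um: np.ndarray  # arc length per outline sample
    kappa_per_um: np.ndarray  # analytic signed curvature per sample
    spectrin_profile: np.ndarray  # programmed S(s) in [0, 1]
    actin_profile: np.ndarray  # programmed A(s) = 1 - S(s)
    theta: np.ndarray
    centre_um: tuple[float, float]  # cell centre in image coordinates
    spec: PhantomCellSpec


def _wrap_angle(delta: np.ndarray) -> np.ndarray:
    return (delta + np.pi) % (2 * np.pi) - np.pi


def _radial(spec: PhantomCellSpec, theta: np.ndarray):
    """r(theta) and its first two derivatives, closed form."""
    r = np.full_like(theta, spec.base_radius_um, dtype=float)
    r1 = np.zeros_like(theta, dtype=float)
    r2 = np.zeros_like(theta, dtype=float)
    for k, amp, phase in spec.harmonics:
        arg = k * theta + phase
        r += spec.base_radius_um * amp * np.cos(arg)
        r1 -= spec.base_radius_um * amp * k * np.sin(arg)
        r2 -= spec.base_radius_um * amp * k * k * np.cos(arg)
    for theta0, width, length in spec.protrusions:
        if width <= 0:
            raise ParameterError("protrusion width must be positive")
        d = _wrap_angle(theta - theta0)
        g = length * np.exp(-0.5 * (d / width) ** 2)
        r += g
        r1 += g * (-d / width**2)
        r2 += g * (d**2 / width**4 - 1.0 / width**2)
    return r, r1, r2


def _polar_curvature(r, r1, r2) -> np.ndarray:
    return (r**2 + 2 * r1**2 - r * r2) / (r**2 + r1**2) ** 1.5


def _logistic_response(kappa_abs, kappa0, steepness) -> np.ndarray:
    # clip the exponent: steepness -> inf degenerates to an indicator
    z = np.clip(steepness * (kappa_abs - kappa0), -500, 500)
    return 1.0 / (1.0 + np.exp(z))


def make_phantom_cell(spec: PhantomCellSpec) -> PhantomCell:
    """Render a two-channel phantom cell with analytic ground truth.

    The spectrin channel has a uniform cytoplasmic fill
    (``fill_fraction * boundary_amplitude``) across the whole cell plus a
    boundary band modulated by the logistic curvature response; the actin
    channel carries the complementary boundary band only.  Gaussian noise
    with sd ``boundary_amplitude / snr`` is added independently per
    channel.

    Raises
    ------
    GenerationError
        If the spec yields a non-positive radius anywhere (non-simple
        outline).
    """
    theta = np.linspace(0.0, 2 * np.pi, spec.n_theta, endpoint=False)
    r, r1, r2 = _radial(spec, theta)
    if np.any(r <= 0):
        raise GenerationError("radial function non-positive: outline not simple")
    kappa = _polar_curvature(r, r1, r2)

    # arc length along theta
    speed = np.hypot(r1, r)  # |d(x,y)/dtheta| = sqrt(r'^2 + r^2)
    dtheta = theta[1] - theta[0]
    s = np.concatenate([[0.0], np.cumsum(speed * dtheta)])[:-1]

    spectrin_profile = _logistic_response(
        np.abs(kappa), spec.kappa0_per_um, spec.response_steepness
    )
    actin_profile = 1.0 - spectrin_profile

    # image grid, cell centred
    r_max = float(r.max())
    half = r_max + spec.margin_um
    n_px = int(np.ceil(2 * half / spec.pixel_size_um))
    centre = (n_px - 1) / 2 * spec.pixel_size_um
    xs = np.arange(n_px) * spec.pixel_size_um - centre
    gx, gy = np.meshgrid(xs, xs)  # gy: rows (y down), gx: cols
    rho = np.hypot(gx, gy)
    ptheta = np.mod(np.arctan2(gy, gx), 2 * np.pi)

    pr, pr1, pr2 = _radial(spec, ptheta)
    pkappa = _polar_curvature(pr, pr1, pr2)
    p_spec = _logistic_response(
        np.abs(pkappa), spec.kappa0_per_um, spec.response_steepness
    )
    dist = rho - pr  # signed distance proxy (radial)
    band = np.abs(dist) <= spec.band_width_um / 2
    # fill reaches the outer band edge so the segmentable cell support has a
    # uniform margin over the nominal outline regardless of channel response
    interior = dist <= spec.band_width_um / 2

    amp = spec.boundary_amplitude
    spectrin_img = spec.fill_fraction * amp * interior + amp * p_spec * band
    actin_img = amp * (1.0 - p_spec) * band

    rng = np.random.default_rng(spec.seed)
    noise_sd = amp / spec.snr
    spectrin_img = spectrin_img + rng.normal(0.0, noise_sd, spectrin_img.shape)
    actin_img = actin_img + rng.normal(0.0, noise_sd, actin_img.shape)

    points = np.column_stack([r * np.cos(theta) + centre, r * np.sin(theta) + centre])
    return PhantomCell(
        images={"spectrin": spectrin_img, "actin": actin_img},
        points_um=points,
        s_um=s,
        kappa_per_um=kappa,
        spectrin_profile=spectrin_profile,
        actin_profile=actin_profile,
        theta=theta,
        centre_um=(centre, centre),
        spec=spec,
    )


def random_phantom_spec(
    seed: int,
    kappa0_per_um: float = 0.2,
    snr: float = 5.0,
    base_radius_um: float = 10.0,
    n_harmonics: int = 2,
    n_protrusions: int = 2,
    pixel_size_um: float = 0.1,
    fill_fraction: float = 0.5,
) -> PhantomCellSpec:
    """A randomized phantom spec with mixed flat/curved boundary.

    Mode amplitudes are scaled so the boundary's |kappa| distribution
    covers the exclusion threshold: each mode k contributes a curvature
    modulation of roughly ``a_k (k^2 - 1) / R0``, drawn at 70-100% of a
    target ``max(0.25, 1.4 * kappa0)``.  A couple of strong high-order
    modes give an extremes-peaked |kappa| density, which populates the
    spectrin class right up to kappa0.
    """
    rng = np.random.default_rng(seed)
    target = max(0.25, 1.4 * kappa0_per_um)
    harmonics = []
    for k in rng.choice(np.arange(6, 13), size=n_harmonics, replace=False):
        modulation = rng.uniform(0.7, 1.0) * target
        harmonics.append(
            (
                int(k),
                float(modulation * base_radius_um / (k * k - 1)),
                float(rng.uniform(0, 2 * np.pi)),
            )
        )
    protrusions = tuple(
        (
            float(rng.uniform(0, 2 * np.pi)),
            float(rng.uniform(0.12, 0.2)),
            float(rng.uniform(1.5, 3.0)),
        )
        for _ in range(n_protrusions)
    )
    return PhantomCellSpec(
        base_radius_um=base_radius_um,
        harmonics=tuple(harmonics),
        protrusions=protrusions,
        kappa0_per_um=kappa0_per_um,
        snr=snr,
        pixel_size_um=pixel_size_um,
        fill_fraction=fill_fraction,
        seed=seed,
    )


# --------------------------------------------------------------------------
# deformation video
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformationCohortSpec:
    """Cohort of synthetic cell transits across flow rates.

    di_curve maps each flow rate Q to the mean programmed peak DI; peaks
    are drawn Normal(mean, di_sd) truncated at 1 from below.
    """

    flow_rates: tuple[float, ...]
    di_curve: dict[float, float]
    di_sd: float = 0.08
    n_cells_per_q: int = 200
    noise_sd: float = 2.0
    size_jitter: float = 0.1
    base_width_px: int = 20
    frame_shape: tuple[int, int] = (64, 64)
    background: float = 100.0
    cell_contrast: float = 60.0
    ramp: tuple[float, ...] = (0.2, 0.6, 1.0, 0.6, 0.2)
    blank_frames: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_q < 1:
            raise ParameterError("need at least one cell per Q")
        missing = set(self.flow_rates) - set(self.di_curve)
        if missing:
            raise ParameterError(f"di_curve missing flow rates {sorted(missing)}")


@dataclass(frozen=True)
class GroundTruthTransit:
    """Realized (rasterized) truth for one cell's transit."""

    cell_id: int
    Q: float
    peak_DI: float  # realized H/W of the peak frame
    H_px: int
    W_px: int
    peak_frame_index: int
    n_frames: int


def _even(value: float, minimum: int = 4) -> int:
    return max(minimum, 2 * int(round(value / 2)))


def _ellipse_frame(shape, H_px: int, W_px: int, background, contrast, rng, noise_sd):
    """Dark axis-aligned ellipse with exact even pixel extents H_px x W_px."""
    rows, cols = shape
    cr = (rows - 1) / 2  # half-integer for even `rows` -> exact extents
    cc = (cols - 1) / 2
    rr, ccg = np.mgrid[0:rows, 0:cols]
    inside = ((rr - cr) / (H_px / 2)) ** 2 + ((ccg - cc) / (W_px / 2)) ** 2 <= 1.0
    frame = np.full(shape, background, dtype=float) - contrast * inside
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, shape)
    return frame, inside


def _mask_extents(mask: np.ndarray) -> tuple[int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)


def make_deformation_video(
    spec: DeformationCohortSpec,
) -> dict[float, tuple[np.ndarray, list[GroundTruthTransit]]]:
    """Per flow rate, a frame stack of single-cell transits plus truth.

    Each transit ramps DI from near 1 up to the cell's programmed peak and
    back down (outflow along image rows), separated by blank frames.  The
    emitted ground truth carries the *realized* integer pixel extents, so
    a noise-free analysis recovers each peak DI exactly.
    """
    if len(spec.frame_shape) != 2 or any(v % 2 for v in spec.frame_shape):
        raise ParameterError("frame_shape must be two even integers")
    out: dict[float, tuple[np.ndarray, list[GroundTruthTransit]]] = {}
    for qi, q in enumerate(spec.flow_rates):
        rng = np.random.default_rng([spec.seed, qi])
        frames: list[np.ndarray] = []
        truths: list[GroundTruthTransit] = []
        blank_rng_shape = spec.frame_shape
        for cell_id in range(spec.n_cells_per_q):
            peak_target = rng.normal(spec.di_curve[q], spec.di_sd)
            peak_target = max(peak_target, 1.0)
            w_px = _even(
                spec.base_width_px * (1 + spec.size_jitter * rng.uniform(-1, 1))
            )
            di_seq = [1.0 + (peak_target - 1.0) * f for f in spec.ramp]
            h_seq = [max(_even(di * w_px), w_px) for di in di_seq]

            peak_h = 0
            peak_idx_local = 0
            start_idx = len(frames)
            for j, h_px in enumerate(h_seq):
                frame, mask = _ellipse_frame(
                    spec.frame_shape,
                    h_px,
                    w_px,
                    spec.background,
                    spec.cell_contrast,
                    rng,
                    spec.noise_sd,
                )
                h_real, w_real = _mask_extents(mask)
                if h_real > peak_h:
                    peak_h, peak_w, peak_idx_local = h_real, w_real, j
                frames.append(frame)
            truths.append(
                GroundTruthTransit(
                    cell_id=cell_id,
                    Q=q,
                    peak_DI=peak_h / peak_w,
                    H_px=peak_h,
                    W_px=peak_w,
                    peak_frame_index=start_idx + peak_idx_local,
                    n_frames=len(h_seq),
                )
            )
            for _ in range(spec.blank_frames):
                blank = np.full(blank_rng_shape, spec.background, dtype=float)
                if spec.noise_sd > 0:
                    blank = blank + rng.normal(0.0, spec.noise_sd, blank_rng_shape)
                frames.append(blank)
        out[q] = (np.stack(frames), truths)
    return out


# --------------------------------------------------------------------------
# gel and strip images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GelImage:
    """Synthetic sedimentation gel: per lane a bound and an unbound band."""

    image: np.ndarray
    rois: dict[str, RectROI]  # labels "B_<i>", "U_<i>"
    lanes: tuple[tuple[float, float, float], ...]  # (B, U, d) as painted
    background: float


@dataclass(frozen=True)
class StripImage:
    """Synthetic lipid-strip: spots at template grid positions."""

    image: np.ndarray
    rois: dict[str, DiscROI]
    affinities: dict[str, float]
    blanks: tuple[str, ...]


def _paint_gaussian(image, row, col, sigma_r, sigma_c, volume) -> None:
    rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    peak = volume / (2 * np.pi * sigma_r * sigma_c)
    image += peak * np.exp(
        -0.5 * (((rr - row) / sigma_r) ** 2 + ((cc - col) / sigma_c) ** 2)
    )


def make_gel_image(
    lanes: list[tuple[float, float, float]],
    band_sigma: tuple[float, float] = (3.0, 5.0),
    snr: float = 50.0,
    seed: int = 0,
    background: float = 5.0,
) -> GelImage:
    """Paint bound/unbound Gaussian bands with prescribed integrated volumes.

    ``lanes`` holds (B, U, d) per lane; B and U are painted directly as
    integrated band volumes (the unbound lane is assumed loaded after its
    physical d-fold dilution, as in the wet assay), and d is carried as
    metadata for the dilution-corrected ratio.  SNR is the peak of the
    dimmest painted band divided by the pixel noise sd.
    """
    if any(b < 0 or u < 0 for b, u, _ in lanes):
        raise ParameterError("band volumes must be non-negative")
    sigma_r, sigma_c = band_sigma
    lane_w = 48
    height = 120
    row_b, row_u = 35, 85
    width = lane_w * len(lanes)
    image = np.full((height, width), background, dtype=float)

    rois: dict[str, RectROI] = {}
    half_r = int(np.ceil(3 * sigma_r))
    half_c = int(np.ceil(3 * sigma_c))
    for i, (b, u, _d) in enumerate(lanes):
        col = lane_w * i + lane_w // 2
        if b > 0:
            _paint_gaussian(image, row_b, col, sigma_r, sigma_c, b)
        if u > 0:
            _paint_gaussian(image, row_u, col, sigma_r, sigma_c, u)
        rois[f"B_{i}"] = RectROI(row_b - half_r, row_b + half_r, col - half_c, col + half_c)
        rois[f"U_{i}"] = RectROI(row_u - half_r, row_u + half_r, col - half_c, col + half_c)

    volumes = [v for b, u, _ in lanes for v in (b, u) if v > 0]
    peak_min = (min(volumes) / (2 * np.pi * sigma_r * sigma_c)) if volumes else 0.0
    noise_sd = peak_min / snr if peak_min > 0 else 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, image.shape)
    return GelImage(image=image, rois=rois, lanes=tuple(lanes), background=background)


#: 8 x 2 grid emulating a commercial lipid strip: 15 lipids + one blank.
DEFAULT_STRIP_LAYOUT: dict[str, tuple[int, int]] = {
    "LPA": (0, 0),
    "LPC": (0, 1),
    "PtdIns": (1, 0),
    "PtdIns3P": (1, 1),
    "PtdIns4P": (2, 0),
    "PtdIns5P": (2, 1),
    "PE": (3, 0),
    "PC": (3, 1),
    "S1P": (4, 0),
    "PtdIns(3,4)P2": (4, 1),
    "PtdIns(3,5)P2": (5, 0),
    "PtdIns(4,5)P2": (5, 1),
    "PtdIns(3,4,5)P3": (6, 0),
    "PA": (6, 1),
    "PS": (7, 0),
    "blank": (7, 1),
}


def make_strip_image(
    affinities: dict[str, float],
    layout: dict[str, tuple[int, int]] | None = None,
    blanks: tuple[str, ...] = ("blank",),
    snr: float = 50.0,
    seed: int = 0,
    spot_sigma: float = 2.5,
    spot_spacing: int = 26,
    margin: int = 16,
    peak: float = 100.0,
) -> StripImage:
    """Paint spots at template grid positions with programmed affinities.

    Affinities must lie in [0, 1]; blank-labelled positions are painted at
    zero regardless.

    Raises
    ------
    ParameterError
        If any affinity falls outside [0, 1] or is not in the layout.
    """
    layout = dict(DEFAULT_STRIP_LAYOUT) if layout is None else dict(layout)
    unknown = set(affinities) - set(layout)
    if unknown:
        raise ParameterError(f"affinities for unknown spots {sorted(unknown)}")
    if any(not (0.0 <= a <= 1.0) for a in affinities.values()):
        raise ParameterError("affinities must lie in [0, 1]")

    n_rows = max(r for r, _ in layout.values()) + 1
    n_cols = max(c for _, c in layout.values()) + 1
    shape = (
        2 * margin + (n_rows - 1) * spot_spacing + 1,
        2 * margin + (n_cols - 1) * spot_spacing + 1,
    )
    image = np.zeros(shape, dtype=float)
    rois: dict[str, DiscROI] = {}
    for name, (gr, gc) in layout.items():
        row = margin + gr * spot_spacing
        col = margin + gc * spot_spacing
        a = 0.0 if name in blanks else float(affinities.get(name, 0.0))
        if a > 0:
            volume = a * peak * 2 * np.pi * spot_sigma**2
            _paint_gaussian(image, row, col, spot_sigma, spot_sigma, volume)
        rois[name] = DiscROI(row=row, col=col, radius=3 * spot_sigma)

    noise_sd = peak / snr
    rng = np.random.default_rng(seed)
    image = image + rng.normal(0.0, noise_sd, shape)
    return StripImage(
        image=image, rois=rois, affinities=dict(affinities), blanks=tuple(blanks)
    )
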