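"""End-to-end in-memory analyses shared by the CLI and the test harness."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytocurv import boundary, enrichment, geometry

__all__ = ["CurvatureParams", "CellAnalysis", "analyze_cell"]


@dataclass(frozen=True)
class CurvatureParams:
    """All knobs of the boundary-curvature localization analysis."""

    segmentation_channel: str = "spectrin"
    segmentation_method: str = "otsu"
    min_area_um2: float = 20.0
    n_samples: int = 1000
    mask_smooth_sigma_px: float = 2.0
    presmooth_window_um: float = 2.0
    abs_smoothing_window_um: float = 2.0
    band_width_um: float = 0.5
    normalization: str = "minmax"
    dominance_margin: float = 0.1
    intensity_floor: float = 0.3
    min_run_samples: int = 10
    curvature_cutoff_per_um: float = 0.2


@dataclass
class CellAnalysis:
    """Bundle of every intermediate and final product for one cell."""

    contour: geometry.Contour
    curvature: geometry.CurvatureProfile
    profiles: dict[str, boundary.IntensityProfile]
    labels: enrichment.RegionLabels
    by_class: enrichment.CurvatureByClass
    stats: dict
    params: CurvatureParams
    table: pd.DataFrame = field(repr=False, default=None)


def analyze_cell(
    images: dict[str, np.ndarray],
    pixel_size_um: float,
    params: CurvatureParams = CurvatureParams(),
    actin_channel: str = "actin",
    spectrin_channel: str = "spectrin",
) -> CellAnalysis:
    """Run segment -> boundary -> curvature -> profiles -> enrichment.

    Parameters
    ----------
    images : dict
        Channel name -> 2D image; must contain the segmentation channel
        and both classification channels.
    pixel_size_um : float
        Physical pixel size (required, never guessed).
    """
    seg_img = images[params.segmentation_channel]
    mask = boundary.segment_cell(
        seg_img,
        method=params.segmentation_method,
        min_area_um2=params.min_area_um2,
        pixel_size_um=pixel_size_um,
    )
    contour = boundary.extract_boundary(
        mask,
        n_samples=params.n_samples,
        smooth_sigma_px=params.mask_smooth_sigma_px,
    )
    curv = geometry.signed_curvature(
        contour, presmooth_window_um=params.presmooth_window_um
    )
    curv = geometry.smooth_abs_curvature(
        curv, window_um=params.abs_smoothing_window_um
    )

    profiles: dict[str, boundary.IntensityProfile] = {}
    for name, img in images.items():
        prof = boundary.sample_boundary_intensity(
            img, contour, band_width_um=params.band_width_um
        )
        prof = boundary.normalize_profile(prof, mode=params.normalization)
        profiles[name] = boundary.IntensityProfile(
            channel_name=name,
            raw=prof.raw,
            band_width_um=prof.band_width_um,
            normalized=prof.normalized,
        )

    labels = enrichment.classify_enriched(
        profiles[actin_channel],
        profiles[spectrin_channel],
        dominance_margin=params.dominance_margin,
        intensity_floor=params.intensity_floor,
        min_run_samples=params.min_run_samples,
    )
    by_class = enrichment.curvature_by_class(
        curv, labels, cutoff_per_um=params.curvature_cutoff_per_um
    )
    stats = enrichment.compare_classes(by_class)

    table = geometry.contour_profile_frame(contour, curv)
    for name, prof in profiles.items():
        table[f"{name}_raw"] = prof.raw
        table[f"{name}_normalized"] = prof.normalized
    table["label"] = labels.labels

    return CellAnalysis(
        contour=contour,
        curvature=curv,
        profiles=profiles,
        labels=labels,
        by_class=by_class,
        stats=stats,
        params=params,
        table=table,
    )
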