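"""Classification of channel-enriched boundary regions and per-class curvature.

A boundary sample is "enriched" for a channel when that channel's
normalized intensity clears an absolute floor and dominates the other
channel by a margin; contiguous runs shorter than a minimum length are
discarded.  Curvature values (smoothed |kappa|) are then pooled per class
and compared with a two-sided rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cytocurv.boundary import IntensityProfile
from cytocurv.geometry import CurvatureProfile

__all__ = [
    "ACTIN",
    "SPECTRIN",
    "UNASSIGNED",
    "RegionLabels",
    "CurvatureByClass",
    "classify_enriched",
    "curvature_by_class",
    "compare_classes",
]

ACTIN = "actin_enriched"
SPECTRIN = "spectrin_enriched"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RegionLabels:
    """Per-sample enrichment labels on a closed boundary.

    ``runs`` lists contiguous enriched stretches as (start_index,
    end_index, label) with inclusive indices; a run may wrap past the last
    sample (then end_index < start_index).
    """

    labels: np.ndarray
    runs: list[tuple[int, int, str]]
    params: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def run_length(self, run: tuple[int, int, str]) -> int:
        start, end, _ = run
        n = self.n_samples
        return (end - start) % n + 1


@dataclass(frozen=True)
class CurvatureByClass:
    """Pooled |kappa| values and summaries per enrichment class.

    ``summary[label]`` is ``None`` for an empty class, otherwise a dict
    with keys median, iqr, frac_below_cutoff, n.
    """

    values: dict[str, np.ndarray]
    summary: dict[str, dict | None]
    cutoff_per_um: float


def _circular_runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal constant-label runs on a circular array, inclusive indices."""
    n = len(labels)
    if n == 0:
        return []
    if all(labels[0] == lab for lab in labels):
        return [(0, n - 1, str(labels[0]))]
    # rotate so a label change occurs at position 0
    start = 0
    for i in range(n):
        if labels[i - 1] != labels[i]:
            start = i
            break
    runs: list[tuple[int, int, str]] = []
    run_start = start
    for k in range(1, n + 1):
        i = (start + k) % n
        prev = (start + k - 1) % n
        if k == n or labels[i] != labels[prev]:
            runs.append((run_start, prev, str(labels[prev])))
            run_start = i
        if k == n:
            break
    return runs


def classify_enriched(
    actin: IntensityProfile,
    spectrin: IntensityProfile,
    dominance_margin: float = 0.1,
    intensity_floor: float = 0.3,
    min_run_samples: int = 10,
) -> RegionLabels:
    """Label each boundary sample actin-/spectrin-enriched or unassigned.

    A sample is labelled for channel c when ``normalized_c >=
    intensity_floor`` and ``normalized_c - normalized_other >=
    dominance_margin``.  Enriched runs shorter than ``min_run_samples``
    (circularly) are dropped to unassigned.  Swapping the two inputs swaps
    the labels exactly.

    Raises
    ------
    ValueError
        If profiles differ in length or are not normalized.
    """
    if actin.normalized is None or spectrin.normalized is None:
        raise ValueError("profiles must be normalized before classification")
    a = np.asarray(actin.normalized, dtype=float)
    s = np.asarray(spectrin.normalized, dtype=float)
    if len(a) != len(s):
        raise ValueError(f"profile length mismatch: {len(a)} vs {len(s)}")

    labels = np.full(len(a), UNASSIGNED, dtype=object)
    labels[(a >= intensity_floor) & (a - s >= dominance_margin)] = ACTIN
    labels[(s >= intensity_floor) & (s - a >= dominance_margin)] = SPECTRIN

    runs = _circular_runs(labels)
    n = len(labels)
    kept: list[tuple[int, int, str]] = []
    for start, end, lab in runs:
        length = (end - start) % n + 1
        if lab == UNASSIGNED:
            continue
        if length < min_run_samples:
            idx = (start + np.arange(length)) % n
            labels[idx] = UNASSIGNED
        else:
            kept.append((start, end, lab))
    return RegionLabels(
        labels=labels,
        runs=kept,
        params={
            "dominance_margin": dominance_margin,
            "intensity_floor": intensity_floor,
            "min_run_samples": min_run_samples,
        },
    )


def curvature_by_class(
    curv: CurvatureProfile,
    labels: RegionLabels,
    cutoff_per_um: float = 0.2,
) -> CurvatureByClass:
    """Pool smoothed |kappa| per enrichment class and summarize.

    The summary per class holds the median, interquartile range, the
    fraction of samples with |kappa| below ``cutoff_per_um``, and the
    sample count.  Empty classes get a ``None`` summary (no exception).
    """
    if curv.n_samples != labels.n_samples:
        raise ValueError("curvature profile and labels differ in length")
    k_abs = np.asarray(curv.kappa_abs_smoothed, dtype=float)
    values: dict[str, np.ndarray] = {}
    summary: dict[str, dict | None] = {}
    for lab in (ACTIN, SPECTRIN):
        vals = k_abs[labels.labels == lab]
        values[lab] = vals
        if len(vals) == 0:
            summary[lab] = None
        else:
            q25, q75 = np.percentile(vals, [25, 75])
            summary[lab] = {
                "median": float(np.median(vals)),
                "iqr": float(q75 - q25),
                "frac_below_cutoff": float(np.mean(vals < cutoff_per_um)),
                "n": int(len(vals)),
            }
    return CurvatureByClass(values=values, summary=summary, cutoff_per_um=cutoff_per_um)


def compare_classes(cbc: CurvatureByClass) -> dict:
    """Two-sided rank-sum comparison of |kappa| between the two classes.

    Returns a dict with the Mann-Whitney U statistic, p-value and the
    rank-biserial effect size ``2 U / (n_a n_s) - 1`` (positive when the
    actin class has larger |kappa|).  Classes with fewer than 3 samples
    yield an undefined result with a warning, not an exception.
    """
    a = cbc.values.get(ACTIN, np.array([]))
    s = cbc.values.get(SPECTRIN, np.array([]))
    if len(a) < 3 or len(s) < 3:
        warnings.warn(
            f"class too small for rank-sum test (n_actin={len(a)}, "
            f"n_spectrin={len(s)})",
            stacklevel=2,
        )
        return {
            "statistic": None,
            "p_value": None,
            "rank_biserial": None,
            "n_actin": int(len(a)),
            "n_spectrin": int(len(s)),
        }
    res = stats.mannwhitneyu(a, s, alternative="two-sided")
    rank_biserial = 2.0 * res.statistic / (len(a) * len(s)) - 1.0
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "rank_biserial": float(rank_biserial),
        "n_actin": int(len(a)),
        "n_spectrin": int(len(s)),
    }


def regions_frame(labels: RegionLabels, curv: CurvatureProfile) -> pd.DataFrame:
    """Run table with arc positions in µm (start/end inclusive)."""
    s = np.asarray(curv.s, dtype=float)
    rows = [
        {
            "start_index": start,
            "end_index": end,
            "start_s_um": s[start],
            "end_s_um": s[end],
            "label": lab,
            "n_samples": labels.run_length((start, end, lab)),
        }
        for start, end, lab in labels.runs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "start_index",
            "end_index",
            "start_s_um",
            "end_s_um",
            "label",
            "n_samples",
        ],
    )
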