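"""Aggregate size-distribution kinetics and eGFP expression time courses.

Retained aggregates are binned by log_e(volume) into eleven unit-width bins
with integer edges -6, -5, ..., 5; this fixed grid covers the observed range
of log-volumes (about -5.5 to 4.1 under the unit-depth volume convention).
Per-image bin counts are normalized by the combined cell volume of the image,
and per-time-point summaries average these densities across the (at least
four) images of each time point.  eGFP expression per time point is
summarized by the median across images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from polyqtc.imagequant import ImageQuantResult

__all__ = [
    "BIN_EDGES",
    "N_BINS",
    "VolumeHistogram",
    "BinnedDensity",
    "TimepointSummary",
    "logvol_bins",
    "density_per_cell_volume",
    "timepoint_aggregate",
    "summaries_to_frame",
    "plot_density_panels",
]

#: fixed log_e(volume/um^3) bin edges: eleven half-open unit bins [-6,-5) ... [4,5)
BIN_EDGES = np.arange(-6, 6)
N_BINS = len(BIN_EDGES) - 1

#: paper-style panel split of the time axis
INTERMEDIATE_TIMES_H = (24.0, 36.0, 48.0)
LATE_TIMES_H = (72.0, 96.0, 120.0)


@dataclass
class VolumeHistogram:
    """Counts of aggregates per unit log_e(volume) bin."""

    counts: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts do not match bin edges")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinnedDensity:
    """Aggregates per um^3 of cell volume, per log-volume bin."""

    densities: np.ndarray
    total_cell_volume: float
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())


@dataclass
class TimepointSummary:
    """Cross-image summary of one post-induction time point."""

    time_h: float
    n_images: int
    mean_density_per_bin: np.ndarray
    egfp_values: list[float]
    egfp_median: float
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())


def logvol_bins(volumes: Iterable[float]) -> VolumeHistogram:
    """Bin aggregate volumes (um^3) by log_e(volume) on the fixed 11-bin grid.

    Raises on non-positive volumes and on log-volumes outside [-6, 5).
    """
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        return VolumeHistogram(np.zeros(N_BINS, dtype=int))
    if np.any(v <= 0):
        bad = v[v <= 0][0]
        raise ValueError(f"volumes must be > 0 (got {bad!r})")
    logv = np.log(v)
    lo, hi = BIN_EDGES[0], BIN_EDGES[-1]
    out_of_range = (logv < lo) | (logv >= hi)
    if np.any(out_of_range):
        bad = logv[out_of_range][0]
        raise ValueError(
            f"log_e(volume) = {bad:.3f} outside the binning range [{lo}, {hi})"
        )
    counts, _ = np.histogram(logv, bins=BIN_EDGES)
    return VolumeHistogram(counts)


def density_per_cell_volume(hist: VolumeHistogram, total_cell_volume: float) -> BinnedDensity:
    """Normalize per-bin counts by the image's combined cell volume (um^3)."""
    if not total_cell_volume > 0:
        raise ValueError("total_cell_volume must be > 0")
    return BinnedDensity(
        densities=hist.counts.astype(float) / total_cell_volume,
        total_cell_volume=total_cell_volume,
        bin_edges=hist.bin_edges.copy(),
    )


def timepoint_aggregate(
    per_image: Sequence[ImageQuantResult], min_images: int = 4
) -> list[TimepointSummary]:
    """Summarize per-image quantifications per post-induction time point.

    Densities are averaged across the images of a time point and eGFP
    expression is summarized by its median.  Time points represented by
    fewer than ``min_images`` images trigger a warning (the study analysed
    at least four images per time point); untagged images are rejected.
    """
    for res in per_image:
        if res.time_h is None:
            raise ValueError(f"image {res.source_id!r} has no time point tag")
    by_time: dict[float, list[ImageQuantResult]] = {}
    for res in per_image:
        by_time.setdefault(float(res.time_h), []).append(res)

    summaries: list[TimepointSummary] = []
    for t in sorted(by_time):
        group = by_time[t]
        if len(group) < min_images:
            warnings.warn(
                f"time point {t:g} h has only {len(group)} image(s); "
                f"the design floor is {min_images}",
                stacklevel=2,
            )
        dens = []
        egfp = []
        for res in group:
            hist = logvol_bins(res.spots.volumes)
            dens.append(
                density_per_cell_volume(hist, res.segmentation.total_cell_volume).densities
            )
            egfp.append(res.egfp_expression)
        summaries.append(
            TimepointSummary(
                time_h=t,
                n_images=len(group),
                mean_density_per_bin=np.mean(dens, axis=0),
                egfp_values=egfp,
                egfp_median=float(np.median(egfp)),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[TimepointSummary]) -> pd.DataFrame:
    """Long-format table (time_h, bin_low, bin_high, mean_density, n_images)."""
    rows = []
    for s in summaries:
        for i in range(N_BINS):
            rows.append(
                {
                    "time_h": s.time_h,
                    "bin_low": int(s.bin_edges[i]),
                    "bin_high": int(s.bin_edges[i + 1]),
                    "mean_density": s.mean_density_per_bin[i],
                    "n_images": s.n_images,
                }
            )
    return pd.DataFrame(rows)


def plot_density_panels(summaries: Sequence[TimepointSummary], path=None):
    """Grouped bar chart of bin densities, split into intermediate and late panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("intermediate (24-48 h)", INTERMEDIATE_TIMES_H),
        ("late (72-120 h)", LATE_TIMES_H),
    ]
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    centers = BIN_EDGES[:-1] + 0.5
    for ax, (title, times) in zip(axes, panels):
        sel = [s for s in summaries if s.time_h in times]
        width = 0.8 / max(len(sel), 1)
        for k, s in enumerate(sel):
            ax.bar(
                centers + (k - (len(sel) - 1) / 2) * width,
                s.mean_density_per_bin,
                width=width,
                label=f"{s.time_h:g} h",
            )
        ax.set_title(title)
        ax.set_xlabel("log$_e$(volume / $\\mu m^3$)")
        ax.legend()
    axes[0].set_ylabel("aggregates per $\\mu m^3$ cell volume")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
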