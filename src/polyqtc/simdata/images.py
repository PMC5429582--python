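"""Synthetic fluorescence images of cells with punctate aggregates.

Cells are rendered as smooth-edged disks of diffuse eGFP signal on a flat
background; aggregates as isotropic 2-D Gaussian peaks placed inside cells.
Each aggregate's ground-truth "volume" follows the pipeline-wide unit-depth
convention: the area of the region above half-maximum of its Gaussian profile
(analytically ``2 * pi * ln 2 * s^2`` um^2 for profile scale ``s`` um) times a
nominal 1 um depth.  Planting a log-volume therefore fixes the Gaussian scale
as ``s = sqrt(V / (2 pi ln 2))``.

Randomness is driven by one global seed; per-image substreams are derived
from it so any subset of a time course is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from polyqtc.imagequant import UNIT_DEPTH_UM, CalibratedImage

__all__ = [
    "ImageSimConfig",
    "AggregateTruth",
    "ImageGroundTruth",
    "TimecourseSimConfig",
    "gen_image",
    "gen_timecourse_images",
    "default_trajectory",
]

_HALF_MAX_FACTOR = 2.0 * math.pi * math.log(2.0)

#: experimental sampling grid (hours post-induction); 0 h is pre-induction
TIMEPOINTS_H = (0, 4, 8, 24, 36, 48, 72, 96, 120)


def spot_scale_um(volume_um3: float) -> float:
    """Gaussian profile scale (um) whose half-max area x 1 um equals the volume."""
    return math.sqrt(volume_um3 / (_HALF_MAX_FACTOR * UNIT_DEPTH_UM))


@dataclass(frozen=True)
class ImageSimConfig:
    """Configuration of one synthetic image.

    Intensities use an 8-bit-like convention (background ~10 AFU, diffuse
    cell signal ~60 AFU, spot amplitudes several hundred AFU) so that the
    published detection thresholds of 30 (cells) and 80 (spots) sit inside
    their intended operating range.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # um / pixel (100x oil objective, CCD)
    n_cells: int = 4
    cell_radius_range: tuple[float, float] = (3.0, 6.0)  # um
    diffuse_intensity: float = 60.0  # AFU added inside cells
    aggregate_logvol_mean: float = 0.5  # log_e(um^3)
    aggregate_logvol_sd: float = 0.5
    n_aggregates: int = 6
    spot_amplitude: float = 800.0  # AFU peak height above local signal
    noise_sd: float = 5.0  # AFU, additive Gaussian
    background_level: float = 10.0  # AFU
    max_intensity: float = 65535.0  # clip ceiling (16-bit by default)
    min_separation_um: float = 2.0  # minimal distance between planted spots
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0 or self.n_aggregates < 0:
            raise ValueError("counts must be >= 0")
        if self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise ValueError("cell_radius_range must be (low, high)")


@dataclass(frozen=True)
class AggregateTruth:
    centroid_px: tuple[float, float]  # (row, col)
    true_volume: float  # um^3
    amplitude: float  # AFU


@dataclass
class ImageGroundTruth:
    """Oracle for detection tests: cell mask, total volume, planted spots."""

    cell_mask: np.ndarray
    total_cell_volume: float  # um^3 (mask area x pixel_size^2 x 1 um)
    aggregates: list[AggregateTruth] = field(default_factory=list)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([a.true_volume for a in self.aggregates], dtype=float)

    @property
    def log_volumes(self) -> np.ndarray:
        v = self.volumes
        return np.log(v) if v.size else v


def _place_cells(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_shape
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_cells):
        r_um = rng.uniform(*cfg.cell_radius_range)
        r_px = r_um / cfg.pixel_size
        # keep the cell centre inside the frame with some margin
        cy = rng.uniform(r_px * 0.5, h - r_px * 0.5)
        cx = rng.uniform(r_px * 0.5, w - r_px * 0.5)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    return mask


def _place_aggregates(
    cfg: ImageSimConfig, cell_mask: np.ndarray, rng: np.random.Generator
) -> list[AggregateTruth]:
    if cfg.n_aggregates == 0:
        return []
    if not cell_mask.any():
        raise ValueError("aggregates requested but no cell present to host them")
    inside = np.argwhere(cell_mask)
    min_sep_px = cfg.min_separation_um / cfg.pixel_size
    centres: list[tuple[float, float]] = []
    aggs: list[AggregateTruth] = []
    attempts = 0
    while len(aggs) < cfg.n_aggregates:
        attempts += 1
        if attempts > 1000 * cfg.n_aggregates:
            raise RuntimeError(
                "could not place aggregates with the requested minimal separation"
            )
        idx = rng.integers(len(inside))
        cy, cx = map(float, inside[idx])
        if any((cy - y) ** 2 + (cx - x) ** 2 < min_sep_px**2 for y, x in centres):
            continue
        logv = rng.normal(cfg.aggregate_logvol_mean, cfg.aggregate_logvol_sd)
        centres.append((cy, cx))
        aggs.append(
            AggregateTruth(
                centroid_px=(cy, cx),
                true_volume=float(np.exp(logv)),
                amplitude=cfg.spot_amplitude,
            )
        )
    return aggs


def _render_spot(
    img: np.ndarray, agg: AggregateTruth, pixel_size: float
) -> None:
    s_px = spot_scale_um(agg.true_volume) / pixel_size
    cy, cx = agg.centroid_px
    ext = max(int(math.ceil(5 * s_px)), 2)
    r0, r1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, img.shape[0])
    c0, c1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, img.shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += agg.amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s_px**2)
    )


def gen_image(config: ImageSimConfig) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Render one synthetic image and its ground truth.

    The image is background + smooth diffuse cell signal + Gaussian spots +
    additive Gaussian noise, clipped to [0, max_intensity].
    """
    rng = np.random.default_rng(config.seed)
    cell_mask = _place_cells(config, rng)
    aggregates = _place_aggregates(config, cell_mask, rng)

    img = np.full(config.image_shape, float(config.background_level))
    if cell_mask.any():
        from scipy import ndimage

        # soften cell edges so the boundary step does not excite the band-pass
        soft = ndimage.gaussian_filter(cell_mask.astype(float), sigma=2.0)
        img += config.diffuse_intensity * soft
    for agg in aggregates:
        _render_spot(img, agg, config.pixel_size)
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=config.image_shape)
    img = np.clip(img, 0.0, config.max_intensity)

    total_volume = float(cell_mask.sum()) * config.pixel_size**2 * UNIT_DEPTH_UM
    truth = ImageGroundTruth(
        cell_mask=cell_mask, total_cell_volume=total_volume, aggregates=aggregates
    )
    return (
        CalibratedImage(img, config.pixel_size, source_id=f"sim-{config.seed}"),
        truth,
    )


@dataclass(frozen=True)
class TimecourseSimConfig:
    """Kinetic trajectory for an image time course.

    ``n_aggregates_by_time`` and ``logvol_mean_by_time`` map each sampled
    time (hours) to the planted aggregate count per image and the mean of the
    log_e-volume distribution; everything else comes from ``base``.  At least
    four images per time point matches the study's imaging floor.
    """

    times_h: tuple[float, ...]
    n_aggregates_by_time: dict[float, int]
    logvol_mean_by_time: dict[float, float]
    logvol_sd: float = 0.5
    images_per_timepoint: int = 4
    base: ImageSimConfig = field(default_factory=ImageSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.times_h) == 0:
            raise ValueError("time course needs at least one time point")
        allowed = set(TIMEPOINTS_H[1:])
        if not set(self.times_h) <= allowed:
            raise ValueError(f"imaging times must be a subset of {sorted(allowed)}")
        missing = [t for t in self.times_h if t not in self.n_aggregates_by_time]
        if missing:
            raise ValueError(f"no aggregate count configured for times {missing}")


def default_trajectory(seed: int = 0, images_per_timepoint: int = 4) -> TimecourseSimConfig:
    """Trajectory emulating the observed aggregation kinetics.

    No aggregates before 24 h; small aggregates appear at 24 h; counts peak
    at 48-72 h while the size distribution shifts towards larger volumes;
    counts drop again by 96-120 h with mostly large aggregates remaining.
    """
    times = (4.0, 8.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0)
    counts = {4.0: 0, 8.0: 0, 24.0: 4, 36.0: 8, 48.0: 12, 72.0: 12, 96.0: 7, 120.0: 6}
    logvol = {4.0: 0.0, 8.0: 0.0, 24.0: -0.5, 36.0: 0.0, 48.0: 0.5, 72.0: 1.5, 96.0: 1.5, 120.0: 1.5}
    return TimecourseSimConfig(
        times_h=times,
        n_aggregates_by_time=counts,
        logvol_mean_by_time=logvol,
        images_per_timepoint=images_per_timepoint,
        seed=seed,
    )


def gen_timecourse_images(
    config: TimecourseSimConfig,
) -> list[tuple[float, CalibratedImage, ImageGroundTruth]]:
    """Generate ``images_per_timepoint`` images for every configured time.

    Per-image seeds are derived deterministically from the global seed and
    the (time, replicate) index.
    """
    seq = np.random.SeedSequence(config.seed)
    out: list[tuple[float, CalibratedImage, ImageGroundTruth]] = []
    for i, t in enumerate(config.times_h):
        for j in range(config.images_per_timepoint):
            child = np.random.SeedSequence(
                entropy=seq.entropy, spawn_key=(i, j)
            ).generate_state(1)[0] % (2**31)
            cfg = replace(
                config.base,
                n_aggregates=config.n_aggregates_by_time[t],
                aggregate_logvol_mean=config.logvol_mean_by_time.get(t, 0.0),
                aggregate_logvol_sd=config.logvol_sd,
                seed=int(child),
            )
            img, truth = gen_image(cfg)
            img = CalibratedImage(
                img.intensities, img.pixel_size, source_id=f"t{t:g}h-rep{j}"
            )
            out.append((t, img, truth))
    return out
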