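"""File I/O: calibrated TIFF images with JSON sidecars, CSV/TSV tables.

Images travel as single-channel 16-bit grayscale TIFF plus a JSON sidecar
recording the pixel size (um) and source id; quantification results as CSV
(one row per spot) and JSON summaries; simulated array data and expression
results as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from polyqtc.imagequant import CalibratedImage, ImageQuantResult

__all__ = [
    "write_image",
    "read_image",
    "write_quant_result",
    "write_ground_truth",
    "write_array_data",
    "read_array_data",
]


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".json")


def write_image(path: str | Path, img: CalibratedImage) -> Path:
    """Write a 16-bit grayscale TIFF and its calibration sidecar."""
    path = Path(path)
    data = np.clip(np.round(img.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size_um": img.pixel_size, "source_id": img.source_id})
    )
    return path


def read_image(path: str | Path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read a grayscale TIFF; calibration from the sidecar unless overridden."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    source_id = path.stem
    if pixel_size_um is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no pixel calibration: sidecar {sidecar} missing and no "
                "pixel_size_um given"
            )
        meta = json.loads(sidecar.read_text())
        pixel_size_um = float(meta["pixel_size_um"])
        source_id = meta.get("source_id", source_id)
    return CalibratedImage(data, pixel_size_um, source_id=source_id)


def write_quant_result(outdir: str | Path, res: ImageQuantResult, stem: str) -> list[Path]:
    """Write the per-image spot CSV and JSON summary; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spot_rows = [
        {
            "id": s.id,
            "y_px": s.centroid[0],
            "x_px": s.centroid[1],
            "volume_um3": s.volume,
            "log_volume": s.log_volume,
            "integrated_intensity": s.integrated_intensity,
        }
        for s in res.spots.spots
    ]
    csv_path = outdir / f"{stem}_spots.csv"
    pd.DataFrame(
        spot_rows,
        columns=["id", "y_px", "x_px", "volume_um3", "log_volume", "integrated_intensity"],
    ).to_csv(csv_path, index=False)
    summary = {
        "source_id": res.source_id,
        "time_h": res.time_h,
        "total_cell_volume_um3": res.segmentation.total_cell_volume,
        "egfp_expression": res.egfp_expression,
        "n_spots": len(res.spots),
    }
    json_path = outdir / f"{stem}_summary.json"
    json_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return [csv_path, json_path]


def write_ground_truth(outdir: str | Path, truth, stem: str) -> list[Path]:
    """Write simulated ground truth: aggregate CSV + totals JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}_truth.csv"
    pd.DataFrame(
        [
            {
                "y_px": a.centroid_px[0],
                "x_px": a.centroid_px[1],
                "true_volume_um3": a.true_volume,
                "amplitude": a.amplitude,
            }
            for a in truth.aggregates
        ],
        columns=["y_px", "x_px", "true_volume_um3", "amplitude"],
    ).to_csv(csv_path, index=False)
    json_path = outdir / f"{stem}_truth.json"
    json_path.write_text(
        json.dumps(
            {
                "total_cell_volume_um3": truth.total_cell_volume,
                "n_aggregates": len(truth.aggregates),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return [csv_path, json_path]


def write_array_data(path: str | Path, long: pd.DataFrame) -> Path:
    path = Path(path)
    long.to_csv(path, sep="\t", index=False)
    return path


def read_array_data(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
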