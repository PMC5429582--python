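"""Evaluation of detections against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polyqtc.imagequant import SpotSet
from polyqtc.simdata.images import ImageGroundTruth

__all__ = ["DetectionEval", "match_detections"]


@dataclass
class DetectionEval:
    """Matched-pair evaluation of one image's detections."""

    n_truth: int
    n_detected: int
    n_matched: int
    true_volumes: np.ndarray  # matched pairs only
    measured_volumes: np.ndarray

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0

    @property
    def volume_rel_errors(self) -> np.ndarray:
        return np.abs(self.measured_volumes - self.true_volumes) / self.true_volumes


def match_detections(
    truth: ImageGroundTruth, spots: SpotSet, max_dist_px: float = 5.0
) -> DetectionEval:
    """Greedily pair detected spots with planted aggregates by centroid distance.

    Pairs are formed closest-first; each planted aggregate and each detection
    is used at most once, and pairs farther apart than ``max_dist_px`` are
    not formed.
    """
    t_xy = np.array([a.centroid_px for a in truth.aggregates], dtype=float).reshape(-1, 2)
    d_xy = np.array([s.centroid for s in spots.spots], dtype=float).reshape(-1, 2)
    t_vol = np.array([a.true_volume for a in truth.aggregates], dtype=float)
    d_vol = np.array([s.volume for s in spots.spots], dtype=float)

    pairs = []
    if len(t_xy) and len(d_xy):
        dist = np.linalg.norm(t_xy[:, None, :] - d_xy[None, :, :], axis=2)
        cand = sorted(
            ((dist[i, j], i, j) for i in range(len(t_xy)) for j in range(len(d_xy))),
            key=lambda c: c[0],
        )
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, i, j in cand:
            if d > max_dist_px:
                break
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            pairs.append((i, j))
    ti = [i for i, _ in pairs]
    dj = [j for _, j in pairs]
    return DetectionEval(
        n_truth=len(t_xy),
        n_detected=len(d_xy),
        n_matched=len(pairs),
        true_volumes=t_vol[ti],
        measured_volumes=d_vol[dj],
    )
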