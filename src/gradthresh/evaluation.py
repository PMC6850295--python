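"""Jaccard-index evaluation against gold-standard masks.

Segmentation quality is scored per gold object with the Jaccard index
``|A n B| / |A u B|`` (1 for a perfect match, 0 for no overlap).  Each gold
object is paired one-to-one with the test region of greatest pixel overlap
(ties broken by larger Jaccard, then smaller region id — the simplest
deterministic matcher; alternatives can be swapped in).  Gold objects left
unmatched contribute 0, so missed objects lower the mean.

The module also hosts the robustness harness: seeded additive Gaussian
noise and a sweep of noise levels, used to chart how segmentation quality
degrades as acquisition noise grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ParameterError
from .gradient_ops import GreyImage, SQUARE_3X3
from .region_threshold import SegmentationResult

__all__ = [
    "EvaluationReport",
    "jaccard",
    "match_objects",
    "exclude_border_regions",
    "add_gaussian_noise",
    "noise_sweep",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Per-gold-object matches and their mean Jaccard index."""

    matches: list[tuple[int, int | None, float]]  # (gold_id, test_id | None, jaccard)
    mean_jaccard: float
    n_gold: int
    n_test: int


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """``|a n b| / |a u b|`` of two boolean rasters; two empty sets give 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # identical empty sets
    return float(np.logical_and(a, b).sum() / union)


def _as_labels(test) -> np.ndarray:
    if isinstance(test, SegmentationResult):
        return test.labelled()
    arr = np.asarray(test)
    if arr.dtype == bool:
        labels, _ = ndimage.label(arr, structure=SQUARE_3X3)
        return labels
    return arr.astype(np.int64)


def match_objects(test, gold: np.ndarray) -> EvaluationReport:
    """Pair gold objects with test regions and average their Jaccard indices.

    ``test`` may be a :class:`SegmentationResult`, a boolean mask (labelled
    8-connected on the fly) or a label image.  ``gold`` is a label image
    with 0 background; it must contain at least one object.
    """
    gold = np.asarray(gold).astype(np.int64)
    test_labels = _as_labels(test)
    if gold.shape != test_labels.shape:
        raise ParameterError(f"shape mismatch {gold.shape} vs {test_labels.shape}")
    gold_ids = [int(g) for g in np.unique(gold) if g > 0]
    if not gold_ids:
        raise ParameterError("gold mask contains no objects")
    test_ids = [int(t) for t in np.unique(test_labels) if t > 0]

    gold_sizes = {g: int((gold == g).sum()) for g in gold_ids}
    test_sizes = {t: int((test_labels == t).sum()) for t in test_ids}
    # Pairwise intersection counts via a joint contingency table.
    pairs: dict[tuple[int, int], int] = {}
    both = (gold > 0) & (test_labels > 0)
    if both.any():
        g = gold[both]
        t = test_labels[both]
        keys, counts = np.unique(np.stack([g, t]), axis=1, return_counts=True)
        pairs = {(int(gi), int(ti)): int(c) for (gi, ti), c in zip(keys.T, counts)}

    available = set(test_ids)
    matches: list[tuple[int, int | None, float]] = []
    total = 0.0
    for gid in gold_ids:
        candidates = []
        for tid in available:
            inter = pairs.get((gid, tid), 0)
            if inter == 0:
                continue
            jac = inter / (gold_sizes[gid] + test_sizes[tid] - inter)
            candidates.append((inter, jac, -tid))
        if not candidates:
            matches.append((gid, None, 0.0))
            continue
        inter, jac, neg_tid = max(candidates)
        tid = -neg_tid
        available.discard(tid)
        matches.append((gid, tid, float(jac)))
        total += jac
    return EvaluationReport(matches, total / len(gold_ids), len(gold_ids), len(test_ids))


def exclude_border_regions(result: SegmentationResult) -> SegmentationResult:
    """Drop regions intersecting the image frame (the 'no borders' analysis)."""
    kept = [r for r in result.regions if not r.touches_border]
    mask = np.zeros(result.mask.shape, dtype=bool)
    for region in kept:
        mask[region.indices] = True
    return SegmentationResult(mask, kept)


def add_gaussian_noise(image: GreyImage, sd: float, seed: int) -> GreyImage:
    """Seeded i.i.d. zero-mean Gaussian noise, rounded and clipped to range."""
    if sd < 0:
        raise ParameterError(f"noise sd must be >= 0, got {sd}")
    if sd == 0:
        return image
    rng = np.random.default_rng(seed)
    noisy = image.pixels.astype(np.float64) + rng.normal(0.0, sd, image.shape)
    clipped = np.clip(np.rint(noisy), 0, image.max_representable)
    return GreyImage(clipped.astype(image.pixels.dtype), image.bit_depth)


def noise_sweep(
    scene,
    sds: Sequence[float],
    seeds: Sequence[int],
    segment: Callable[[GreyImage], SegmentationResult],
) -> pd.DataFrame:
    """Mean Jaccard versus noise sd, averaged over seeds.

    Noise is added to the scene image first; any smoothing belongs inside
    ``segment`` (mirroring the evaluation of a noisy acquisition).
    Returns a ``(sd, mean_jaccard)`` table.
    """
    if len(sds) == 0:
        raise ParameterError("need at least one noise sd")
    rows = []
    for sd in sds:
        scores = []
        for seed in seeds:
            noisy = add_gaussian_noise(scene.image, sd, seed)
            report = match_objects(segment(noisy), scene.gold)
            scores.append(report.mean_jaccard)
        rows.append({"sd": sd, "mean_jaccard": float(np.mean(scores))})
    return pd.DataFrame(rows)
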