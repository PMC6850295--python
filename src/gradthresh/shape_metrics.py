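"""Region area, perimeter and circularity for object specification.

Candidate regions are admitted into the analysis only if they look like the
objects being sought.  The admission test uses circularity,
``4 * pi * Area / Perimeter**2`` (1 for a perfect circle, -> 0 for elongated
shapes), together with inclusive area bounds in squared pixels.

The perimeter estimator is an 8-connected Moore contour trace through pixel
centres, summing 1 per axial step and sqrt(2) per diagonal step.  This is
the convention of common particle-analysis tools: a 10x10 solid square
measures 36, a single pixel is defined as 4 (its unit-square contour).
Chain-code estimators of this family overestimate the length of smooth
curves by a few percent depending on orientation, so digital disks plateau
at circularity ~0.9 rather than reaching 1; the published 0.4-0.5 operating
band for nuclei is insensitive to this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ObjectSpec",
    "region_area",
    "region_perimeter",
    "circularity",
    "passes_spec",
]


@dataclass(frozen=True)
class ObjectSpec:
    """Admission constraints for candidate regions.

    Defaults (circularity >= 0.5, area in [250, 3000] px^2) suit nuclei of
    ~10-30 px radius; scale the area bounds with the expected object size.
    ``max_area`` may be ``math.inf`` to leave the upper bound open.
    """

    min_circularity: float = 0.5
    min_area: float = 250
    max_area: float = 3000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ParameterError(
                f"min_circularity must be in [0, 1], got {self.min_circularity}"
            )
        if not 0 < self.min_area <= self.max_area:
            raise ParameterError(
                f"need 0 < min_area <= max_area, got ({self.min_area}, {self.max_area})"
            )


def _as_mask(region: np.ndarray) -> np.ndarray:
    mask = np.asarray(region, dtype=bool)
    if mask.ndim != 2:
        raise ParameterError("region must be a 2-D boolean raster")
    if not mask.any():
        raise ParameterError("region is empty")
    return mask


def region_area(region: np.ndarray) -> int:
    """Number of member pixels of a region."""
    return int(_as_mask(region).sum())


# Clockwise Moore neighbourhood starting East.
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_STEP_LEN = {d: math.hypot(*d) for d in _MOORE}


def region_perimeter(region: np.ndarray) -> float:
    """Length of the outer contour of a connected region.

    Moore (8-connected) boundary trace through pixel centres with
    Jacob's stopping criterion; axial steps count 1, diagonal steps
    sqrt(2).  A single pixel is defined to have perimeter 4.  Holes do
    not contribute (outer contour only).
    """
    mask = _as_mask(region)
    ys, xs = np.nonzero(mask)
    if len(ys) == 1:
        return 4.0
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    # Start at the topmost-leftmost pixel; its West neighbour is background.
    y0 = ys.min()
    start = (y0 + 1, int(xs[ys == y0].min()) + 1)
    backtrack = (start[0], start[1] - 1)

    perimeter = 0.0
    current = start
    first_move: tuple[int, int] | None = None
    max_steps = 4 * padded.size  # safety bound; the trace always closes before this
    for _ in range(max_steps):
        db = (backtrack[0] - current[0], backtrack[1] - current[1])
        i0 = _MOORE.index(db)
        nxt = None
        for k in range(1, 9):
            d = _MOORE[(i0 + k) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if padded[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel (cannot happen for len > 1 connected sets)
            return 4.0
        if current == start and first_move is not None and nxt == first_move:
            break  # closed the contour: re-leaving the start in the initial direction
        step = (nxt[0] - current[0], nxt[1] - current[1])
        perimeter += _STEP_LEN[step]
        if first_move is None:
            first_move = nxt
        current = nxt
    return perimeter


def circularity(region: np.ndarray) -> float:
    """``4 pi A / P^2``, capped at 1.0 (small digital squares can exceed it)."""
    area = region_area(region)
    perim = region_perimeter(region)
    return min(1.0, 4.0 * math.pi * area / perim**2)


def passes_spec(region: np.ndarray, spec: ObjectSpec) -> bool:
    """True iff the region meets the spec (all bounds inclusive)."""
    area = region_area(region)
    if not spec.min_area <= area <= spec.max_area:
        return False
    return circularity(region) >= spec.min_circularity
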