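"""Global threshold selection from the gradient of phase boundaries.

For an image ``I`` with dark objects on a bright background, every
candidate threshold ``L`` defines a phase ``B(L)`` (pixels valued 0..L) and
its one-pixel boundary ``E(L)``.  When ``L`` is optimal the phase boundary
coincides with the object edges, i.e. with the large values of the gradient
raster ``G``.  The method therefore scans every level between the image's
extreme grey values and records

* ``N(L)``       — the number of boundary pixels,
* ``G_Total(L)`` — the sum of ``G`` over ``E(L)``,
* ``G_Average(L) = G_Total(L) / N(L)`` (0 where the boundary is empty),

and picks the level maximising the chosen statistic.  The average statistic
weighs gradient strength by boundary length and frequently shows secondary
local maxima, which correspond to alternative or multiple thresholds (e.g.
nuclei vs whole cells in a two-tone specimen); ``find_threshold_maxima``
exposes those.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import NoPhaseError, ParameterError
from .gradient_ops import BinaryMask, GradientImage, GreyImage, phase_boundary

__all__ = [
    "Polarity",
    "GradientCurve",
    "threshold_phase",
    "gradient_curves",
    "find_optimal_threshold",
    "find_threshold_maxima",
]


class Polarity(str, enum.Enum):
    """Which side of the threshold is foreground."""

    DARK_OBJECTS = "dark_objects"    # foreground = pixels <= L
    BRIGHT_OBJECTS = "bright_objects"  # foreground = pixels >= L

    @classmethod
    def coerce(cls, value: "Polarity | str") -> "Polarity":
        if isinstance(value, cls):
            return value
        aliases = {"dark": cls.DARK_OBJECTS, "bright": cls.BRIGHT_OBJECTS}
        try:
            return aliases.get(value, cls(value))
        except ValueError:
            raise ParameterError(f"unknown polarity {value!r}") from None


@dataclass(frozen=True)
class GradientCurve:
    """Per-level boundary statistics N(L), G_Total(L), G_Average(L)."""

    levels: np.ndarray     # ascending integer levels, L_Min..L_Max
    n_boundary: np.ndarray
    g_total: np.ndarray
    g_average: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "n_boundary": self.n_boundary,
                "g_total": self.g_total,
                "g_average": self.g_average,
            }
        )

    def statistic(self, name: str) -> np.ndarray:
        if name == "total":
            return self.g_total
        if name == "average":
            return self.g_average
        raise ParameterError(f"unknown statistic {name!r}; use 'total' or 'average'")


def threshold_phase(
    image: GreyImage, level: int, polarity: Polarity | str = Polarity.DARK_OBJECTS
) -> BinaryMask:
    """Binary phase at a test threshold (level itself is foreground)."""
    polarity = Polarity.coerce(polarity)
    if not image.level_min <= level <= image.level_max:
        raise ParameterError(
            f"level {level} outside image range [{image.level_min}, {image.level_max}]"
        )
    if polarity is Polarity.DARK_OBJECTS:
        return image.pixels <= level
    return image.pixels >= level


def gradient_curves(
    image: GreyImage,
    gradient: GradientImage,
    polarity: Polarity | str = Polarity.DARK_OBJECTS,
    boundary_method: str = "internal_gradient",
) -> GradientCurve:
    """Exhaustive per-level scan of boundary-gradient statistics."""
    polarity = Polarity.coerce(polarity)
    gradient = np.asarray(gradient, dtype=np.float64)
    if gradient.shape != image.shape:
        raise ParameterError(
            f"gradient shape {gradient.shape} != image shape {image.shape}"
        )
    levels = np.arange(image.level_min, image.level_max + 1)
    n_boundary = np.zeros(levels.shape, dtype=np.int64)
    g_total = np.zeros(levels.shape, dtype=np.float64)
    for i, level in enumerate(levels):
        phase = threshold_phase(image, int(level), polarity)
        edge = phase_boundary(phase, boundary_method)
        n = int(edge.sum())
        n_boundary[i] = n
        if n:
            g_total[i] = gradient[edge].sum()
    with np.errstate(invalid="ignore"):
        g_average = np.where(n_boundary > 0, g_total / np.maximum(n_boundary, 1), 0.0)
    return GradientCurve(levels, n_boundary, g_total, g_average)


def find_optimal_threshold(curve: GradientCurve, statistic: str = "average") -> int:
    """Level maximising the statistic; ties break toward the smallest level.

    Levels with an empty boundary are excluded; if every level is empty a
    :class:`NoPhaseError` is raised.
    """
    values = curve.statistic(statistic)
    valid = curve.n_boundary > 0
    if not valid.any():
        raise NoPhaseError("no phase found: every level has an empty boundary")
    masked = np.where(valid, values, -np.inf)
    return int(curve.levels[int(np.argmax(masked))])


def find_threshold_maxima(
    curve: GradientCurve,
    statistic: str = "average",
    max_count: int = 2,
    min_prominence: float = 0.0,
) -> list[int]:
    """Interior local maxima of the statistic, ranked by value (descending).

    Plateau maxima are reported at their smallest level.  ``min_prominence``
    suppresses peaks rising less than that above the higher of their
    flanking minima.  Endpoints of the curve are not interior maxima, so a
    strictly monotone curve yields no entries.
    """
    if max_count < 1:
        raise ParameterError(f"max_count must be >= 1, got {max_count}")
    if min_prominence < 0:
        raise ParameterError(f"min_prominence must be >= 0, got {min_prominence}")
    values = curve.statistic(statistic).astype(np.float64)
    peaks, props = signal.find_peaks(
        values,
        plateau_size=(1, None),
        prominence=min_prominence if min_prominence > 0 else None,
    )
    if len(peaks) == 0:
        return []
    positions = props["left_edges"]  # smallest level of each plateau
    order = np.argsort(-values[positions], kind="stable")  # ties: lower level first
    chosen = positions[order][:max_count]
    return [int(curve.levels[p]) for p in chosen]
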