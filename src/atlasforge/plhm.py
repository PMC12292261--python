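"""Piecewise linear histogram matching (PLHM) intensity standardization.

Nyul-style two-stage normalization: *training* learns standard histogram
landmarks from a set of images; *transformation* maps each image's own
landmark percentiles onto the standard ones with a monotone piecewise-linear
function.  The standard scale is fixed to [0, 100].  Zero (background)
voxels of skull-stripped images are excluded from percentile estimation and
always map to exactly 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core import Volume

# Robust min/max anchors plus deciles: the method's canonical configuration.
DEFAULT_PERCENTILES: tuple[float, ...] = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                                          60.0, 70.0, 80.0, 90.0, 99.0)
SCALE_BOUNDS = (0.0, 100.0)


class DegenerateHistogramError(ValueError):
    """Raised when an image's foreground has no intensity spread."""


@dataclasses.dataclass
class StandardHistogram:
    """Learned standard landmarks on the fixed [0, 100] scale."""

    landmark_percentiles: tuple[float, ...]
    standard_landmarks: np.ndarray
    scale_bounds: tuple[float, float] = SCALE_BOUNDS

    def __post_init__(self) -> None:
        self.standard_landmarks = np.asarray(self.standard_landmarks, dtype=float)
        if len(self.standard_landmarks) != len(self.landmark_percentiles):
            raise ValueError("landmark count mismatch")
        if np.any(np.diff(self.standard_landmarks) < 0):
            raise ValueError("standard landmarks must be nondecreasing")
        lo, hi = self.scale_bounds
        if self.standard_landmarks.min() < lo or self.standard_landmarks.max() > hi:
            raise ValueError("standard landmarks outside scale bounds")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "landmark_percentiles": list(self.landmark_percentiles),
            "standard_landmarks": self.standard_landmarks.tolist(),
            "scale_bounds": list(self.scale_bounds),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardHistogram":
        obj = json.loads(Path(path).read_text())
        return cls(tuple(obj["landmark_percentiles"]),
                   np.asarray(obj["standard_landmarks"]),
                   tuple(obj["scale_bounds"]))


def _image_landmarks(vol: Volume, percentiles: tuple[float, ...]) -> np.ndarray:
    fg = vol.data[vol.data > 0]
    if fg.size < len(percentiles):
        raise DegenerateHistogramError(
            f"foreground has {fg.size} voxels, fewer than {len(percentiles)} landmarks"
        )
    marks = np.percentile(fg, percentiles)
    if marks[-1] - marks[0] <= 0:
        raise DegenerateHistogramError("degenerate histogram: constant foreground intensity")
    return marks


def learn_landmarks(
    images: list[Volume],
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
) -> StandardHistogram:
    """Learn standard landmarks: per-image landmarks are affinely rescaled to
    [0, 100] (anchors to the endpoints) and averaged across images; the
    endpoints themselves are pinned at exactly 0 and 100."""
    if not images:
        raise ValueError("need at least one training image")
    lo, hi = SCALE_BOUNDS
    rescaled = []
    for vol in images:
        marks = _image_landmarks(vol, percentiles)
        rescaled.append(lo + (marks - marks[0]) * (hi - lo) / (marks[-1] - marks[0]))
    standard = np.mean(rescaled, axis=0)
    standard[0], standard[-1] = lo, hi
    standard = np.maximum.accumulate(np.clip(standard, lo, hi))
    return StandardHistogram(tuple(percentiles), standard)


def apply_plhm(vol: Volume, hist: StandardHistogram) -> Volume:
    """Map an image onto the standard histogram.

    Foreground intensities are passed through the piecewise-linear function
    taking the image's own landmark percentiles to ``hist.standard_landmarks``
    (linear extrapolation at the robust anchors, then clipped to the scale
    bounds); background zeros stay exactly 0.
    """
    marks = _image_landmarks(vol, hist.landmark_percentiles)
    fg_mask = vol.data > 0
    values = vol.data[fg_mask]
    # np.interp clamps outside the landmark range; extend the end segments
    # linearly first so the robust anchors do not flatten the tails.
    mapped = np.interp(values, marks, hist.standard_landmarks)
    lo_slope = _segment_slope(marks, hist.standard_landmarks, 0)
    hi_slope = _segment_slope(marks, hist.standard_landmarks, -2)
    below = values < marks[0]
    above = values > marks[-1]
    mapped[below] = hist.standard_landmarks[0] + (values[below] - marks[0]) * lo_slope
    mapped[above] = hist.standard_landmarks[-1] + (values[above] - marks[-1]) * hi_slope
    out = np.zeros_like(vol.data)
    lo, hi = hist.scale_bounds
    # Foreground voxels stay strictly positive (floor just above 0) so the
    # foreground set — and hence the landmark estimation — is stable under
    # repeated application.
    out[fg_mask] = np.clip(mapped, max(lo, 1e-9), hi)
    return vol.like(out)


def _segment_slope(x: np.ndarray, y: np.ndarray, i: int) -> float:
    dx = x[i + 1] - x[i]
    return float((y[i + 1] - y[i]) / dx) if dx > 0 else 0.0
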