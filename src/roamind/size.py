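"""Worm-size estimation from cropped grayscale frames.

A frame is normalized against a background estimate as
f_norm = (f - b + 100) / 256 (8-bit grayscale), the worm contour is found
at the fixed level 0.34, and the pixels enclosed by a single closed contour
are counted. Frames with no closed contour or more than one (detection
failures, collisions with the arena edge) yield a missing value, and a
301-frame running median that skips missing frames smooths the series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "estimate_background",
    "normalize_frame",
    "frame_area",
    "running_median",
]


def estimate_background(frames: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pixel-wise mean of 8 equally spaced sample frames (first and last
    included)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 8:
        raise ValueError("need at least 8 frames")
    idx = np.round(np.linspace(0, frames.shape[0] - 1, 8)).astype(int)
    return frames[idx].mean(axis=0)


def normalize_frame(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Background-subtract and rescale: (f - b + 100) / 256.

    A pixel equal to the background maps to 100/256 ~ 0.391 (above the worm
    threshold); worm pixels, darker than the background, fall below it. The
    transform is invariant to adding a constant to both frame and
    background.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    return (frame - background + 100.0) / 256.0


def frame_area(normalized: np.ndarray, threshold: float = 0.34) -> float:
    """Pixels enclosed by the worm contour, or NaN if detection failed.

    Iso-contours of the normalized frame are traced at ``threshold``;
    exactly one closed contour is required — zero (no worm) or multiple
    (split detection, debris) give a missing value. The enclosed count
    includes pixels whose centers lie inside the contour polygon.
    """
    normalized = np.asarray(normalized, dtype=float)
    contours = measure.find_contours(normalized, threshold)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if len(closed) != 1:
        return float("nan")
    mask = measure.grid_points_in_poly(normalized.shape, closed[0])
    return float(mask.sum())


def running_median(areas: np.ndarray, window: int = 301) -> np.ndarray:
    """Centered running median skipping missing (NaN) frames.

    Window length must be odd (301 frames = 10 min at 3 fps in the default
    recordings). Edge frames use the truncated window of available values;
    an all-missing window stays missing.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    s = pd.Series(np.asarray(areas, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()
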