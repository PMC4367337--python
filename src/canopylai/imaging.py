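"""Upward-looking canopy photograph handling.

Reads RGB cover photographs, extracts the blue band (the channel that gives
the best contrast between foliage and sky/clouds), finds the foliage/sky
threshold automatically from the valley between the two histogram modes, and
binarizes the image into a foliage mask.

Conventions: pixel grids are row-major numpy arrays, origin at the top-left,
0-based indices.  In a :class:`BinaryCanopyMask`, ``True`` marks foliage;
``False`` marks sky (gap) pixels.  A pixel whose blue value is greater than
or equal to the threshold is classified as sky.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

__all__ = [
    "CanopyImage",
    "BlueBand",
    "BlueHistogram",
    "BinaryCanopyMask",
    "ThresholdFallbackWarning",
    "load_image",
    "extract_blue",
    "blue_histogram",
    "find_threshold",
    "binarize",
    "write_mask_png",
]

#: default moving-average window (intensity bins) for histogram smoothing
DEFAULT_SMOOTH_WINDOW = 9

#: minimum separation (intensity levels) between the two histogram modes
MIN_PEAK_SEPARATION = 10


class ThresholdFallbackWarning(UserWarning):
    """Emitted when the histogram has no interior valley and an
    Otsu-style between-class-variance split is used instead."""


@dataclass(frozen=True)
class CanopyImage:
    """One upward-looking RGB photograph.

    Attributes
    ----------
    pixels : ndarray, shape (height, width, 3), uint8
        8-bit RGB values.
    source_id : str
        Label identifying the tree and quadrant the photo belongs to.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("CanopyImage requires an RGB (H, W, 3) pixel array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1 pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class BlueBand:
    """Blue-channel intensities of a canopy image (same dimensions)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("BlueBand requires a 2-D array")
        object.__setattr__(self, "values", v.astype(np.uint8))


@dataclass(frozen=True)
class BlueHistogram:
    """256-bin intensity histogram of a blue band."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError("BlueHistogram requires exactly 256 counts")
        if (c < 0).any():
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryCanopyMask:
    """Per-pixel foliage/sky classification.

    ``is_foliage[r, c]`` is True for foliage and False for sky/gap pixels.
    """

    is_foliage: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        m = np.asarray(self.is_foliage, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not 0 <= int(self.threshold_used) <= 255:
            raise ValueError("threshold must be in [0, 255]")
        object.__setattr__(self, "is_foliage", m)
        object.__setattr__(self, "threshold_used", int(self.threshold_used))

    @property
    def shape(self) -> tuple[int, int]:
        return self.is_foliage.shape


def load_image(path: str | Path, source_id: str | None = None) -> CanopyImage:
    """Read a JPEG or PNG photograph without resampling.

    Parameters
    ----------
    path : path-like
        Location of an 8-bit RGB image file.
    source_id : str, optional
        Label to attach; defaults to the file stem.

    Raises
    ------
    FileNotFoundError / OSError
        If the file is missing or not decodable.
    ValueError
        If the image is not RGB (grayscale input is rejected rather than
        silently promoted: the method needs a real blue channel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("L", "LA", "I", "I;16", "F", "1"):
                raise ValueError(
                    f"RGB image required, got {mode}-mode (grayscale) file: {path}"
                )
            if mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except ValueError:
        raise
    except Exception as exc:  # undecodable / truncated file
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return CanopyImage(arr, source_id if source_id is not None else path.stem)


def extract_blue(image: CanopyImage) -> BlueBand:
    """Keep only the blue channel (450–495 nm), which separates foliage
    from sky and clouds best; red and green are discarded."""
    return BlueBand(image.pixels[:, :, 2])


def blue_histogram(band: BlueBand) -> BlueHistogram:
    """Tally blue intensities into 256 bins."""
    counts = np.bincount(band.values.ravel(), minlength=256)
    return BlueHistogram(counts)


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; values outside [0, 255] count as zero."""
    kernel = np.full(window, 1.0 / window)
    return np.convolve(counts.astype(float), kernel, mode="same")


def find_threshold(
    hist: BlueHistogram, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> int:
    """Automatic foliage/sky threshold from the blue-band histogram.

    The histogram is smoothed with a centered moving average of
    ``smooth_window`` bins, the two dominant modes (foliage at low blue,
    sky at high blue) are located, and the threshold is the intensity of
    the minimum of the smoothed histogram strictly between them.  A tie
    (flat valley) resolves to the midpoint of the minimal plateau.

    If the smoothed histogram has no two modes separated by at least
    ``MIN_PEAK_SEPARATION`` intensity levels, an Otsu between-class-variance
    split is used instead and a :class:`ThresholdFallbackWarning` is emitted.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if hist.total == 0:
        raise ValueError("empty histogram: no pixels to threshold")

    smoothed = _smooth(hist.counts, smooth_window)

    # pad so maxima touching the 0/255 boundary count as peaks
    padded = np.concatenate(([-1.0], smoothed, [-1.0]))
    peak_idx, _ = find_peaks(padded)
    peak_idx = peak_idx - 1  # undo the pad offset
    peak_idx = peak_idx[(peak_idx >= 0) & (peak_idx <= 255)]

    if len(peak_idx) >= 2:
        order = np.argsort(smoothed[peak_idx])[::-1]
        ranked = peak_idx[order]
        p1 = int(ranked[0])
        p2 = None
        for cand in ranked[1:]:
            if abs(int(cand) - p1) >= MIN_PEAK_SEPARATION:
                p2 = int(cand)
                break
        if p2 is not None:
            lo, hi = sorted((p1, p2))
            interior = smoothed[lo + 1 : hi]
            vmin = interior.min()
            at_min = np.flatnonzero(interior == vmin) + lo + 1
            # midpoint of the minimal plateau (deterministic tie rule)
            return int((at_min[0] + at_min[-1]) // 2)

    warnings.warn(
        "histogram is not bimodal after smoothing; "
        "falling back to a between-class-variance (Otsu) split",
        ThresholdFallbackWarning,
        stacklevel=2,
    )
    return _otsu_from_histogram(hist.counts)


def _otsu_from_histogram(counts: np.ndarray) -> int:
    """Between-class-variance-maximizing split of a 256-bin histogram."""
    nonzero = np.flatnonzero(counts)
    if len(nonzero) == 1:
        return int(nonzero[0])  # single intensity: split at that value
    t = threshold_otsu(hist=(counts.astype(float), np.arange(256.0)))
    return int(round(t))


def binarize(band: BlueBand, threshold: int) -> BinaryCanopyMask:
    """Classify pixels: blue < threshold ⇒ foliage, blue ≥ threshold ⇒ sky.

    Sky and clouds form the bright blue-band class, so the threshold itself
    belongs to the sky side.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return BinaryCanopyMask(band.values < threshold, threshold)


def write_mask_png(mask: BinaryCanopyMask, path: str | Path) -> None:
    """Debug output: foliage as black (0), sky as white (255)."""
    img = np.where(mask.is_foliage, 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(Path(path))
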