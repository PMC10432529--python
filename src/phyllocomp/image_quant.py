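"""Two-channel microscopy quantification of bioreporter cells.

Mirrors the classic ImageJ particle-analysis route: the constitutive red
channel is binarised with the iterative "intermodes" histogram threshold,
8-connected components are labelled, particles outside 0.5-2.5 µm² or
touching the image border are discarded, and the per-cell mean green
fluorescence is measured inside the retained masks.  Background green
fluorescence is sampled from a randomly placed cell-free patch per image.

The size window is interpreted as particle area in µm² (particle-analysis
semantics); the default pixel size of 0.045 µm/px corresponds to a 100x
widefield configuration and is a configuration value, not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as label_components
from skimage.measure import regionprops

__all__ = [
    "ChannelImage",
    "ThresholdError",
    "intermodes_threshold",
    "segment_cells",
    "measure_green",
    "sample_background",
    "quantify_image",
]

DEFAULT_PIXEL_SIZE = 0.045  # µm per pixel
MIN_AREA_UM2 = 0.5
MAX_AREA_UM2 = 2.5


class ThresholdError(RuntimeError):
    """Histogram never became bimodal under iterative smoothing."""


@dataclass
class ChannelImage:
    pixels: np.ndarray
    channel: str = "red"
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 65535:
            raise ValueError("intensities must fit a 16-bit range")


def intermodes_threshold(histogram: np.ndarray, max_iterations: int = 10000) -> int:
    """Intermodes threshold on a 256-bin histogram.

    The histogram is repeatedly smoothed with a running 3-bin mean until
    exactly two local maxima remain; the threshold is the floor of the
    midpoint between the two modes.  Raises :class:`ThresholdError` if the
    histogram never becomes bimodal within ``max_iterations``.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if h.sum() == 0:
        raise ValueError("empty histogram")

    def modes(arr: np.ndarray) -> np.ndarray:
        padded = np.concatenate([[-1.0], arr, [-1.0]])  # endpoint bins can be modes
        peaks = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
        return np.flatnonzero(peaks)

    for _ in range(max_iterations):
        peaks = modes(h)
        if len(peaks) == 2:
            return int((peaks[0] + peaks[1]) // 2)
        if len(peaks) < 2:
            break
        h = np.convolve(h, np.ones(3) / 3.0, mode="same")
    raise ThresholdError("histogram did not become bimodal; supply a manual threshold")


def _image_threshold(image: ChannelImage) -> float:
    """Map the 256-bin intermodes threshold back to the intensity scale."""
    pix = image.pixels.astype(float)
    lo, hi = float(pix.min()), float(pix.max())
    if hi <= lo:
        raise ThresholdError("constant image has no threshold")
    hist, edges = np.histogram(pix, bins=256, range=(lo, hi))
    t_bin = intermodes_threshold(hist)
    return edges[t_bin + 1]  # upper edge: everything above the midpoint bin


def segment_cells(red: ChannelImage, min_area: float = MIN_AREA_UM2,
                  max_area: float = MAX_AREA_UM2,
                  threshold: float | None = None) -> np.ndarray:
    """Label retained cells in the red channel.

    Thresholds with intermodes (or an explicit fallback ``threshold``),
    labels 8-connected components, and removes particles outside
    [``min_area``, ``max_area``] µm² or touching any image border.  Returns
    a relabelled integer mask (0 = background).
    """
    if threshold is None:
        threshold = _image_threshold(red)
    binary = red.pixels.astype(float) > threshold
    labels = label_components(binary, connectivity=2)
    px_area = red.pixel_size**2
    keep = np.zeros_like(labels)
    next_label = 1
    nrows, ncols = labels.shape
    for region in regionprops(labels):
        area_um2 = region.area * px_area
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == nrows or maxc == ncols
        if touches or not (min_area <= area_um2 <= max_area):
            continue
        keep[labels == region.label] = next_label
        next_label += 1
    return keep


def measure_green(mask: np.ndarray, green: ChannelImage,
                  red: ChannelImage | None = None) -> pd.DataFrame:
    """Per-cell mean green (and optionally red) intensity over mask pixels."""
    if mask.shape != green.pixels.shape:
        raise ValueError("mask and green image dimensions differ")
    px_area = green.pixel_size**2
    rows = []
    for region in regionprops(mask, intensity_image=green.pixels.astype(float)):
        row = {
            "cell_id": region.label,
            "area_um2": region.area * px_area,
            "centroid_r": region.centroid[0],
            "centroid_c": region.centroid[1],
            "green_intensity": region.intensity_mean,
        }
        if red is not None:
            row["red_intensity"] = float(red.pixels.astype(float)[mask == region.label].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id", "area_um2", "centroid_r", "centroid_c",
                                       "green_intensity"]
                        + (["red_intensity"] if red is not None else []))


def sample_background(green: ChannelImage, mask: np.ndarray, patch: int = 20,
                      seed: int = 0, max_attempts: int = 10000) -> float:
    """Mean intensity of one randomly placed, cell-free square patch."""
    if mask.shape != green.pixels.shape:
        raise ValueError("mask and image dimensions differ")
    nrows, ncols = mask.shape
    if patch > min(nrows, ncols):
        raise ValueError("patch larger than image")
    rng = np.random.default_rng(seed)
    occupied = mask > 0
    for _ in range(max_attempts):
        r = rng.integers(0, nrows - patch + 1)
        c = rng.integers(0, ncols - patch + 1)
        if not occupied[r:r + patch, c:c + patch].any():
            return float(green.pixels[r:r + patch, c:c + patch].mean())
    raise RuntimeError("no cell-free patch found; image may be confluent")


def quantify_image(red: ChannelImage, green: ChannelImage, fov: int = 0,
                   patch: int = 20, seed: int = 0, **segment_kwargs) -> pd.DataFrame:
    """Full per-image quantification producing CUSPER-ready cell records."""
    mask = segment_cells(red, **segment_kwargs)
    records = measure_green(mask, green, red=red)
    if records.empty:
        records["bg_green"] = pd.Series(dtype=float)
        records["fov"] = pd.Series(dtype=int)
        return records
    records["bg_green"] = sample_background(green, mask, patch=patch, seed=seed)
    records["fov"] = fov
    return records
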