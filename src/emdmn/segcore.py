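"""Thresholding and particle-measurement primitives.

These are the building blocks every image stage shares: histogram
auto-thresholding (Otsu, Intermodes, Yen -- the classic ImageJ methods,
computed on a 256-bin histogram of the rescaled image), connected-component
labelling, and per-particle morphometry (area, perimeter, circularity,
solidity, per-channel mean intensity) in physical units.

Conventions
-----------
* Images are 2-D arrays of arbitrary intensity scale; thresholding
  internally rescales to 8-bit [0, 255] and maps the chosen level back to
  the original scale.
* An optional ``floor`` (on the 8-bit scale) bounds the returned threshold
  from below; this guards against very dim backgrounds.
* Pixels strictly above the threshold are foreground.
* Coordinates are pixel-centred, origin top-left, ``x`` = column,
  ``y`` = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "DegenerateImageError",
    "FieldImage",
    "LabelMask",
    "Particle",
    "auto_threshold",
    "threshold_mask",
    "label_particles",
    "measure_particles",
]

THRESHOLD_METHODS = ("otsu", "intermodes", "yen")


class DegenerateImageError(ValueError):
    """Raised when an image has too few distinct values to threshold."""


@dataclass
class FieldImage:
    """A multi-channel 2-D field with physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"dapi"``, ``"emerin"``) to a 2-D
        intensity array. All channels must share one shape.
    pixel_size_um
        Pixel edge length in micrometres; must be positive.
    provenance
        Free-text note on where the field came from.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        for name, ch in self.channels.items():
            if np.asarray(ch).ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMask:
    """Connected-component labelling of a binary mask.

    ``labels`` holds 0 for background and consecutive integers
    1..``n_labels`` for objects.
    """

    labels: np.ndarray
    n_labels: int

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        if self.n_labels != len(present):
            raise ValueError("n_labels inconsistent with label image")
        if self.n_labels and present[-1] != self.n_labels:
            raise ValueError("labels must be consecutive 1..n_labels")

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class Particle:
    """Measurements of one labelled object.

    ``circularity`` is :math:`4\\pi A / P^2` capped at 1.0 (tiny rasterised
    objects can exceed 1 before capping, matching the ImageJ convention).
    ``solidity`` is area over convex-hull area.
    """

    label: int
    area_um2: float
    perimeter_um: float
    centroid_xy: tuple[float, float]
    circularity: float
    solidity: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    area_px: int = 0


def _rescale_to_8bit(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map image linearly onto integer levels 0..255; return levels, lo, hi.

    Images whose values already lie in [0, 255] are binned on the absolute
    8-bit scale (so a threshold floor keeps its meaning on dim images);
    wider-range images are min-max rescaled first.
    """
    img = np.asarray(image, dtype=float)
    lo = float(img.min())
    hi = float(img.max())
    if hi <= lo:
        raise DegenerateImageError("image is constant; cannot threshold")
    if 0.0 <= lo and hi <= 255.0:
        return np.rint(img).astype(np.int64), 0.0, 255.0
    levels = np.rint((img - lo) * (255.0 / (hi - lo))).astype(np.int64)
    return levels, lo, hi


def _otsu_level(hist: np.ndarray) -> int:
    """Level maximising between-class variance (class split: <= t vs > t)."""
    p = hist.astype(float) / hist.sum()
    idx = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * idx)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -np.inf
    # candidates 0..254: both classes must be non-empty
    var_between[255] = -np.inf
    return int(np.argmax(var_between))

def _yen_level(hist: np.ndarray) -> int:
    """Level maximising Yen's maximum-correlation criterion."""
    p = hist.astype(float) / hist.sum()
    p1 = np.cumsum(p)
    p1_sq = np.cumsum(p**2)
    p2_sq = p1_sq[-1] - p1_sq
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(p1_sq * p2_sq) + 2.0 * np.log(p1 * (1.0 - p1))
    crit[~np.isfinite(crit)] = -np.inf
    crit[255] = -np.inf
    return int(np.argmax(crit))


def _intermodes_level(hist: np.ndarray, max_iter: int = 10_000) -> int:
    """Midpoint between the two modes of the iteratively smoothed histogram.

    The histogram is smoothed with a window-3 moving average until exactly
    two local maxima remain; the threshold is the integer midpoint of the
    two peak positions. Histograms that never become bimodal raise
    :class:`DegenerateImageError`.
    """
    h = hist.astype(float)

    def modes(a: np.ndarray) -> np.ndarray:
        interior = (a[1:-1] > a[:-2]) & (a[1:-1] >= a[2:])
        return np.flatnonzero(interior) + 1

    for _ in range(max_iter):
        m = modes(h)
        if len(m) == 2:
            return int((m[0] + m[1]) // 2)
        if len(m) < 2:
            break
        # window-3 moving average with edge replication
        padded = np.concatenate(([h[0]], h, [h[-1]]))
        h = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    raise DegenerateImageError("histogram did not become bimodal (intermodes)")


_LEVEL_FUNCS = {
    "otsu": _otsu_level,
    "yen": _yen_level,
    "intermodes": _intermodes_level,
}


def auto_threshold(
    image: np.ndarray,
    method: str = "otsu",
    floor: float | None = None,
) -> float:
    """Compute an automatic threshold on the image's original scale.

    The image is rescaled to integer levels 0..255, a 256-bin histogram is
    formed, the named method selects a level, the optional ``floor`` (also
    on the 8-bit scale) bounds it from below, and the level is mapped back
    to the original intensity scale. Foreground is strictly above the
    returned value.

    Raises
    ------
    DegenerateImageError
        If the image is constant (or never bimodal, for intermodes).
    ValueError
        If ``method`` is unknown.
    """
    if method not in _LEVEL_FUNCS:
        raise ValueError(
            f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}"
        )
    levels, lo, hi = _rescale_to_8bit(image)
    hist = np.bincount(levels.ravel(), minlength=256)[:256]
    level = _LEVEL_FUNCS[method](hist)
    if floor is not None:
        level = max(level, float(floor))
    # place the cut halfway between level and level+1, so that for integer
    # 8-bit images "strictly above" reproduces the classic > level rule
    return lo + (level + 0.5) * (hi - lo) / 255.0


def threshold_mask(
    image: np.ndarray,
    method: str = "otsu",
    floor: float | None = None,
) -> np.ndarray:
    """Binary foreground mask: pixels strictly above the auto threshold."""
    thr = auto_threshold(image, method=method, floor=floor)
    return np.asarray(image, dtype=float) > thr


def label_particles(mask: np.ndarray, connectivity: int = 8) -> LabelMask:
    """Label connected components of a binary mask.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent;
    the default, matching ImageJ's Analyze Particles).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    labels, n = measure.label(
        mask, connectivity=1 if connectivity == 4 else 2, return_num=True
    )
    return LabelMask(labels=labels, n_labels=int(n))


def measure_particles(
    labels: LabelMask,
    intensity_channels: dict[str, np.ndarray] | None = None,
    pixel_size_um: float = 1.0,
) -> list[Particle]:
    """Measure every labelled object.

    Areas are pixel counts times ``pixel_size_um**2``; perimeters use the
    weighted contour estimate of ``skimage.measure.regionprops``. Mean
    intensities are computed per requested channel over the label's pixels.
    """
    intensity_channels = intensity_channels or {}
    props = measure.regionprops(labels.labels)
    means = {
        name: ndimage.mean(
            np.asarray(ch, dtype=float),
            labels=labels.labels,
            index=np.arange(1, labels.n_labels + 1),
        )
        for name, ch in intensity_channels.items()
    }
    particles: list[Particle] = []
    for i, rp in enumerate(props):
        area_px = int(rp.area)
        area = area_px * pixel_size_um**2
        perim = float(rp.perimeter) * pixel_size_um
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
        cy, cx = rp.centroid
        particles.append(
            Particle(
                label=int(rp.label),
                area_um2=area,
                perimeter_um=perim,
                centroid_xy=(float(cx), float(cy)),
                circularity=min(circ, 1.0),
                solidity=float(rp.solidity),
                mean_intensity={n: float(means[n][i]) for n in means},
                area_px=area_px,
            )
        )
    return particles
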