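"""Cell- and spheroid-level phenotype metrics.

Morphometry of the invasive phenotype: nuclear area and shape, focal
adhesion size from paxillin staining, the signed distance between the
microtubule-organizing centre (MTOC, pericentrin) and the nucleus,
structure-tensor coherency of F-actin fibres, spheroid shape with
invading-cell counting, and migration path statistics from exported
single-cell tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segcore import (
    DegenerateImageError,
    LabelMask,
    Particle,
    label_particles,
    measure_particles,
    threshold_mask,
)

__all__ = [
    "MtocResult",
    "SpheroidMetrics",
    "TrackPath",
    "nuclear_shape",
    "focal_adhesion_sizes",
    "mtoc_nucleus_distance",
    "factin_coherency",
    "spheroid_metrics",
    "path_statistics",
    "read_tracks",
]


@dataclass
class MtocResult:
    """Signed centrosome-to-nucleus distance for one cell.

    ``distance_um`` is negative exactly when the centrosome centroid lies
    within the nucleus footprint (the 2-D reading of a centrosome sitting
    over the nucleus).
    """

    distance_um: float
    centrosome_xy: tuple[float, float]
    nearest_border_xy: tuple[float, float]


@dataclass
class SpheroidMetrics:
    area_um2: float
    circularity: float
    solidity: float
    n_invading: int


@dataclass
class TrackPath:
    """One migration track: samples of (t minutes, x um, y um)."""

    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_min) == len(self.x_um) == len(self.y_um)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("time stamps must be strictly increasing")


def nuclear_shape(
    dapi: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 20.0,
    floor: float | None = 25.0,
) -> list[Particle]:
    """Per-nucleus area (um^2), circularity and solidity from DAPI.

    Otsu segmentation (8-bit floor), hole filling, small-object removal,
    then standard particle measurement.
    """
    mask = threshold_mask(dapi, method="otsu", floor=floor)
    mask = ndimage.binary_fill_holes(mask)
    lab = label_particles(mask, connectivity=8)
    parts = measure_particles(lab, pixel_size_um=pixel_size_um)
    return [p for p in parts if p.area_um2 >= min_area_um2]


def focal_adhesion_sizes(
    paxillin: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_um: float,
    floor: float | None = 25.0,
) -> dict:
    """Focal-adhesion morphometry for one cell.

    The paxillin signal is segmented with an Intermodes threshold (8-bit
    floor) restricted to ``cell_mask``, particles are measured, and the
    per-cell mean FA area is reported. A cell without any particle yields
    ``count 0`` and a *missing* (NaN) mean, never 0.
    """
    paxillin = np.asarray(paxillin, dtype=float)
    cell_mask = np.asarray(cell_mask).astype(bool)
    try:
        mask = threshold_mask(paxillin, method="intermodes", floor=floor) & cell_mask
    except DegenerateImageError:
        # unimodal histogram: no adhesion signal distinguishable from background
        mask = np.zeros_like(cell_mask)
    lab = label_particles(mask, connectivity=8)
    parts = measure_particles(
        lab, intensity_channels={"paxillin": paxillin}, pixel_size_um=pixel_size_um
    )
    areas = np.array([p.area_um2 for p in parts])
    return {
        "count": len(parts),
        "mean_area_um2": float(areas.mean()) if len(parts) else float("nan"),
        "particles": parts,
    }


def mtoc_nucleus_distance(
    pericentrin: np.ndarray,
    dapi: np.ndarray,
    pixel_size_um: float,
    pericentrin_floor: float | None = 25.0,
    dapi_floor: float | None = 100.0,
) -> MtocResult | None:
    """Signed distance from the centrosome to the closest nucleus border.

    The pericentrin channel is segmented with a Yen threshold and the
    largest component taken as the centrosome; the nucleus comes from an
    Otsu threshold of DAPI (floor 100 on the 8-bit scale, suppressing dim
    cytoplasmic background). The distance is the minimum Euclidean
    distance (um) from the centrosome centroid to the nucleus border
    pixels, with negative sign when the centroid falls inside the nucleus
    footprint. Returns ``None`` when no pericentrin signal survives the
    threshold.
    """
    peri = np.asarray(pericentrin, dtype=float)
    dapi = np.asarray(dapi, dtype=float)
    try:
        peri_mask = threshold_mask(peri, method="yen", floor=pericentrin_floor)
    except ValueError:
        return None
    lab = label_particles(peri_mask, connectivity=8)
    if lab.n_labels == 0:
        return None
    counts = np.bincount(lab.labels.ravel())[1:]
    centrosome = lab.labels == (int(np.argmax(counts)) + 1)
    cy, cx = ndimage.center_of_mass(centrosome)

    nuc_mask = threshold_mask(dapi, method="otsu", floor=dapi_floor)
    nuc_mask = ndimage.binary_fill_holes(nuc_mask)
    if not nuc_mask.any():
        return None
    border = nuc_mask & ~ndimage.binary_erosion(nuc_mask)
    br, bc = np.nonzero(border)
    d2 = (br - cy) ** 2 + (bc - cx) ** 2
    k = int(np.argmin(d2))
    dist = float(np.sqrt(d2[k])) * pixel_size_um
    inside = nuc_mask[int(round(cy)), int(round(cx))]
    return MtocResult(
        distance_um=-dist if inside else dist,
        centrosome_xy=(float(cx), float(cy)),
        nearest_border_xy=(float(bc[k]), float(br[k])),
    )


def factin_coherency(
    factin: np.ndarray,
    cell_mask: np.ndarray | None = None,
    window_sigma_um: float = 2.0,
    pixel_size_um: float = 0.3,
    grad_sigma_px: float = 1.0,
) -> float:
    """Mean structure-tensor coherency of the F-actin texture in a cell.

    Gradients are Gaussian derivatives (``grad_sigma_px``, a numerical
    kernel width in pixels); their outer products are averaged with a
    Gaussian integration window of ``window_sigma_um``. Per pixel the
    coherency is ``(l1 - l2) / (l1 + l2)`` for tensor eigenvalues
    ``l1 >= l2 >= 0`` (0 by convention where the tensor vanishes, e.g. a
    constant image); the mean over ``cell_mask`` is returned. Values lie
    in [0, 1]; 1 means perfectly parallel fibres. Reflective boundary
    handling keeps the measure invariant to affine intensity rescaling.
    """
    img = np.asarray(factin, dtype=float)
    if cell_mask is None:
        cell_mask = np.ones(img.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask).astype(bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    win = max(window_sigma_um / pixel_size_um, 1.0)
    gx = ndimage.gaussian_filter(img, grad_sigma_px, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(img, grad_sigma_px, order=(1, 0), mode="reflect")
    Axx = ndimage.gaussian_filter(gx * gx, win, mode="reflect")
    Axy = ndimage.gaussian_filter(gx * gy, win, mode="reflect")
    Ayy = ndimage.gaussian_filter(gy * gy, win, mode="reflect")
    trace = Axx + Ayy
    # eigenvalue gap of a symmetric 2x2 tensor
    gap = np.sqrt((Axx - Ayy) ** 2 + 4.0 * Axy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(trace > 0, gap / trace, 0.0)
    return float(coh[cell_mask].mean())


def spheroid_metrics(
    body_mask: np.ndarray,
    nuclei_centroids_xy: list[tuple[float, float]],
    pixel_size_um: float,
) -> SpheroidMetrics:
    """Shape of the main spheroid body plus the invading-cell count.

    The main body is the largest connected component of ``body_mask``; an
    invading cell is one whose nucleus centroid falls outside that body.
    """
    body_mask = np.asarray(body_mask).astype(bool)
    lab = label_particles(body_mask, connectivity=8)
    if lab.n_labels == 0:
        raise ValueError("spheroid body mask is empty")
    counts = np.bincount(lab.labels.ravel())[1:]
    main_id = int(np.argmax(counts)) + 1
    main = LabelMask(labels=(lab.labels == main_id).astype(int), n_labels=1)
    p = measure_particles(main, pixel_size_um=pixel_size_um)[0]
    n_inv = 0
    body = main.labels > 0
    for x, y in nuclei_centroids_xy:
        r = min(max(int(round(y)), 0), body.shape[0] - 1)
        c = min(max(int(round(x)), 0), body.shape[1] - 1)
        if not body[r, c]:
            n_inv += 1
    return SpheroidMetrics(
        area_um2=p.area_um2,
        circularity=p.circularity,
        solidity=p.solidity,
        n_invading=n_inv,
    )


def path_statistics(path: TrackPath) -> tuple[float, float]:
    """Total path length (um) and mean velocity (um/min) of one track.

    The length is the sum of consecutive Euclidean steps; the velocity is
    that length divided by the elapsed time. Requires at least two samples.
    """
    if len(path.t_min) < 2:
        raise ValueError("a path needs at least two samples")
    steps = np.hypot(np.diff(path.x_um), np.diff(path.y_um))
    total = float(steps.sum())
    elapsed = float(path.t_min[-1] - path.t_min[0])
    return total, total / elapsed


def read_tracks(csv_path) -> dict[int, TrackPath]:
    """Read tracks from a CSV with columns track_id, t_min, x_um, y_um."""
    df = pd.read_csv(csv_path)
    required = {"track_id", "t_min", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"track CSV must have columns {sorted(required)}")
    out: dict[int, TrackPath] = {}
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("t_min")
        out[int(tid)] = TrackPath(
            t_min=grp["t_min"].to_numpy(),
            x_um=grp["x_um"].to_numpy(),
            y_um=grp["y_um"].to_numpy(),
        )
    return out
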