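"""Intensity-ratio statistics: DAPI content, NE pauperization, MN/NE Emerin.

Three dimensionless ratios quantify where chromatin and Emerin sit:

* :func:`dapi_content_ratio` -- mean DAPI in a micronucleus over mean DAPI
  in its parent nucleus (reduced DNA content in Emerin-rich MN).
* :func:`ne_cytoplasm_ratio` -- mean Emerin over the NE ring divided by the
  *median* Emerin of a cytoplasmic annulus; a low value indicates Emerin
  pauperization at the envelope.
* :func:`mn_ne_ratio` -- mean Emerin in an MN over the NE ring mean; values
  near 2 characterise Emerin-rich MN.

All ratios are invariant to multiplying the image by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segcore import auto_threshold

__all__ = ["RatioResult", "dapi_content_ratio", "ne_cytoplasm_ratio", "mn_ne_ratio"]


@dataclass
class RatioResult:
    """A computed intensity ratio with its provenance."""

    value: float
    numerator_mean: float
    denominator_stat: float
    masks_used: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("intensity ratios are non-negative")


def _check_mask(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError(f"{name} mask is empty")
    return mask


def dapi_content_ratio(
    dapi: np.ndarray, mn_mask: np.ndarray, nucleus_mask: np.ndarray
) -> RatioResult:
    """Mean DAPI over the MN mask divided by mean DAPI over the nucleus mask."""
    dapi = np.asarray(dapi, dtype=float)
    mn_mask = _check_mask(mn_mask, "mn")
    nucleus_mask = _check_mask(nucleus_mask, "nucleus")
    num = float(dapi[mn_mask].mean())
    den = float(dapi[nucleus_mask].mean())
    if den <= 0:
        raise ValueError("nucleus mean DAPI is zero; ratio undefined")
    return RatioResult(
        value=num / den,
        numerator_mean=num,
        denominator_stat=den,
        masks_used={"mn_px": int(mn_mask.sum()), "nucleus_px": int(nucleus_mask.sum())},
    )


def ne_cytoplasm_ratio(
    emerin: np.ndarray,
    nucleus_mask: np.ndarray,
    ring_width_um: float = 0.9,
    cyto_annulus_um: float = 3.0,
    pixel_size_um: float = 0.3,
    cell_mask: np.ndarray | None = None,
) -> RatioResult:
    """NE-ring mean over cytoplasmic-annulus median Emerin.

    The NE ring is ``dilation(nucleus, w) - erosion(nucleus, w)`` with
    ``w = ring_width_um``; the cytoplasm is the annulus between ``w`` and
    ``w + cyto_annulus_um`` beyond the nucleus, intersected with the cell
    region. When ``cell_mask`` is not supplied the cell is delimited by an
    Intermodes threshold (8-bit floor 25) of the Emerin channel; pass an
    explicit mask (e.g. all-True) to skip that segmentation. The
    denominator is the *median* cytoplasmic intensity, which is robust to
    bright vesicular puncta.

    Raises :class:`ValueError` when the annulus is empty (cell cropped at
    the border or fully masked out).
    """
    emerin = np.asarray(emerin, dtype=float)
    nucleus_mask = _check_mask(nucleus_mask, "nucleus")

    w_px = max(int(round(ring_width_um / pixel_size_um)), 1)
    outer_px = max(int(round((ring_width_um + cyto_annulus_um) / pixel_size_um)), w_px + 1)
    ring = (
        ndimage.binary_dilation(nucleus_mask, _disk(w_px))
        & ~ndimage.binary_erosion(nucleus_mask, _disk(w_px))
    )
    if cell_mask is None:
        # delimit the cell with an Intermodes threshold; the NE band is by
        # construction not cytoplasm, so it is excluded from the histogram
        # with a one-ring-width guard margin (otherwise the bright envelope
        # forms a third mode and the cut lands above the cytoplasm level)
        guard = (
            ndimage.binary_dilation(nucleus_mask, _disk(2 * w_px))
            & ~ndimage.binary_erosion(nucleus_mask, _disk(2 * w_px))
        )
        thr = auto_threshold(emerin[~guard], method="intermodes", floor=25.0)
        cell_mask = (emerin > thr) | nucleus_mask
    else:
        cell_mask = np.asarray(cell_mask).astype(bool)
    annulus = (
        ndimage.binary_dilation(nucleus_mask, _disk(outer_px))
        & ~ndimage.binary_dilation(nucleus_mask, _disk(w_px))
        & cell_mask
    )
    if not annulus.any():
        raise ValueError("cytoplasmic annulus is empty; cannot form ratio")
    num = float(emerin[ring].mean())
    den = float(np.median(emerin[annulus]))
    if den <= 0:
        raise ValueError("cytoplasmic median is zero; ratio undefined")
    return RatioResult(
        value=num / den,
        numerator_mean=num,
        denominator_stat=den,
        masks_used={"ring_px": int(ring.sum()), "annulus_px": int(annulus.sum())},
    )


def mn_ne_ratio(
    emerin: np.ndarray, mn_mask: np.ndarray, ne_ring_mask: np.ndarray
) -> RatioResult:
    """Mean Emerin over the MN mask divided by the NE-ring mean."""
    emerin = np.asarray(emerin, dtype=float)
    mn_mask = _check_mask(mn_mask, "mn")
    ne_ring_mask = _check_mask(ne_ring_mask, "ne_ring")
    num = float(emerin[mn_mask].mean())
    den = float(emerin[ne_ring_mask].mean())
    if den <= 0:
        raise ValueError("NE ring mean is zero; ratio undefined")
    return RatioResult(
        value=num / den,
        numerator_mean=num,
        denominator_stat=den,
        masks_used={"mn_px": int(mn_mask.sum()), "ring_px": int(ne_ring_mask.sum())},
    )


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return xx**2 + yy**2 <= radius**2
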