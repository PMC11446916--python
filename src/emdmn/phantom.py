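"""Synthetic fluorescence phantoms and expression/survival cohorts.

Every downstream stage of the pipeline is benchmarked against data with
known ground truth. Two generators live here:

* :func:`generate_field` paints a 2-D two-channel (DAPI + Emerin) field:
  elliptical nuclei whose nuclear envelope (NE) carries an Emerin rim at a
  reference intensity, plus small extranuclear micronuclei (MN) of two
  classes -- "rich" MN whose Emerin is a multiple (default 2x) of the NE
  level and whose DAPI is reduced (default 0.5x the nuclear level), and
  "NE-level" MN at 1x both.
* :func:`generate_cohort` draws a gene-by-sample count matrix in which a
  9-gene signature is shifted upward in a "pauperized" subgroup, together
  with exponential survival times realising a prescribed hazard ratio
  between subgroups.

Both are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .segcore import FieldImage

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "CohortSimParams",
    "PlacementError",
    "generate_field",
    "generate_cohort",
    "DEFAULT_SIGNATURE",
]

#: The 9-gene Emerin-pauperization signature.
DEFAULT_SIGNATURE = (
    "CXCR4", "APOE", "SPARC", "VIM", "GSN", "ANXA2P2", "SFRP1", "COL18A1", "FN1",
)


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed without forbidden overlap."""


@dataclass
class PhantomParams:
    """Parameters of a phantom microscopy field.

    Intensities are painted on an arbitrary linear scale with the NE rim at
    ``ne_intensity`` and the nucleus DAPI fill at ``dapi_intensity``; MN are
    painted at ``factor x`` those references. The NE rim straddles the
    nucleus boundary, extending ``ne_rim_width_um`` inward and outward
    (matching the measurement ring used to read the NE reference back).

    Defaults emulate a 20x widefield field of view: 0.3 um/px, 20 nuclei
    with semi-axes 3.5-6 um, 4 rich + 4 NE-level MN of 1-8 um^2 each,
    rich Emerin at 2.0x the NE level and rich DAPI at 0.5x the nucleus.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.3
    n_nuclei: int = 20
    nucleus_axes_um: tuple[float, float] = (3.5, 6.0)
    ne_rim_width_um: float = 0.9
    n_mn_rich: int = 4
    n_mn_ne: int = 4
    mn_area_um2_range: tuple[float, float] = (1.0, 8.0)
    mn_max_dist_um: float = 12.0
    mn_clearance_um: float = 0.6
    rich_emerin_factor: float = 2.0
    ne_level_emerin_factor: float = 1.0
    rich_dapi_factor: float = 0.5
    ne_level_dapi_factor: float = 1.0
    cytoplasm_emerin_factor: float = 0.0
    noise_sd: float = 4.0
    background: float = 10.0
    ne_intensity: float = 100.0
    dapi_intensity: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.field_size_px) < 16:
            raise ValueError("field_size_px too small")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_nuclei < 0 or self.n_mn_rich < 0 or self.n_mn_ne < 0:
            raise ValueError("object counts must be non-negative")
        if not self.rich_emerin_factor > self.ne_level_emerin_factor >= 0:
            raise ValueError(
                "require rich_emerin_factor > ne_level_emerin_factor >= 0"
            )
        lo, hi = self.mn_area_um2_range
        if not 0 < lo <= hi:
            raise ValueError("mn_area_um2_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class MNTruth:
    centroid_xy: tuple[float, float]
    area_um2: float
    mn_class: str  # "rich" | "ne_level"
    emerin_factor: float
    dapi_factor: float


@dataclass
class NucleusTruth:
    centroid_xy: tuple[float, float]
    axes_um: tuple[float, float]
    angle_rad: float


@dataclass
class GroundTruth:
    """Planted objects of one phantom field, one entry per painted object."""

    nuclei: list[NucleusTruth] = dataclass_field(default_factory=list)
    mn: list[MNTruth] = dataclass_field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nuclei": [asdict(n) for n in self.nuclei],
                "mn": [asdict(m) for m in self.mn],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            nuclei=[
                NucleusTruth(
                    centroid_xy=tuple(n["centroid_xy"]),
                    axes_um=tuple(n["axes_um"]),
                    angle_rad=n["angle_rad"],
                )
                for n in d["nuclei"]
            ],
            mn=[
                MNTruth(
                    centroid_xy=tuple(m["centroid_xy"]),
                    area_um2=m["area_um2"],
                    mn_class=m["mn_class"],
                    emerin_factor=m["emerin_factor"],
                    dapi_factor=m["dapi_factor"],
                )
                for m in d["mn"]
            ],
        )


def _ellipse_mask(shape, cx, cy, a_px, b_px, angle):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(angle), np.sin(angle)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _ellipse_norm(shape, cx, cy, a_px, b_px, angle):
    """Normalised elliptical radius (1.0 on the boundary) per pixel."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(angle), np.sin(angle)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)


_MAX_ATTEMPTS = 1000


def generate_field(params: PhantomParams) -> tuple[FieldImage, GroundTruth]:
    """Paint one phantom field and return it with its ground truth.

    Nuclei are ellipses filled with DAPI at ``dapi_intensity`` and carry an
    Emerin NE rim of half-width ``ne_rim_width_um`` about the boundary at
    ``ne_intensity``. MN are disks placed outside all nuclei footprints
    (rim included) but within ``mn_max_dist_um`` of the nearest nucleus --
    micronuclei derive from a parent nucleus and sit beside it -- by
    rejection sampling (1000 attempts per object; exhaustion raises
    :class:`PlacementError` naming the object). MN are
    painted at ``emerin_factor x ne_intensity`` in the Emerin channel and
    ``dapi_factor x dapi_intensity`` in DAPI. Additive Gaussian noise
    (``noise_sd``) is applied last and clipped at zero.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size_px
    ps = params.pixel_size_um
    shape = (h, w)

    dapi = np.full(shape, params.background, dtype=float)
    emerin = np.full(shape, params.background, dtype=float)

    # footprint of everything placed so far (nuclei incl. rim; then MN)
    occupied = np.zeros(shape, dtype=bool)
    truth = GroundTruth()

    rim_half_px = max(params.ne_rim_width_um / ps, 0.5)
    a_lo, a_hi = params.nucleus_axes_um

    for i in range(params.n_nuclei):
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            a_um = rng.uniform(a_lo, a_hi)
            b_um = rng.uniform(a_lo, a_hi)
            angle = rng.uniform(0, np.pi)
            a_px, b_px = a_um / ps, b_um / ps
            margin = max(a_px, b_px) + rim_half_px + 2
            if 2 * margin >= min(h, w):
                continue
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            r = _ellipse_norm(shape, cx, cy, a_px, b_px, angle)
            outer = r <= 1.0 + rim_half_px / min(a_px, b_px)
            if (outer & occupied).any():
                continue
            interior = r <= 1.0
            # rim: band of +- rim_half_px (in elliptical-normal units per axis)
            rim = np.abs(r - 1.0) <= rim_half_px / min(a_px, b_px)
            if params.cytoplasm_emerin_factor > 0:
                cyto = (r > 1.0) & (
                    r <= 1.0 + (6.0 / ps) / min(a_px, b_px)
                )
                emerin[cyto] = (
                    params.cytoplasm_emerin_factor * params.ne_intensity
                )
            dapi[interior] = params.dapi_intensity
            emerin[rim] = params.ne_intensity
            occupied |= outer
            truth.nuclei.append(
                NucleusTruth(
                    centroid_xy=(float(cx), float(cy)),
                    axes_um=(float(a_um), float(b_um)),
                    angle_rad=float(angle),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place nucleus {i + 1}")

    mn_specs = [
        ("rich", params.rich_emerin_factor, params.rich_dapi_factor)
    ] * params.n_mn_rich + [
        ("ne_level", params.ne_level_emerin_factor, params.ne_level_dapi_factor)
    ] * params.n_mn_ne

    # micronuclei bud off a parent nucleus, so they are planted within
    # mn_max_dist_um of the nearest nucleus footprint
    if params.n_nuclei > 0:
        dist_to_nucleus = ndimage.distance_transform_edt(~occupied) * ps
    else:
        dist_to_nucleus = np.zeros(shape)

    lo_area, hi_area = params.mn_area_um2_range
    for j, (cls, ef, df) in enumerate(mn_specs):
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            area_um2 = rng.uniform(lo_area, hi_area)
            r_px = max(np.sqrt(area_um2 / np.pi) / ps, 1.0)
            margin = r_px + 2
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if dist_to_nucleus[int(cy), int(cx)] > params.mn_max_dist_um:
                continue
            disk = _ellipse_mask(shape, cx, cy, r_px, r_px, 0.0)
            # enforce a clearance so discrete bodies never abut pixel-to-pixel
            clear_px = r_px + params.mn_clearance_um / ps
            halo = _ellipse_mask(shape, cx, cy, clear_px, clear_px, 0.0)
            if (halo & occupied).any() or not disk.any():
                continue
            emerin[disk] = ef * params.ne_intensity
            dapi[disk] = df * params.dapi_intensity
            occupied |= disk
            truth.mn.append(
                MNTruth(
                    centroid_xy=(float(cx), float(cy)),
                    area_um2=float(disk.sum() * ps**2),
                    mn_class=cls,
                    emerin_factor=float(ef),
                    dapi_factor=float(df),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place micronucleus {j + 1} ({cls})")

    if params.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, params.noise_sd, shape)
        emerin = emerin + rng.normal(0.0, params.noise_sd, shape)
    dapi = np.clip(dapi, 0.0, None)
    emerin = np.clip(emerin, 0.0, None)

    field = FieldImage(
        channels={"dapi": dapi, "emerin": emerin},
        pixel_size_um=ps,
        provenance=f"phantom seed={params.seed}",
    )
    return field, truth


@dataclass
class CohortSimParams:
    """Parameters of a synthetic expression + survival cohort.

    ``effect_log2`` is the mean upward log2 shift of the signature genes in
    the pauperized subgroup; ``true_hr`` the hazard ratio of that subgroup's
    exponential survival distribution relative to the rest. Censoring uses
    an independent uniform administrative time whose horizon is solved so
    the expected censored fraction equals ``censor_frac``. The defaults
    (n = 500, HR 1.75, 25% pauperized, 60% censoring) emulate a
    localized-prostate-cancer cohort followed for biochemical recurrence.
    """

    n_samples: int = 500
    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE
    n_noise_genes: int = 100
    effect_log2: float = 1.0
    frac_pauperized: float = 0.25
    true_hr: float = 1.75
    censor_frac: float = 0.6
    baseline_hazard_per_month: float = np.log(2) / 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8 for a meaningful quartile split")
        if not 0 < self.frac_pauperized < 1:
            raise ValueError("frac_pauperized must be in (0, 1)")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")
        if len(self.signature_genes) != 9:
            raise ValueError("signature must contain exactly 9 genes")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")


def _censor_horizon(lam0: float, lam1: float, frac1: float, target: float) -> float:
    """Uniform(0, m) horizon giving expected censored fraction = target."""
    def frac_censored(m):
        # P(T > C) for T ~ Exp(lam), C ~ U(0, m): (1 - exp(-lam m)) / (lam m)
        def f(lam):
            return (1.0 - np.exp(-lam * m)) / (lam * m)
        return (1 - frac1) * f(lam0) + frac1 * f(lam1)

    return brentq(lambda m: frac_censored(m) - target, 1e-6, 1e7)


def generate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a gene x sample count matrix, true labels, and survival.

    Returns
    -------
    matrix : DataFrame, genes x samples
        Log-normal counts on the linear (normalized-count) scale; the
        signature genes are shifted by ``effect_log2`` (in log2) in
        pauperized samples.
    labels : Series of bool, indexed by sample
        True where the sample is pauperized (the planted group).
    survival : DataFrame with columns sample, time, event
        Exponential event times with hazard ratio ``true_hr`` for the
        pauperized group, censored by a uniform administrative time.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    n_pauper = int(round(params.frac_pauperized * n))
    is_pauper = np.zeros(n, dtype=bool)
    is_pauper[rng.choice(n, size=n_pauper, replace=False)] = True

    sig = list(params.signature_genes)
    noise_genes = [f"NOISE{i + 1:04d}" for i in range(params.n_noise_genes)]
    genes = sig + noise_genes

    # per-gene baseline expression on log2 scale, biological + technical spread
    base_log2 = rng.uniform(4.0, 10.0, size=len(genes))
    log2_expr = (
        base_log2[:, None] + rng.normal(0.0, 0.8, size=(len(genes), n))
    )
    log2_expr[: len(sig), :] += params.effect_log2 * is_pauper[None, :]
    matrix = pd.DataFrame(2.0 ** log2_expr, index=genes, columns=samples)

    lam0 = params.baseline_hazard_per_month
    lam1 = lam0 * params.true_hr
    lam = np.where(is_pauper, lam1, lam0)
    t_event = rng.exponential(1.0 / lam)
    if params.censor_frac > 0:
        horizon = _censor_horizon(
            lam0, lam1, n_pauper / n, params.censor_frac
        )
        t_censor = rng.uniform(0.0, horizon, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    labels = pd.Series(is_pauper, index=samples, name="pauperized")
    survival = pd.DataFrame({"sample": samples, "time": time, "event": event})
    return matrix, labels, survival
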