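"""File formats: multi-page TIFF fields, ground truth JSON, cohort CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import GroundTruth
from .segcore import FieldImage

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_ground_truth",
    "read_ground_truth",
    "write_cohort",
    "read_matrix",
    "read_survival",
]


def write_field_tiff(field: FieldImage, path) -> None:
    """Write a field as a multi-page 16-bit TIFF, one page per channel.

    Channel names and the pixel size travel in each page's description as
    JSON. Floating-point intensities are rounded and clipped to uint16.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        for name, ch in field.channels.items():
            data = np.clip(np.rint(np.asarray(ch, dtype=float)), 0, 65535)
            tw.write(
                data.astype(np.uint16),
                description=json.dumps(
                    {"channel": name, "pixel_size_um": field.pixel_size_um}
                ),
            )


def read_field_tiff(path, channel_names: list[str] | None = None,
                    pixel_size_um: float | None = None) -> FieldImage:
    """Read a multi-page TIFF back into a :class:`FieldImage`.

    Channel names are taken from page descriptions when present; otherwise
    ``channel_names`` (or ``ch0``, ``ch1``, ...) is used. An explicit
    ``pixel_size_um`` overrides any value stored in the file.
    """
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    ps = pixel_size_um
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            name = None
            desc = page.description
            if desc:
                try:
                    meta = json.loads(desc)
                    name = meta.get("channel")
                    if ps is None and "pixel_size_um" in meta:
                        ps = float(meta["pixel_size_um"])
                except (json.JSONDecodeError, AttributeError):
                    pass
            if name is None:
                name = (
                    channel_names[i]
                    if channel_names and i < len(channel_names)
                    else f"ch{i}"
                )
            channels[name] = page.asarray().astype(float)
    if ps is None:
        raise ValueError(f"pixel size not stored in {path}; pass pixel_size_um")
    return FieldImage(channels=channels, pixel_size_um=ps, provenance=str(path))


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_cohort(matrix: pd.DataFrame, labels: pd.Series,
                 survival: pd.DataFrame, out_dir) -> None:
    """Write a cohort as CSVs: genes x samples matrix, labels, survival."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "expression.csv")
    labels.to_frame().to_csv(out / "labels.csv")
    survival.to_csv(out / "survival.csv", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample CSV/TSV; first column holds gene identifiers."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_survival(path) -> pd.DataFrame:
    """Read a survival CSV with columns sample, time, event."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for want in ("sample", "time", "event"):
        match = [c for lc, c in cols.items() if lc.startswith(want)]
        if not match:
            raise ValueError(f"survival table lacks a '{want}' column")
        df = df.rename(columns={match[0]: want})
    return df[["sample", "time", "event"]]
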