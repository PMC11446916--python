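"""Pipeline orchestration: run configuration and the end-to-end stages.

A :class:`RunConfig` gathers every tunable of the image workflow (channel
map, pixel size, thresholds, gates, stratification cutoffs, seed) in one
JSON-serializable document so that a report can always be traced back to
the exact parameters that produced it. :func:`run_quantify` executes the
micronucleus workflow over a directory of TIFF fields and emits per-field
and per-MN CSVs plus a JSON run log; :func:`concordance` scores detected
MN against a ground-truth file by centroid matching.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mn
from .io import read_field_tiff, read_ground_truth
from .mn import StratificationCutoffs
from .phantom import GroundTruth
from .segcore import FieldImage

__all__ = ["RunConfig", "run_quantify", "quantify_one", "match_mn"]


@dataclass
class RunConfig:
    """Every knob of the image workflow, with module-level defaults."""

    dapi_channel: str = "dapi"
    emerin_channel: str = "emerin"
    pixel_size_um: float = 0.3
    nucleus_floor_8bit: float = 25.0
    emerin_floor_8bit: float = 25.0
    min_nucleus_area_um2: float = 20.0
    ring_width_um: float = 0.9
    size_gate_um2: tuple[float, float] = (0.2, 12.0)
    rich_ratio: float = 1.2
    d_max_um: float = 15.0
    cutoffs: StratificationCutoffs = field(default_factory=StratificationCutoffs)
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "cutoffs" in d and isinstance(d["cutoffs"], dict):
            d["cutoffs"] = StratificationCutoffs(**d["cutoffs"])
        if "size_gate_um2" in d:
            d["size_gate_um2"] = tuple(d["size_gate_um2"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def quantify_one(field: FieldImage, config: RunConfig):
    """Run the MN workflow on one in-memory field with a config."""
    return mn.quantify_field(
        field,
        dapi_channel=config.dapi_channel,
        emerin_channel=config.emerin_channel,
        min_nucleus_area_um2=config.min_nucleus_area_um2,
        ring_width_um=config.ring_width_um,
        size_gate_um2=config.size_gate_um2,
        rich_ratio=config.rich_ratio,
        d_max_um=config.d_max_um,
    )


def match_mn(
    truth: GroundTruth,
    records: list[mn.MNRecord],
    pixel_size_um: float,
    match_radius_um: float = 2.0,
) -> dict:
    """Match planted MN to detections by centroid distance.

    Greedy nearest-first one-to-one matching within ``match_radius_um``.
    Returns recall/precision plus the class-confusion counts over matched
    pairs.
    """
    planted = [(m.centroid_xy, m.mn_class) for m in truth.mn]
    detected = [(r.particle.centroid_xy, r.mn_class) for r in records]
    pairs = []
    for i, ((px, py), _) in enumerate(planted):
        for j, ((dx, dy), _) in enumerate(detected):
            d = np.hypot(px - dx, py - dy) * pixel_size_um
            if d <= match_radius_um:
                pairs.append((d, i, j))
    pairs.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matches.append((i, j))
    n_match = len(matches)
    class_correct = sum(
        planted[i][1] == detected[j][1] for i, j in matches
    )
    return {
        "n_planted": len(planted),
        "n_detected": len(detected),
        "n_matched": n_match,
        "recall": n_match / len(planted) if planted else float("nan"),
        "precision": n_match / len(detected) if detected else float("nan"),
        "class_accuracy": class_correct / n_match if n_match else float("nan"),
    }


def run_quantify(
    image_paths: list[Path],
    config: RunConfig,
    out_dir: Path,
    truth_paths: dict[str, Path] | None = None,
) -> dict:
    """Quantify every field, write CSV reports and a JSON run log.

    ``truth_paths`` optionally maps field names to ground-truth JSON files;
    when present, detection concordance is scored and included in the
    summary. Returns the summary dict (also written to ``run_log.json``).
    """
    if not image_paths:
        raise ValueError("no input images given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    field_rows = []
    mn_rows = []
    concord = []
    for path in sorted(Path(p) for p in image_paths):
        fld = read_field_tiff(path, pixel_size_um=config.pixel_size_um)
        summary, records, _ = quantify_one(fld, config)
        strat = mn.stratify([summary.rich_per_nucleus], config.cutoffs)[0]
        field_rows.append(
            {
                "field": path.stem,
                "n_nuclei": summary.n_nuclei,
                "n_rich": summary.n_rich,
                "n_ne_level": summary.n_ne_level,
                "n_dropped_unassigned": summary.n_dropped_unassigned,
                "rich_per_nucleus": summary.rich_per_nucleus,
                "stratum": strat,
            }
        )
        for r in records:
            mn_rows.append(
                {
                    "field": path.stem,
                    "mn_class": r.mn_class,
                    "nucleus_id": r.nucleus_id,
                    "emerin_ratio_to_ne": r.emerin_ratio_to_ne,
                    "area_um2": r.particle.area_um2,
                    "x_px": r.particle.centroid_xy[0],
                    "y_px": r.particle.centroid_xy[1],
                }
            )
        if truth_paths and path.stem in truth_paths:
            truth = read_ground_truth(truth_paths[path.stem])
            concord.append(
                match_mn(truth, records, config.pixel_size_um)
            )

    pd.DataFrame(field_rows).to_csv(out_dir / "fields.csv", index=False)
    pd.DataFrame(mn_rows).to_csv(out_dir / "micronuclei.csv", index=False)
    summary = {
        "n_fields": len(field_rows),
        "n_mn_total": len(mn_rows),
        "config": json.loads(config.to_json()),
    }
    if concord:
        summary["concordance"] = {
            "mean_recall": float(np.mean([c["recall"] for c in concord])),
            "mean_precision": float(np.mean([c["precision"] for c in concord])),
            "mean_class_accuracy": float(
                np.mean([c["class_accuracy"] for c in concord])
            ),
        }
    (out_dir / "run_log.json").write_text(json.dumps(summary, indent=2))
    return summary
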