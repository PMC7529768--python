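"""Readers and writers for cell tables, configs and result files.

Cell tables are plain CSV with a header row and columns
``colony_id, cell_id, cell_type, x_um, y_um`` (coordinates in um with six
decimal places, '.' decimal separator, UTF-8).  Results are JSON; run
configurations are YAML or JSON documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Micropattern, disc, ellipse
from .metric import GroundTruth, FittedBorder
from .shapes import CircleFit, EllipseFit
from .simulator import Colony

CELL_TABLE_COLUMNS = ["colony_id", "cell_id", "cell_type", "x_um", "y_um"]


def colonies_to_table(colonies: list[Colony]) -> pd.DataFrame:
    """Flatten final colony snapshots into a cell table."""
    rows = []
    for cid, c in enumerate(colonies):
        for i in range(c.n_cells):
            rows.append((cid, c.ids[i], c.types[i], c.xs[i], c.ys[i]))
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    table[CELL_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: not a cell table (missing {missing})")
    return table


def pattern_to_config(pattern: Micropattern) -> dict:
    return {
        "kind": pattern.kind,
        "disc_radius": pattern.disc_radius,
        "semi_major": pattern.semi_major,
        "semi_minor": pattern.semi_minor,
        "interior_margin": pattern.interior_margin,
    }


def pattern_from_config(cfg: dict) -> Micropattern:
    kind = cfg.get("kind", "disc")
    if kind == "disc":
        return disc(
            radius=float(cfg.get("disc_radius", 97.5)),
            interior_margin=float(cfg.get("interior_margin", 2.0)),
        )
    return ellipse(
        semi_major=float(cfg.get("semi_major", 195.5)),
        semi_minor=float(cfg.get("semi_minor", 49.0)),
        interior_margin=float(cfg.get("interior_margin", 2.0)),
    )


def _border_to_dict(border: FittedBorder) -> dict:
    comps = []
    for c in border.components:
        if isinstance(c, CircleFit):
            comps.append({"shape": "circle", "cx": c.cx, "cy": c.cy, "r": c.r})
        else:
            comps.append(
                {"shape": "ellipse", "cx": c.cx, "cy": c.cy, "a": c.a, "b": c.b,
                 "theta": c.theta}
            )
    return {"shape": border.shape, "hda_side": border.hda_side,
            "symmetrized": border.symmetrized, "components": comps}


def _border_from_dict(d: dict) -> FittedBorder:
    comps = []
    for c in d["components"]:
        if c["shape"] == "circle":
            comps.append(CircleFit(c["cx"], c["cy"], c["r"]))
        else:
            comps.append(EllipseFit(c["cx"], c["cy"], c["a"], c["b"], c["theta"]))
    return FittedBorder(d["shape"], comps, d["hda_side"], d["symmetrized"])


def write_ground_truth(gt: GroundTruth, path) -> None:
    doc = {
        "pattern": pattern_to_config(gt.pattern),
        "borders": {k: _border_to_dict(v) for k, v in gt.borders.items()},
        "te": gt.te,
        "bandwidths": {k: list(v) for k, v in gt.bandwidths.items()},
        "thresholds": gt.thresholds,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        pattern=pattern_from_config(doc["pattern"]),
        borders={k: _border_from_dict(v) for k, v in doc["borders"].items()},
        te={k: float(v) for k, v in doc["te"].items()},
        bandwidths={k: tuple(float(x) for x in v) for k, v in doc["bandwidths"].items()},
        thresholds={k: float(v) for k, v in doc["thresholds"].items()},
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
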