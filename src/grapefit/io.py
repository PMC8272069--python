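"""File I/O: probability-map PNGs, box tables, phenotype records, scenes.

Probability maps are stored as 8-bit grayscale PNG with ``value =
round(255 * p)`` — lossy to 1/255 by design, for universal tooling support.
All CSV files are comma-separated UTF-8 with a mandatory header row and '.'
as the decimal separator.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import Ellipse
from .pipeline import CandidateBox, PhenotypeRecord
from .synthetic import SceneGroundTruth

__all__ = [
    "read_image",
    "write_probability_map",
    "read_probability_map",
    "read_boxes",
    "write_boxes",
    "write_records",
    "read_records",
    "write_scene",
    "read_scene_ground_truth",
    "load_benchmark_table",
]

RECORD_COLUMNS = [
    "grape_id",
    "cx",
    "cy",
    "a",
    "b",
    "theta",
    "long_axis_px",
    "area_px2",
    "fitness",
]
BOX_COLUMNS = ["x_min", "y_min", "x_max", "y_max", "score"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as float in [0, 1] (grayscale stays 2-D)."""
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def write_probability_map(path: str | Path, p: np.ndarray) -> None:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.min() < 0 or p.max() > 1:
        raise ValueError("probability map must be 2-D with values in [0, 1]")
    iio.imwrite(Path(path), np.round(p * 255.0).astype(np.uint8))


def read_probability_map(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(float) / 255.0


def read_boxes(path: str | Path, one_based_closed: bool = False) -> list[CandidateBox]:
    """Read candidate boxes from CSV or JSON (keyed x_min/y_min/x_max/y_max).

    With ``one_based_closed=True`` the coordinates are interpreted in the
    1-based closed convention common in annotation tools and converted.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    boxes = []
    for row in rows:
        x0, y0, x1, y1 = (float(row[k]) for k in BOX_COLUMNS[:4])
        if one_based_closed:
            x0, y0 = x0 - 1, y0 - 1  # x1/y1 stay: closed max == half-open max - 1 + 1
        score = row.get("score")
        if score is not None and (isinstance(score, float) and np.isnan(score)):
            score = None
        boxes.append(
            CandidateBox(int(x0), int(y0), int(x1), int(y1), None if score is None else float(score))
        )
    return boxes


def write_boxes(path: str | Path, boxes: list[CandidateBox]) -> None:
    pd.DataFrame([asdict(b) for b in boxes], columns=BOX_COLUMNS).to_csv(path, index=False)


def write_records(path: str | Path, records: list[PhenotypeRecord]) -> None:
    """Write phenotype records as CSV or JSON, chosen by file suffix."""
    rows = [
        {
            "grape_id": r.grape_id,
            "cx": r.ellipse.cx,
            "cy": r.ellipse.cy,
            "a": r.ellipse.a,
            "b": r.ellipse.b,
            "theta": r.ellipse.theta,
            "long_axis_px": r.long_axis_px,
            "area_px2": r.area_px2,
            "fitness": r.fitness,
            "box": asdict(r.box),
        }
        for r in records
    ]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        flat = [{k: v for k, v in row.items() if k != "box"} for row in rows]
        pd.DataFrame(flat, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        return pd.DataFrame([{k: v for k, v in r.items() if k != "box"} for r in rows])
    return pd.read_csv(path)


def write_scene(
    out_dir: str | Path, edge_map: np.ndarray, gt: SceneGroundTruth, prefix: str = "scene"
) -> dict[str, Path]:
    """Write a synthetic scene: edge-map PNG, boxes CSV, ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edge_map": out_dir / f"{prefix}_edges.png",
        "boxes": out_dir / f"{prefix}_boxes.csv",
        "truth": out_dir / f"{prefix}_truth.json",
    }
    iio.imwrite(paths["edge_map"], (np.asarray(edge_map) > 0).astype(np.uint8) * 255)
    write_boxes(paths["boxes"], gt.boxes)
    payload = {
        "ellipses": [asdict(e) for e in gt.ellipses],
        "visible_arcs": gt.visible_arcs,
        "boxes": [asdict(b) for b in gt.boxes],
        "areas": gt.areas,
        "visible_fraction": gt.visible_fraction,
    }
    paths["truth"].write_text(json.dumps(payload, indent=2))
    return paths


def read_scene_ground_truth(path: str | Path) -> SceneGroundTruth:
    data = json.loads(Path(path).read_text())
    return SceneGroundTruth(
        ellipses=[Ellipse(**e) for e in data["ellipses"]],
        visible_arcs=[[tuple(iv) for iv in arcs] for arcs in data["visible_arcs"]],
        boxes=[CandidateBox(**b) for b in data["boxes"]],
        areas=list(data["areas"]),
        visible_fraction=list(data["visible_fraction"]),
    )


def load_benchmark_table(kind: str) -> pd.DataFrame:
    """Load a bundled benchmark measurement table.

    ``kind`` is ``'long_axis'`` or ``'projected_area'``. Columns are the
    per-method measurements (``least_squares``, ``aamed``, ``elsd``,
    ``ours``) and the manually measured ``ground_truth``, in pixels /
    square pixels.
    """
    if kind not in ("long_axis", "projected_area"):
        raise ValueError("kind must be 'long_axis' or 'projected_area'")
    ref = resources.files("grapefit.data") / f"{kind}_benchmark.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
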