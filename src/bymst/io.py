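"""Plain-text persistence: CSV panels, CSV/GeoJSON geometry, YAML/JSON
truth records and indicator sidecars, columnar draw storage with a JSON
manifest."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deprivation import IndicatorTable
from .inference import PosteriorDraws
from .model import ModelSpec, PANEL_COLUMNS
from .synthetic_data import Geometry, TruthRecord


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    return panel


def write_geometry(geometry: Geometry, path: str | Path) -> None:
    """CSV (tract_id,x,y) or GeoJSON points, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        features = [
            {
                "type": "Feature",
                "properties": {"tract_id": str(t)},
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            }
            for t, x, y in zip(geometry.tract_id, geometry.x, geometry.y)
        ]
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
    else:
        geometry.to_frame().to_csv(path, index=False)


def read_geometry(path: str | Path) -> Geometry:
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        doc = json.loads(path.read_text())
        ids, xs, ys = [], [], []
        for feat in doc["features"]:
            ids.append(feat["properties"]["tract_id"])
            x, y = feat["geometry"]["coordinates"]
            xs.append(x)
            ys.append(y)
        frame = pd.DataFrame({"tract_id": ids, "x": xs, "y": ys})
    else:
        frame = pd.read_csv(path)
    xy = frame[["x", "y"]].to_numpy(dtype=float)
    from scipy.spatial.distance import pdist, squareform

    return Geometry(
        tract_id=frame["tract_id"].to_numpy(),
        x=xy[:, 0],
        y=xy[:, 1],
        pairwise_distance=squareform(pdist(xy)),
    )


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    doc = {}
    for f in dataclasses.fields(truth):
        v = getattr(truth, f.name)
        if v is None:
            continue
        doc[f.name] = np.asarray(v).tolist() if isinstance(v, np.ndarray) else float(v)
    Path(path).write_text(yaml.safe_dump(doc))


def read_truth(path: str | Path) -> TruthRecord:
    doc = yaml.safe_load(Path(path).read_text())
    arrays = {
        k: np.asarray(v)
        for k, v in doc.items()
        if k in {"beta", "gamma", "upsilon", "S", "tau_t", "eta"}
    }
    scalars = {k: v for k, v in doc.items() if k not in arrays}
    return TruthRecord(**scalars, **arrays)


def read_model_spec(path: str | Path) -> ModelSpec:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return ModelSpec(**doc)


def write_indicators(table: IndicatorTable, values_path: str | Path, orientation_path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "tract_id", table.tract_id)
    out.to_csv(values_path, index=False)
    Path(orientation_path).write_text(
        yaml.safe_dump(
            {c: int(o) for c, o in zip(table.values.columns, table.orientation)}
        )
    )


def read_indicators(values_path: str | Path, orientation_path: str | Path | None = None) -> IndicatorTable:
    frame = pd.read_csv(values_path)
    ids = frame.pop("tract_id").to_numpy()
    orientation = None
    if orientation_path is not None:
        doc = yaml.safe_load(Path(orientation_path).read_text())
        orientation = np.array([doc[c] for c in frame.columns], dtype=float)
    return IndicatorTable(tract_id=ids, values=frame, orientation=orientation)


def write_draws(draws: PosteriorDraws, out_dir: str | Path) -> None:
    """Columnar text storage: one CSV of flattened draws + a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols, manifest_vars = {}, {}
    for name, arr in draws.draws.items():
        flat = np.asarray(arr, dtype=float).reshape(draws.n_kept, -1)
        manifest_vars[name] = list(np.asarray(arr).shape[1:])
        for j in range(flat.shape[1]):
            cols[f"{name}[{j}]" if flat.shape[1] > 1 else name] = flat[:, j]
    cols["loglik"] = draws.loglik
    pd.DataFrame(cols).to_csv(out / "draws.csv", index=False)
    if draws.loglik_rows is not None:
        np.savetxt(out / "loglik_rows.csv", draws.loglik_rows, delimiter=",")
    manifest = {
        "variables": manifest_vars,
        "n_kept": draws.n_kept,
        "n_burnin": draws.n_burnin,
        "thin": draws.thin,
        "seed": draws.seed,
        "acceptance": draws.acceptance,
        "spec": dataclasses.asdict(draws.spec),
        "tract_ids": [str(t) for t in draws.tract_ids],
        "years": [int(y) for y in draws.years],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_draws(out_dir: str | Path) -> PosteriorDraws:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    frame = pd.read_csv(out / "draws.csv")
    n_kept = manifest["n_kept"]
    draws = {}
    for name, shape in manifest["variables"].items():
        size = int(np.prod(shape)) if shape else 1
        if size == 1 and not shape:
            draws[name] = frame[name].to_numpy()
        else:
            block = np.column_stack(
                [frame[f"{name}[{j}]"].to_numpy() for j in range(size)]
            )
            draws[name] = block.reshape([n_kept] + shape)
    rows_path = out / "loglik_rows.csv"
    loglik_rows = (
        np.loadtxt(rows_path, delimiter=",", ndmin=2) if rows_path.exists() else None
    )
    return PosteriorDraws(
        draws=draws,
        loglik=frame["loglik"].to_numpy(),
        loglik_rows=loglik_rows,
        n_kept=n_kept,
        n_burnin=manifest["n_burnin"],
        thin=manifest["thin"],
        seed=manifest["seed"],
        acceptance=manifest["acceptance"],
        spec=ModelSpec(**manifest["spec"]),
        tract_ids=np.array(manifest["tract_ids"]),
        years=np.array(manifest["years"]),
    )
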