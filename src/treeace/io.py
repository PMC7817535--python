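"""File I/O contracts: tree table, pedigree and CI CSVs, truth JSON,
crown polygons GeoJSON, and input validation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "write_trees", "read_trees", "write_pedigree", "read_pedigree",
    "write_truth", "read_truth", "write_crown_geojson", "validate_inputs",
]

TREE_COLUMNS = ["tree_id", "family", "control", "rep", "iblock",
                "row", "col", "x", "y", "alive"]
TRAIT_COLUMNS = ["H", "DBH", "V", "D38", "A"]


def write_trees(trees: pd.DataFrame, path: str) -> None:
    cols = [c for c in TREE_COLUMNS + TRAIT_COLUMNS if c in trees.columns]
    extra = [c for c in trees.columns if c not in cols]
    trees[cols + extra].to_csv(path, index=False)


def read_trees(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tree table missing columns {missing}")
    df["control"] = df["control"].astype(bool)
    df["alive"] = df["alive"].astype(bool)
    return df


def write_pedigree(ped: Pedigree, path: str) -> None:
    ped.records.to_csv(path, index=False)


def read_pedigree(path: str) -> Pedigree:
    return Pedigree(pd.read_csv(path))


def write_truth(truth: dict, path: str) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(truth, indent=1, default=default))


def read_truth(path: str) -> dict:
    return json.loads(Path(path).read_text())


def write_crown_geojson(crowns: np.ndarray, cell_size: float,
                        origin: tuple[float, float], path: str) -> None:
    """Crown label raster to GeoJSON polygons (one feature per label)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    feats = []
    x0, y1 = origin
    for lbl in np.unique(crowns):
        if lbl == 0:
            continue
        rr, cc = np.nonzero(crowns == lbl)
        cells = [box(x0 + c * cell_size, y1 - (r + 1) * cell_size,
                     x0 + (c + 1) * cell_size, y1 - r * cell_size)
                 for r, c in zip(rr, cc)]
        geom = unary_union(cells)
        feats.append({"type": "Feature", "properties": {"label": int(lbl)},
                      "geometry": mapping(geom)})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def validate_inputs(tree_path: str | None = None,
                    pedigree_path: str | None = None,
                    chm_path: str | None = None) -> dict:
    """Schema and consistency checks on the input files.

    Returns {'ok': bool, 'errors': [...], 'warnings': [...]} with
    line-level messages: tree-table schema, duplicate grid cells,
    pedigree topological ordering, CHM nodata handling.
    """
    errors: list[str] = []
    warnings: list[str] = []
    trees = None
    if tree_path is not None:
        try:
            trees = read_trees(tree_path)
        except (OSError, ValueError) as e:
            errors.append(f"tree table: {e}")
        if trees is not None:
            dup = trees.duplicated(["row", "col"])
            for i in np.flatnonzero(dup.to_numpy()):
                errors.append(f"tree table row {i}: duplicate grid cell "
                              f"({trees.loc[i, 'row']}, {trees.loc[i, 'col']})")
            if trees["tree_id"].duplicated().any():
                errors.append("tree table: duplicate tree_id values")
    if pedigree_path is not None:
        try:
            ped = read_pedigree(pedigree_path)
        except (OSError, ValueError) as e:
            errors.append(f"pedigree: {e}")
        else:
            if trees is not None:
                known = set(ped.ids)
                absent = set(trees["tree_id"]) - known
                if absent:
                    errors.append(f"pedigree: {len(absent)} tree ids missing "
                                  f"(e.g. {sorted(absent)[:3]})")
    if chm_path is not None:
        from .raster import CHMRaster
        try:
            chm = CHMRaster.read(chm_path)
        except (OSError, ValueError) as e:
            errors.append(f"CHM: {e}")
        else:
            vals = chm.values[chm.mask()]
            if np.any(vals < 0):
                errors.append("CHM: negative heights outside nodata")
            if not chm.mask().any():
                errors.append("CHM: all cells nodata")
            if (~chm.mask()).any():
                warnings.append(f"CHM: {(~chm.mask()).sum()} nodata cells")
    return {"ok": not errors, "errors": errors, "warnings": warnings}
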