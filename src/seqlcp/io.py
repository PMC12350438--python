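"""Reading and writing pipeline artifacts (GeoJSON paths, CSV tables)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .lcp import LeastCostPath
from .raster import GridTransform

__all__ = [
    "write_paths_geojson",
    "read_paths_geojson",
    "write_rates",
    "write_populations",
    "write_assignments",
]


def write_paths_geojson(
    paths: list[LeastCostPath],
    transform: GridTransform,
    out_path: str | Path,
    path_population: dict[int, int] | None = None,
) -> None:
    """Write least-cost paths as a GeoJSON FeatureCollection of LineStrings.

    The cell sequence is stored alongside the projected geometry so that
    files round-trip losslessly without the raster.
    """
    features = []
    for i, p in enumerate(paths):
        props = {
            "year": p.year,
            "accumulated_cost": p.accumulated_cost,
            "source_row": p.source[0], "source_col": p.source[1],
            "target_row": p.target[0], "target_col": p.target[1],
            "cells": [list(c) for c in p.cells],
        }
        if path_population is not None:
            props["population_id"] = path_population.get(i)
        coords = [list(xy) for xy in p.line_coordinates(transform)]
        if len(coords) == 1:  # zero-length path (source == target)
            coords = coords * 2
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "features": features}
    Path(out_path).write_text(json.dumps(doc))


def read_paths_geojson(path: str | Path) -> list[LeastCostPath]:
    """Read paths written by :func:`write_paths_geojson`."""
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc["features"]:
        props = feat["properties"]
        cells = tuple(tuple(c) for c in props["cells"])
        out.append(LeastCostPath(
            source=(props["source_row"], props["source_col"]),
            target=(props["target_row"], props["target_col"]),
            year=int(props["year"]),
            accumulated_cost=float(props["accumulated_cost"]),
            cells=cells,
        ))
    return out


def write_rates(rates: pd.DataFrame, path: str | Path) -> None:
    rates.to_csv(path, index=False, na_rep="N/A")


def write_populations(populations: pd.DataFrame, path: str | Path) -> None:
    populations.to_csv(path, index_label="population_id")


def write_assignments(record_population: dict[str, int], path: str | Path) -> None:
    df = pd.DataFrame(
        {"id": list(record_population), "population_id": list(record_population.values())}
    )
    df.to_csv(path, index=False)
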