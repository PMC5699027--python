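"""Readers and writers for the package's on-disk formats.

Commune maps and antennas travel as GeoJSON (planar km coordinates in the
``coordinates`` arrays, which keeps the files self-describing without a
CRS); event logs, household tables, feature tables and predictions are
plain CSV/TSV with headers matching the in-memory column names.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from povgp.synthetic import AntennaSet, CommuneMap

__all__ = [
    "write_commune_map",
    "read_commune_map",
    "write_antennas",
    "read_antennas",
    "write_feature_table",
    "read_feature_table",
]


def write_commune_map(cmap: CommuneMap, path: str) -> None:
    features = []
    for i in range(cmap.n):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(cmap.polygons[i]),
                "properties": {
                    "commune_id": cmap.commune_ids[i],
                    "region_id": cmap.region_ids[i],
                    "is_urban": bool(cmap.is_urban[i]),
                    "centroid_x": float(cmap.centroids[i, 0]),
                    "centroid_y": float(cmap.centroids[i, 1]),
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "extent_km": cmap.extent_km,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_commune_map(path: str) -> CommuneMap:
    with open(path) as fh:
        doc = json.load(fh)
    ids, polys, cents, regions, urban = [], [], [], [], []
    for feat in doc["features"]:
        props = feat["properties"]
        ids.append(props["commune_id"])
        regions.append(props["region_id"])
        urban.append(bool(props["is_urban"]))
        polys.append(shape(feat["geometry"]))
        cents.append([props["centroid_x"], props["centroid_y"]])
    return CommuneMap(
        ids,
        polys,
        np.array(cents),
        regions,
        np.array(urban),
        float(doc.get("extent_km", 0.0)),
    )


def write_antennas(antennas: AntennaSet, path: str) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(antennas.positions[i, 0]), float(antennas.positions[i, 1])],
            },
            "properties": {
                "antenna_id": antennas.antenna_ids[i],
                "commune_id": antennas.commune_ids[i],
            },
        }
        for i in range(antennas.n)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_antennas(path: str) -> AntennaSet:
    with open(path) as fh:
        doc = json.load(fh)
    ids, pos, communes = [], [], []
    for feat in doc["features"]:
        ids.append(feat["properties"]["antenna_id"])
        communes.append(feat["properties"]["commune_id"])
        pos.append(feat["geometry"]["coordinates"])
    return AntennaSet(ids, np.array(pos, dtype=float), communes)


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=True)


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="commune_id")
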