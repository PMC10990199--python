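"""Text exports: summary TSV, network adjacency, GeoJSON map layers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .network import AreaPie, HaplotypeNetwork


def network_to_tsv(network: HaplotypeNetwork, path: str | Path) -> None:
    rows = [{"hap_a": e.hap_a, "hap_b": e.hap_b, "steps": e.steps,
             "alternative": e.alternative} for e in network.edges]
    pd.DataFrame(rows, columns=["hap_a", "hap_b", "steps", "alternative"]) \
        .to_csv(path, sep="\t", index=False)


def network_to_json(network: HaplotypeNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network.to_dict(), indent=1))


def pies_to_geojson(pies: list[AreaPie], path: str | Path) -> None:
    """Pie centroids with haplotype-composition payload as GeoJSON points."""
    features = []
    for p in pies:
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [p.centroid_lon, p.centroid_lat]},
            "properties": {
                "cell": list(p.cell), "n": p.n,
                "composition": p.composition,
                "colors": {h: list(c) for h, c in p.colors.items()},
            },
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def summary_to_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    """Species summary with missing statistics as empty fields, never 0."""
    summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
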