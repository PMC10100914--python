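"""Readers and writers for the tab-separated bundle and network formats.

A bundle directory holds three TSV tables: ``counts.tsv`` (samples as rows,
taxa as columns), ``taxonomy.tsv`` (taxa as rows with ``domain``, ``marker``
and optional ``lineage`` columns) and ``metadata.tsv`` (samples as rows with
site, depth interval and porewater chemistry).  Networks round-trip through
GraphML, a 3-column weighted edge list, or JSON, always with a JSON
provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountTable, InteractionNetwork, SampleMetadata

COUNTS_FILE = "counts.tsv"
TAXONOMY_FILE = "taxonomy.tsv"
METADATA_FILE = "metadata.tsv"

NETWORK_FORMATS = ("graphml", "edgelist", "json")


def read_bundle(directory: str | Path) -> tuple[CountTable, SampleMetadata]:
    """Load and cross-validate a counts/taxonomy/metadata bundle."""
    directory = Path(directory)
    counts_path = directory / COUNTS_FILE
    tax_path = directory / TAXONOMY_FILE
    meta_path = directory / METADATA_FILE
    for path in (counts_path, tax_path, meta_path):
        if not path.exists():
            raise FileNotFoundError(f"bundle file missing: {path}")

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(tax_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)

    if taxonomy.index.has_duplicates:
        raise ValueError("duplicate taxon ids in taxonomy")
    missing = [t for t in counts.columns if t not in taxonomy.index]
    if missing:
        raise ValueError(f"{len(missing)} taxa missing from taxonomy: {missing[:5]}")
    extra_samples = [s for s in counts.index if s not in meta.index]
    if extra_samples:
        raise ValueError(
            f"{len(extra_samples)} samples missing from metadata: {extra_samples[:5]}"
        )

    table = CountTable(
        counts=counts.astype(int),
        domain_of=taxonomy["domain"].to_dict(),
        marker_of=taxonomy["marker"].to_dict(),
        taxonomy=(taxonomy["lineage"].dropna().to_dict()
                  if "lineage" in taxonomy.columns else {}),
    )
    metadata = SampleMetadata(meta.loc[counts.index])
    return table, metadata


def write_bundle(
    counts: CountTable, meta: SampleMetadata, directory: str | Path
) -> Path:
    """Write a bundle in the layout :func:`read_bundle` consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts.counts.to_csv(directory / COUNTS_FILE, sep="\t")
    tax = pd.DataFrame({
        "domain": pd.Series(counts.domain_of),
        "marker": pd.Series(counts.marker_of),
        "lineage": pd.Series(counts.taxonomy, dtype=object),
    })
    tax.loc[counts.taxon_ids].rename_axis("taxon_id").to_csv(
        directory / TAXONOMY_FILE, sep="\t"
    )
    meta.table.rename_axis("sample_id").to_csv(directory / METADATA_FILE, sep="\t")
    return directory


def write_network(
    net: InteractionNetwork,
    path: str | Path,
    format: str = "graphml",
    sidecar: bool = True,
) -> Path:
    """Write a network as GraphML, TSV edge list or JSON (+ provenance)."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edgelist":
        frame = net.edges_frame()[["source", "target", "weight"]]
        frame.to_csv(path, sep="\t", index=False)
    else:
        payload = {
            "nodes": [{"id": v, **net.graph.nodes[v]} for v in net.graph.nodes],
            "edges": [
                {"source": u, "target": v, **{k: _jsonable(x) for k, x in d.items()}}
                for u, v, d in net.graph.edges(data=True)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    if sidecar:
        side = path.with_suffix(path.suffix + ".provenance.json")
        side.write_text(json.dumps(_jsonable(net.provenance), indent=1, default=str))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_network(path: str | Path, format: str = "graphml") -> InteractionNetwork:
    """Read a network written by :func:`write_network`."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    if format == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.relabel_nodes(graph, {v: str(v) for v in graph.nodes})
    elif format == "edgelist":
        frame = pd.read_csv(path, sep="\t")
        graph = nx.Graph()
        for _, row in frame.iterrows():
            graph.add_edge(str(row["source"]), str(row["target"]),
                           weight=float(row["weight"]))
    else:
        payload = json.loads(path.read_text())
        graph = nx.Graph()
        for node in payload["nodes"]:
            attrs = {k: v for k, v in node.items() if k != "id"}
            graph.add_node(node["id"], **attrs)
        for edge in payload["edges"]:
            attrs = {k: v for k, v in edge.items() if k not in ("source", "target")}
            graph.add_edge(edge["source"], edge["target"], **attrs)
    side = path.with_suffix(path.suffix + ".provenance.json")
    provenance = json.loads(side.read_text()) if side.exists() else {}
    return InteractionNetwork(graph, provenance)
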