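"""Core in-memory containers shared across the pipeline stages.

The pipeline operates on sample × taxon amplicon count tables annotated with
the domain (bacteria / archaea / fungus / other) and marker gene (16S or 18S)
of every taxon, per-sample environmental metadata from sediment depth
profiles, CLR-transformed abundance matrices, and signed weighted interaction
networks inferred from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "archaea", "fungus", "other")
MARKERS = ("16S", "18S")


class EmptyResultError(ValueError):
    """Raised when a filtering or subsetting step leaves nothing behind."""


@dataclass
class CountTable:
    """Sample × taxon integer count matrix with per-taxon annotations.

    ``counts`` has samples as rows and taxa as columns.  ``domain_of`` and
    ``marker_of`` must cover every taxon; ``taxonomy`` (ranked lineage
    strings) is optional per taxon.
    """

    counts: pd.DataFrame
    domain_of: dict[str, str]
    marker_of: dict[str, str]
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [t for t in self.counts.columns if t not in self.domain_of]
        if missing:
            raise ValueError(f"taxa without domain annotation: {missing[:5]}")
        missing = [t for t in self.counts.columns if t not in self.marker_of]
        if missing:
            raise ValueError(f"taxa without marker annotation: {missing[:5]}")
        bad = {d for d in self.domain_of.values()} - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domains: {sorted(bad)}")
        bad = {m for m in self.marker_of.values()} - set(MARKERS)
        if bad:
            raise ValueError(f"unknown markers: {sorted(bad)}")

    def subset_taxa(self, taxa: Iterable[str]) -> "CountTable":
        taxa = [t for t in self.taxon_ids if t in set(taxa)]
        return CountTable(
            counts=self.counts[taxa].copy(),
            domain_of={t: self.domain_of[t] for t in taxa},
            marker_of={t: self.marker_of[t] for t in taxa},
            taxonomy={t: self.taxonomy[t] for t in taxa if t in self.taxonomy},
        )

    def domains(self) -> pd.Series:
        return pd.Series({t: self.domain_of[t] for t in self.taxon_ids})


@dataclass
class SampleMetadata:
    """Per-sample site, depth interval (cm below sea floor) and porewater
    chemistry.  ``table`` is indexed by sample id with columns ``site``,
    ``depth_top_cm``, ``depth_bottom_cm``, ``seep_status`` and any of
    ``methane``, ``sulfate``, ``sulfide``, ``dic`` (missing values allowed).
    """

    table: pd.DataFrame

    REQUIRED = ("site", "depth_top_cm", "depth_bottom_cm")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        top = self.table["depth_top_cm"].to_numpy(float)
        bot = self.table["depth_bottom_cm"].to_numpy(float)
        if not (top < bot).all():
            raise ValueError("depth_top_cm must be < depth_bottom_cm")
        for col in ("methane", "sulfate", "sulfide", "dic"):
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if (vals < 0).any():
                    raise ValueError(f"negative {col} concentration")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class ClrMatrix:
    """Centered log-ratio abundances, transformed per marker block.

    Each marker's taxa are CLR-transformed jointly (16S and 18S libraries
    are sequenced separately, so their compositions are closed separately);
    within a block every sample row sums to zero.
    """

    values: pd.DataFrame
    pseudocount: float
    marker_blocks: dict[str, list[str]]
    domain_of: dict[str, str] = field(default_factory=dict)
    marker_of: dict[str, str] = field(default_factory=dict)
    taxonomy: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class InteractionNetwork:
    """Signed weighted undirected co-occurrence network over taxa.

    Nodes carry ``domain``, ``marker`` and optional ``taxonomy`` attributes;
    edges carry a signed real ``weight`` (pseudocorrelation scale) and, when
    inferred by stability selection, a ``stability`` frequency.  ``provenance``
    records the inference parameters and tuning outcome.
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-edges are not allowed")
        for u, v, d in self.graph.edges(data=True):
            w = d.get("weight", None)
            if w is None or not np.isfinite(w) or w == 0:
                raise ValueError(f"edge ({u}, {v}) has invalid weight {w!r}")

    def domain_of(self, node: str) -> str:
        return self.graph.nodes[node].get("domain", "other")

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v,
             "weight": d.get("weight", 1.0),
             "stability": d.get("stability", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "stability"])

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy(), dict(self.provenance))


def annotate_graph(
    graph: nx.Graph,
    domain_of: Mapping[str, str] | None = None,
    marker_of: Mapping[str, str] | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Attach domain/marker/taxonomy node attributes in place."""
    for node in graph.nodes:
        if domain_of is not None:
            graph.nodes[node]["domain"] = domain_of.get(node, "other")
        if marker_of is not None:
            graph.nodes[node]["marker"] = marker_of.get(node, "16S")
        if taxonomy is not None and node in taxonomy:
            graph.nodes[node]["taxonomy"] = taxonomy[node]
    return graph
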