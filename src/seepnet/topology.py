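"""Network topology: centralities, keystone taxa, core extraction,
between-domain comparisons.

Degree and betweenness are computed on the unweighted topology (no
weight-to-distance mapping is assumed for signed pseudocorrelations); edge
weights enter only through the mean absolute incident weight.  Keystone taxa
are nodes in the top 20th percentile of both degree and betweenness; the
core network keeps the top half of both, then prunes weakly connected taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import InteractionNetwork

METRICS = ("degree", "betweenness", "mean_abs_weight")


def compute_centralities(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node degree, betweenness and mean absolute edge weight.

    Betweenness is the unnormalized shortest-path betweenness (each unordered
    node pair contributes its fraction of shortest paths through the node).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    btw = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for v in g.nodes:
        weights = [abs(d.get("weight", 1.0)) for _, _, d in g.edges(v, data=True)]
        rows.append({
            "node": v,
            "degree": g.degree(v),
            "betweenness": btw[v],
            "mean_abs_weight": float(np.mean(weights)) if weights else 0.0,
            "domain": g.nodes[v].get("domain", "other"),
        })
    return pd.DataFrame(rows).set_index("node")


@dataclass
class KeystoneReport:
    """Nodes in the top (1 - percentile) of both degree and betweenness."""

    percentile: float
    degree_threshold: float
    betweenness_threshold: float
    keystone_ids: list[str]
    flags: pd.DataFrame  # per-node booleans: high_degree, high_betweenness, keystone


def keystone_nodes(table: pd.DataFrame, percentile: float = 0.80) -> KeystoneReport:
    """Extract keystone taxa by the double-percentile rule.

    Thresholds are the linear-interpolation quantiles of the empirical degree
    and betweenness distributions; keystones are the nodes at or above both.
    With all-tied metrics every node qualifies (degenerate but well defined).
    """
    if table.empty:
        raise ValueError("empty centrality table")
    deg_thr = float(np.quantile(table["degree"], percentile))
    btw_thr = float(np.quantile(table["betweenness"], percentile))
    hi_deg = table["degree"] >= deg_thr
    hi_btw = table["betweenness"] >= btw_thr
    flags = pd.DataFrame({
        "high_degree": hi_deg,
        "high_betweenness": hi_btw,
        "keystone": hi_deg & hi_btw,
    })
    return KeystoneReport(
        percentile=percentile,
        degree_threshold=deg_thr,
        betweenness_threshold=btw_thr,
        keystone_ids=list(table.index[flags["keystone"]]),
        flags=flags,
    )


def core_network(
    net: InteractionNetwork,
    percentile: float = 0.50,
    min_edges: int = 3,
) -> InteractionNetwork:
    """Extract the core: top-percentile nodes, then prune weak connectors.

    Order of operations: (1) keep nodes at or above the ``percentile``
    quantile of both degree and betweenness; (2) take the induced subgraph;
    (3) drop nodes with fewer than ``min_edges`` edges in that subgraph;
    (4) drop nodes the pruning left isolated.  The result is flagged empty
    in provenance when nothing survives.
    """
    table = compute_centralities(net)
    report = keystone_nodes(table, percentile)
    keep = set(report.keystone_ids)
    sub = net.graph.subgraph(keep).copy()
    sub.remove_nodes_from([v for v, d in sub.degree if d < min_edges])
    sub.remove_nodes_from([v for v, d in sub.degree if d == 0])
    provenance = {
        **net.provenance,
        "core_percentile": percentile,
        "core_min_edges": min_edges,
        "core_of_n_nodes": net.n_nodes,
        "empty": sub.number_of_nodes() == 0,
    }
    return InteractionNetwork(sub, provenance)


@dataclass
class DomainComparison:
    """Two-sample rank test between the metric values of two domains."""

    metric: str
    domain_a: str
    domain_b: str
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    top20_share_a: float
    top20_share_b: float
    test_name: str = "mann-whitney-u"


def compare_domain_metric(
    table: pd.DataFrame,
    metric: str,
    domain_a: str,
    domain_b: str,
    top_percentile: float = 0.80,
) -> DomainComparison:
    """Compare a centrality metric between two domains.

    Uses the two-sample Mann–Whitney U rank test (the groups are unpaired,
    so a signed-rank test is not applicable).  Also reports each domain's
    share of the pooled top-20% nodes of the metric.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    a = table.loc[table["domain"] == domain_a, metric]
    b = table.loc[table["domain"] == domain_b, metric]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both domains need at least 2 nodes")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    pooled = table.loc[table["domain"].isin([domain_a, domain_b]), metric]
    thr = float(np.quantile(pooled, top_percentile))
    top = table.loc[table["domain"].isin([domain_a, domain_b]) & (table[metric] >= thr)]
    n_top = len(top)
    return DomainComparison(
        metric=metric,
        domain_a=domain_a,
        domain_b=domain_b,
        statistic=float(stat),
        p_value=float(p),
        median_a=float(a.median()),
        median_b=float(b.median()),
        n_a=len(a),
        n_b=len(b),
        top20_share_a=float((top["domain"] == domain_a).sum() / n_top) if n_top else 0.0,
        top20_share_b=float((top["domain"] == domain_b).sum() / n_top) if n_top else 0.0,
    )
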