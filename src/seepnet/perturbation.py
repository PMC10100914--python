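"""Random-attack robustness, vulnerability and nodal efficiency.

Robustness of a network of N nodes under random attack is the area under the
relative largest-component curve: nodes are removed one at a time in a
uniformly random order, sigma(i) is the size of the largest connected
component after i removals divided by the original N (sigma(N) = 0), and

    R = (1/N) * sum_{i=1..N} sigma(i),        V = 0.5 - R.

A complete graph attains the minimum V = 1/(2N); an edgeless graph the
maximum V = 0.5 - (N-1)/N^2.  The curve is recomputed over many random
removal orders (bootstrap iterations) to give a V distribution per network.

Nodal information-transfer efficiency of node i is the mean inverse
shortest-path distance to every other node, with unreachable pairs
contributing zero (Latora–Marchiori efficiency).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .containers import InteractionNetwork


def _as_graph(net: InteractionNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


def sigma_curve(net: InteractionNetwork | nx.Graph, perm: np.ndarray) -> np.ndarray:
    """Relative largest-component sizes sigma(1..N) for one removal order.

    ``perm`` is a permutation of node positions (0-based, in the order the
    graph iterates its nodes); entry i of the result is sigma after the
    first i+1 nodes of ``perm`` have been removed.  Computed by adding nodes
    in reverse order with a union-find, which makes each curve O(N + E).
    """
    g = _as_graph(net)
    nodes = list(g.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in g.edges:
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])

    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    present = np.zeros(n, dtype=bool)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]  # path halving
            a = parent[a]
        return a

    sigma = np.zeros(n)
    largest = 0
    # add nodes in reverse removal order; after adding k nodes the graph
    # equals the state after n-k removals
    for k in range(1, n):
        v = perm[n - k]
        present[v] = True
        largest = max(largest, 1)
        for u in adj[v]:
            if present[u]:
                ra, rb = find(v), find(u)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                    if size[ra] > largest:
                        largest = size[ra]
        sigma[n - k - 1] = largest / n
    sigma[n - 1] = 0.0
    return sigma


@dataclass
class AttackResult:
    """Per-iteration robustness/vulnerability samples and their summary."""

    n_nodes: int
    n_iter: int
    R: np.ndarray
    V: np.ndarray
    mean_sigma_curve: np.ndarray
    seed: int

    @property
    def V_mean(self) -> float:
        return float(self.V.mean())

    @property
    def V_sd(self) -> float:
        return float(self.V.std(ddof=1)) if self.n_iter > 1 else 0.0


def attack_robustness(
    net: InteractionNetwork | nx.Graph,
    n_iter: int = 10_000,
    seed: int = 0,
) -> AttackResult:
    """Random-attack robustness with bootstrap iterations.

    Each iteration draws a fresh uniform removal permutation (every node
    removed exactly once) and records R and V = 0.5 - R; the mean sigma
    curve over iterations is kept for plotting.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network must have at least 2 nodes")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    R = np.empty(n_iter)
    curve_sum = np.zeros(n)
    for it in range(n_iter):
        sigma = sigma_curve(g, rng.permutation(n))
        R[it] = sigma.mean()
        curve_sum += sigma
    V = 0.5 - R
    return AttackResult(n, n_iter, R, V, curve_sum / n_iter, seed)


@dataclass
class EfficiencyResult:
    """Per-node Latora–Marchiori efficiencies and their network mean."""

    efficiency: dict[str, float]

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.efficiency.values()))

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def nodal_efficiency(net: InteractionNetwork | nx.Graph) -> EfficiencyResult:
    """E(i) = (1/(N-1)) * sum_{j != i} 1/d(i, j), unweighted distances."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network must have at least 2 nodes")
    eff = {}
    for v in g.nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        eff[v] = sum(1.0 / d for u, d in dist.items() if u != v) / (n - 1)
    return EfficiencyResult(eff)


@dataclass
class ComparisonResult:
    """Welch's t comparison of two samples with effect size.

    With tens of thousands of bootstrap iterations the p-value of any real
    difference is astronomically small; ``percent_change`` is the
    biologically interpretable effect size and should be read first.
    """

    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    percent_change: float  # (mean_a - mean_b) / mean_a * 100
    test_name: str = "welch-t"
    degenerate: bool = False


def _welch(a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    pct = (mean_a - mean_b) / mean_a * 100.0 if mean_a != 0 else float("nan")
    var_a = float(np.var(a, ddof=1)) if len(a) > 1 else 0.0
    var_b = float(np.var(b, ddof=1)) if len(b) > 1 else 0.0
    if var_a <= 1e-24 and var_b <= 1e-24:  # exact-V networks: zero variance
        p = 1.0 if np.isclose(mean_a, mean_b, atol=1e-12) else 0.0
        return ComparisonResult(float("inf") if p == 0 else 0.0, p,
                                mean_a, mean_b, pct, degenerate=True)
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(float(stat), float(p), mean_a, mean_b, pct)


def compare_vulnerability(a: AttackResult, b: AttackResult) -> ComparisonResult:
    """Welch's t-test on the per-iteration vulnerability samples."""
    if a.n_iter < 2 or b.n_iter < 2:
        raise ValueError("need at least 2 iterations per network")
    return _welch(a.V, b.V)


def compare_efficiency(a: EfficiencyResult, b: EfficiencyResult) -> ComparisonResult:
    """Welch's t-test on the per-node efficiency distributions."""
    if len(a.efficiency) < 3 or len(b.efficiency) < 3:
        raise ValueError("need at least 3 nodes per network")
    return _welch(a.values, b.values)
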