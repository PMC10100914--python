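"""Synthetic community generator.

Produces every input the analysis stages need without external data: fixture
graphs with known topology, zero-inflated compositional count tables drawn
from a known sparse precision matrix (logistic-normal-multinomial model),
sediment depth-profile metadata with a methane peak inside a sulfate–methane
transition zone (SMTZ), and planted taxon–response signals for validating
balance selection.

The generator reproduces the two data properties the network-inference
method is designed around — compositionality (counts are a multinomial draw
from a softmax-mapped latent Gaussian) and zero inflation (independent
sampling zeros added on top) — while keeping the dependence structure fully
known, so edge-recovery and signal-recovery rates can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountTable, InteractionNetwork, SampleMetadata, annotate_graph

FIXTURE_KINDS = ("complete", "edgeless", "star", "path", "erdos_renyi", "barbell")

#: depth of sequencing varies between libraries; log-normal with CV 0.3
DEPTH_CV = 0.3


@dataclass
class TrueModel:
    """Ground-truth sparse Gaussian dependence structure for a community.

    ``precision`` is symmetric positive definite; its off-diagonal support is
    the set of true conditional-dependence edges the inference stage should
    recover.  Every taxon has exactly one domain and one marker (fungi carry
    the 18S marker, prokaryotes 16S).
    """

    precision: np.ndarray
    taxon_ids: list[str]
    domain_of: dict[str, str]
    marker_of: dict[str, str]
    seed: int

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def true_edges(self) -> set[frozenset]:
        edges = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.precision[i, j] != 0.0:
                    edges.add(frozenset((self.taxon_ids[i], self.taxon_ids[j])))
        return edges

    def validate(self) -> None:
        if not np.allclose(self.precision, self.precision.T):
            raise ValueError("precision matrix not symmetric")
        np.linalg.cholesky(self.precision)  # raises if not PD

    def to_dict(self) -> dict:
        return {
            "taxon_ids": self.taxon_ids,
            "edges": sorted(sorted(e) for e in self.true_edges),
            "domain_of": self.domain_of,
            "marker_of": self.marker_of,
            "seed": self.seed,
        }


@dataclass
class PlantedSignal:
    """Truth record for a planted taxon–response association.

    The numerator group is elevated in "high" samples and the denominator
    group in "low" samples, by a factor exp(effect_size) on the counts.
    """

    numerator_taxa: set[str]
    denominator_taxa: set[str]
    effect_size: float
    response: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.numerator_taxa or not self.denominator_taxa:
            raise ValueError("numerator and denominator must be non-empty")
        if self.numerator_taxa & self.denominator_taxa:
            raise ValueError("numerator and denominator overlap")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _taxon_ids(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


def make_fixture_graph(
    kind: str,
    n: int,
    p_edge: float | None = None,
    seed: int = 0,
) -> InteractionNetwork:
    """Build a named oracle topology as an InteractionNetwork.

    All edges get weight +1.  Node ids are "t1".."tn"; for ``star`` the hub
    is "t1", for ``path`` nodes are chained in id order, for ``barbell``
    (n even, >= 6) two cliques of n/2 are joined by a single bridge edge.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if n < 2:
        raise ValueError("n must be >= 2")
    ids = _taxon_ids(n)
    if kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "edgeless":
        g = nx.empty_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)  # node 0 is the hub
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "erdos_renyi":
        if p_edge is None or not 0 <= p_edge <= 1:
            raise ValueError("erdos_renyi requires p_edge in [0, 1]")
        g = nx.gnp_random_graph(n, p_edge, seed=seed)
    elif kind == "barbell":
        if n < 6 or n % 2:
            raise ValueError("barbell requires even n >= 6")
        g = nx.barbell_graph(n // 2, 0)
    g = nx.relabel_nodes(g, dict(zip(range(n), ids)))
    nx.set_edge_attributes(g, 1.0, "weight")
    annotate_graph(g, domain_of={t: "bacteria" for t in ids},
                   marker_of={t: "16S" for t in ids})
    return InteractionNetwork(g, provenance={"fixture": kind, "n": n, "seed": seed})


DEFAULT_DOMAIN_FRACTIONS = {"bacteria": 0.6, "archaea": 0.2, "fungus": 0.2}


def make_true_model(
    p: int,
    edge_density: float,
    domain_fractions: dict[str, float] | None = None,
    condition_floor: float = 0.1,
    edge_magnitude: tuple[float, float] = (0.25, 0.5),
    seed: int = 0,
) -> TrueModel:
    """Draw a sparse symmetric positive-definite precision matrix.

    Off-diagonal support is sampled uniformly at ``edge_density``; entry
    magnitudes are uniform in ``edge_magnitude`` with random signs.  The
    diagonal starts at 1 and is inflated so the minimum eigenvalue is at
    least ``condition_floor``.  Domains are assigned by ``domain_fractions``
    (largest-remainder rounding); fungi carry the 18S marker.
    """
    if p < 4:
        raise ValueError("p must be >= 4")
    if not 0 <= edge_density < 0.5:
        raise ValueError("edge_density must be in [0, 0.5)")
    fractions = dict(domain_fractions or DEFAULT_DOMAIN_FRACTIONS)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("domain_fractions must sum to 1")

    rng = np.random.default_rng(seed)
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < edge_density
    mags = rng.uniform(*edge_magnitude, size=len(iu[0]))
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    vals = np.where(present, mags * signs, 0.0)
    omega[iu] = vals
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0)
    min_eig = np.linalg.eigvalsh(omega)[0]
    if min_eig < condition_floor:
        omega[np.diag_indices(p)] += condition_floor - min_eig
    # additive inflation shifts every eigenvalue; verify anyway
    if np.linalg.eigvalsh(omega)[0] < condition_floor - 1e-10:
        raise RuntimeError("failed to reach positive definiteness")

    ids = _taxon_ids(p)
    # largest-remainder apportionment of taxa to domains, in fixed domain order
    order = list(fractions)
    raw = np.array([fractions[d] * p for d in order])
    counts = np.floor(raw).astype(int)
    rem = p - counts.sum()
    for i in np.argsort(-(raw - np.floor(raw)))[:rem]:
        counts[i] += 1
    domain_of: dict[str, str] = {}
    k = 0
    for d, c in zip(order, counts):
        for _ in range(c):
            domain_of[ids[k]] = d
            k += 1
    marker_of = {t: ("18S" if domain_of[t] == "fungus" else "16S") for t in ids}
    model = TrueModel(omega, ids, domain_of, marker_of, seed)
    model.validate()
    return model


def simulate_counts(
    truth: TrueModel,
    n_samples: int,
    depth_mean: int = 20_000,
    zero_inflation: float = 0.0,
    seed: int = 0,
) -> CountTable:
    """Draw a zero-inflated compositional count table from the true model.

    Latent abundances are multivariate normal with covariance equal to the
    inverse precision; a per-sample softmax maps them to a composition; reads
    are multinomial at a log-normal library depth (CV 0.3 around
    ``depth_mean``); finally each count is independently zeroed with
    probability ``zero_inflation`` (sampling zeros, not structural).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0 <= zero_inflation < 1:
        raise ValueError("zero_inflation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = truth.p
    cov = np.linalg.inv(truth.precision)
    z = rng.multivariate_normal(np.zeros(p), cov, size=n_samples, method="cholesky")
    z -= z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)
    sigma2 = np.log1p(DEPTH_CV**2)
    depths = rng.lognormal(np.log(depth_mean) - sigma2 / 2, np.sqrt(sigma2), n_samples)
    depths = np.maximum(depths.round().astype(int), 1)
    counts = np.vstack([rng.multinomial(d, c) for d, c in zip(depths, comp)])
    if zero_inflation > 0:
        counts[rng.random(counts.shape) < zero_inflation] = 0
    frame = pd.DataFrame(
        counts,
        index=[f"s{i + 1}" for i in range(n_samples)],
        columns=truth.taxon_ids,
    )
    return CountTable(frame, dict(truth.domain_of), dict(truth.marker_of))


def simulate_metadata(
    sites: list[str],
    depth_slices_cm: list[tuple[float, float]],
    smtz_interval_cm: tuple[float, float] = (10.0, 13.0),
    methane_peak: float = 5.0,
    control_sites: tuple[str, ...] = (),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SampleMetadata:
    """Generate depth-profile metadata with an SMTZ methane peak.

    The noise-free methane curve is a Gaussian bump centred in the SMTZ
    interval (so its argmax lies inside it); sulfate decreases monotonically
    with depth; sulfide rises toward the SMTZ.  One record per (site, slice);
    sample ids are "<site>_<top>-<bottom>cm".
    """
    if not sites or not depth_slices_cm:
        raise ValueError("sites and depth_slices_cm must be non-empty")
    lo, hi = smtz_interval_cm
    depths = [d for s in depth_slices_cm for d in s]
    if lo < min(depths) or hi > max(depths):
        raise ValueError("smtz_interval_cm outside covered depth range")
    rng = np.random.default_rng(seed)
    centre = (lo + hi) / 2
    width = max((hi - lo) / 2, 1.0)
    max_depth = max(depths)
    rows = []
    for site in sites:
        control = site in control_sites
        for top, bottom in depth_slices_cm:
            mid = (top + bottom) / 2
            methane = 0.05 * methane_peak + methane_peak * np.exp(
                -((mid - centre) ** 2) / (2 * width**2)
            )
            if control:
                methane *= 0.05
            sulfate = 28.0 * (1.0 - 0.8 * mid / max_depth)
            sulfide = 0.2 + 2.0 * np.exp(-((mid - centre) ** 2) / (2 * (2 * width) ** 2))
            dic = 5.0 + 0.1 * mid
            noise = rng.lognormal(0.0, noise_sd, size=4)
            rows.append({
                "sample_id": f"{site}_{top:g}-{bottom:g}cm",
                "site": site,
                "depth_top_cm": float(top),
                "depth_bottom_cm": float(bottom),
                "methane": methane * noise[0],
                "sulfate": sulfate * noise[1],
                "sulfide": sulfide * noise[2],
                "dic": dic * noise[3],
                "seep_status": "control" if control else "seep",
            })
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(table)


def methane_curve(
    depth_cm: np.ndarray,
    smtz_interval_cm: tuple[float, float] = (10.0, 13.0),
    methane_peak: float = 5.0,
) -> np.ndarray:
    """Noise-free methane profile used by :func:`simulate_metadata`."""
    lo, hi = smtz_interval_cm
    centre = (lo + hi) / 2
    width = max((hi - lo) / 2, 1.0)
    depth_cm = np.asarray(depth_cm, dtype=float)
    return 0.05 * methane_peak + methane_peak * np.exp(
        -((depth_cm - centre) ** 2) / (2 * width**2)
    )


def plant_balance_signal(
    counts: CountTable,
    numerator_taxa: set[str] | list[str],
    denominator_taxa: set[str] | list[str],
    effect_size: float,
    seed: int = 0,
) -> tuple[CountTable, PlantedSignal]:
    """Plant a two-group log-ratio shift between balanced binary classes.

    Samples are split half/half into "high" and "low" at random; numerator
    counts are multiplied by exp(effect_size) in high samples and denominator
    counts by the same factor in low samples, then re-rounded to integers.
    """
    num = set(numerator_taxa)
    den = set(denominator_taxa)
    if num & den:
        raise ValueError("numerator and denominator taxa overlap")
    missing = (num | den) - set(counts.taxon_ids)
    if missing:
        raise ValueError(f"taxa not in table: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = counts.n_samples
    order = rng.permutation(n)
    labels = np.array(["low"] * n, dtype=object)
    labels[order[: n // 2]] = "high"
    response = pd.Series(labels, index=counts.sample_ids, name="response")

    mat = counts.counts.copy().astype(float)
    factor = float(np.exp(effect_size))
    high = response == "high"
    mat.loc[high, sorted(num)] *= factor
    mat.loc[~high, sorted(den)] *= factor
    mat = mat.round().astype(int)
    planted = CountTable(mat, dict(counts.domain_of), dict(counts.marker_of),
                         dict(counts.taxonomy))
    signal = PlantedSignal(num, den, float(effect_size), response)
    return planted, signal
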