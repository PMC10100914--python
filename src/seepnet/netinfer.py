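"""Sparse cross-domain network inference from CLR abundances.

The estimator is penalized neighborhood selection (a lasso regression of each
taxon on all others), tuned by StARS stability selection: the lasso path is
refit on many random subsamples and the penalty is chosen as the smallest
lambda (densest graph) whose edge-set instability, monotonized from the
sparse end of the path, stays below a threshold.  An optional low-rank
latent-variable adjustment removes the top principal components of the CLR
matrix before fitting (sequencing-depth and environmental gradients induce
dense apparent covariance); the number of removed components is chosen by
extended BIC over candidate ranks.

Edge weights are the refit lasso coefficients after symmetrization
(pseudocorrelations): sign gives the direction of association, magnitude its
strength relative to other edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .containers import ClrMatrix, InteractionNetwork, annotate_graph


@dataclass
class NetInferParams:
    """Tuning parameters for stability-selected neighborhood inference.

    Defaults follow the standard cross-domain workflow: a 20-point lambda
    path down to 0.005 of lambda_max, 20 stability subsamples, instability
    threshold 0.05.  ``latent_rank_max = 0`` disables the latent-variable
    adjustment; ``ebic_gamma`` weights the extended-BIC sparsity penalty used
    to choose the rank.
    """

    nlambda: int = 20
    lambda_min_ratio: float = 0.005
    stars_threshold: float = 0.05
    n_reps: int = 20
    subsample_size: int | None = None  # None -> floor(10*sqrt(n)), capped at 0.8n
    latent_rank_max: int = 0
    ebic_gamma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if not 0 < self.stars_threshold < 1:
            raise ValueError("stars_threshold must be in (0, 1)")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")

    def resolve_subsample_size(self, n: int) -> int:
        if self.subsample_size is not None:
            b = int(self.subsample_size)
            if b > n:
                raise ValueError(f"subsample size {b} exceeds n = {n}")
            return b
        b = math.floor(10 * math.sqrt(n))
        if b >= n:  # small-n regime: fall back to the 80% convention
            b = math.floor(0.8 * n)
        return max(b, 2)


@dataclass
class StarsResult:
    """Lambda path, per-edge selection frequencies and the StARS choice."""

    lambdas: np.ndarray  # descending
    frequencies: np.ndarray  # (nlambda, p, p), symmetric, diag 0
    instability: np.ndarray  # raw D(lambda)
    monotonized: np.ndarray  # sup-monotonized from the sparse end
    selected_index: int
    taxon_ids: list[str] = field(default_factory=list)

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_index])

    @property
    def selected_frequencies(self) -> np.ndarray:
        return self.frequencies[self.selected_index]


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd < 1e-12):
        raise ValueError("degenerate (constant) columns in input matrix")
    return (x - mu) / sd


def _lambda_path(xs: np.ndarray, params: NetInferParams) -> np.ndarray:
    """Log-spaced path from the maximum absolute empirical correlation."""
    n = xs.shape[0]
    corr = xs.T @ xs / n
    np.fill_diagonal(corr, 0.0)
    lam_max = float(np.abs(corr).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * params.lambda_min_ratio, params.nlambda)


def _neighborhood_coefs(xs: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Lasso coefficient cube: coefs[j, k, l] for the regression of column j
    on the other columns along the (descending) lambda path."""
    n, p = xs.shape
    L = len(lambdas)
    coefs = np.zeros((p, p, L))
    idx = np.arange(p)
    with warnings.catch_warnings():
        # near-duplicate columns stall coordinate descent at the dense end of
        # the path; those lambdas are never selected, so cap the iterations
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(p):
            others = idx[idx != j]
            _, w, _ = lasso_path(xs[:, others], xs[:, j], alphas=lambdas,
                                 max_iter=2000, tol=1e-3)
            coefs[j, others, :] = w
    return coefs


def _adjacency(coefs: np.ndarray) -> np.ndarray:
    """Union ("or") symmetrization of nonzero neighborhood coefficients."""
    nz = coefs != 0.0
    return nz | nz.transpose(1, 0, 2)


def instability_statistic(frequencies: np.ndarray) -> float:
    """StARS total instability: mean over taxon pairs of 2 f (1 - f)."""
    p = frequencies.shape[0]
    iu = np.triu_indices(p, k=1)
    f = frequencies[iu]
    return float(np.mean(2.0 * f * (1.0 - f)))


def stars_path(clr: ClrMatrix | pd.DataFrame, params: NetInferParams) -> StarsResult:
    """Run stability selection over the lambda path.

    For each of ``n_reps`` seeded subsamples (without replacement, size
    floor(10*sqrt(n)) by default) the neighborhood-selection path is refit
    and each pair's selection frequency is recorded per lambda.  The selected
    lambda is the smallest one whose monotonized instability is at or below
    ``stars_threshold``.
    """
    values = clr.values if isinstance(clr, ClrMatrix) else clr
    taxa = list(values.columns)
    x = values.to_numpy(dtype=float)
    n, p = x.shape
    if p < 3:
        raise ValueError("need at least 3 taxa")
    xs = _standardize(x)
    lambdas = _lambda_path(xs, params)
    b = params.resolve_subsample_size(n)

    counts = np.zeros((params.nlambda, p, p))
    for rep in range(params.n_reps):
        rng = np.random.default_rng(params.seed + rep)
        idx = rng.choice(n, size=b, replace=False)
        sub = _standardize(x[idx])
        adj = _adjacency(_neighborhood_coefs(sub, lambdas))
        counts += adj.transpose(2, 0, 1)
    freq = counts / params.n_reps

    instab = np.array([instability_statistic(freq[l]) for l in range(params.nlambda)])
    monotone = np.maximum.accumulate(instab)  # lambdas descend: sparse -> dense
    ok = monotone <= params.stars_threshold
    selected = int(np.nonzero(ok)[0][-1]) if ok.any() else 0
    return StarsResult(lambdas, freq, instab, monotone, selected, taxa)


def _ebic_of_model(
    xc: np.ndarray, coefs: np.ndarray, gamma: float, latent_df: int = 0
) -> float:
    """Extended-BIC score of one selected neighborhood model.

    ``xc`` is the (possibly latent-adjusted) column-centered matrix and
    ``coefs`` the (p, p) coefficient matrix fit on its standardized columns.
    Residuals are rescaled to the original column variances so that scores
    for different latent adjustments of the same data are comparable (the
    variance a removed component explains counts as explained by the latent
    part, which is charged ``latent_df`` * log n).  The graph pays the usual
    extended-BIC price |E| * (log n + 4 * gamma * log p).
    """
    n, p = xc.shape
    sd = xc.std(axis=0)
    xs = _standardize(xc)
    idx = np.arange(p)
    loglik_term = 0.0
    for j in range(p):
        others = idx[idx != j]
        resid = xs[:, j] - xs[:, others] @ coefs[j, others]
        rss = float(resid @ resid) * sd[j] ** 2
        loglik_term += n * math.log(max(rss, 1e-12) / n)
    nz = coefs != 0.0
    n_edges = int((nz | nz.T)[np.triu_indices(p, k=1)].sum())
    return (loglik_term
            + n_edges * (math.log(n) + 4.0 * gamma * math.log(p))
            + latent_df * math.log(n))


def latent_rank_select(
    clr: ClrMatrix | pd.DataFrame, params: NetInferParams
) -> tuple[int, pd.DataFrame, dict[int, float]]:
    """Choose how many latent components to remove before inference.

    For each candidate rank r in 0..latent_rank_max the top-r principal
    components are subtracted from the column-centered CLR matrix, a
    stability-selected network is created on the adjusted matrix, and that
    selected model is scored by extended BIC (iterative network creation
    and assessment); the r with the best score wins.  Rank 0 returns the
    input unchanged.
    """
    values = clr.values if isinstance(clr, ClrMatrix) else clr
    if params.latent_rank_max == 0:
        return 0, values, {0: float("nan")}
    n, p = values.shape
    if params.latent_rank_max >= min(n, p):
        raise ValueError("latent_rank_max must be < min(n_samples, n_taxa)")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores: dict[int, float] = {}
    adjusted: dict[int, np.ndarray] = {}
    for r in range(params.latent_rank_max + 1):
        xr = xc - (u[:, :r] * s[:r]) @ vt[:r] if r else xc
        adjusted[r] = xr
        frame = pd.DataFrame(xr, index=values.index, columns=values.columns)
        stars = stars_path(frame, params)
        coefs = _neighborhood_coefs(_standardize(xr), stars.lambdas)
        # a rank-r n x p component has r*(n + p - r) free parameters
        latent_df = r * (n + p - r)
        scores[r] = _ebic_of_model(
            xc if r == 0 else xr, coefs[:, :, stars.selected_index],
            params.ebic_gamma, latent_df,
        )
    best = min(scores, key=lambda r: scores[r])
    out = pd.DataFrame(adjusted[best], index=values.index, columns=values.columns)
    return best, out, scores


def infer_network(clr: ClrMatrix, params: NetInferParams | None = None) -> InteractionNetwork:
    """Infer a signed weighted interaction network from CLR abundances.

    Pipeline: latent-rank adjustment (if enabled) -> StARS lambda selection
    -> refit of the neighborhood lasso on the full adjusted data at the
    selected lambda.  The two directed coefficients of each pair are
    symmetrized by keeping the one of larger magnitude (ties broken toward
    the lexicographically smaller source taxon); its sign is the edge sign.
    Isolated nodes are dropped from the final network.
    """
    params = params or NetInferParams()
    rank, adjusted, ebic_scores = latent_rank_select(clr, params)
    stars = stars_path(adjusted, params)

    x = adjusted.to_numpy(dtype=float)
    xs = _standardize(x)
    coefs = _neighborhood_coefs(xs, stars.lambdas)[:, :, stars.selected_index]

    taxa = list(adjusted.columns)
    p = len(taxa)
    graph = nx.Graph()
    graph.add_nodes_from(taxa)
    freq = stars.selected_frequencies
    for i in range(p):
        for j in range(i + 1, p):
            a, b = coefs[i, j], coefs[j, i]
            if abs(a) > abs(b):
                w = a
            elif abs(b) > abs(a):
                w = b
            else:  # tie: take the coefficient whose source node sorts first
                w = a if taxa[i] <= taxa[j] else b
            if w != 0.0:
                graph.add_edge(taxa[i], taxa[j], weight=float(w),
                               stability=float(freq[i, j]))
    annotate_graph(graph, clr.domain_of, clr.marker_of, clr.taxonomy)
    graph.remove_nodes_from([v for v, d in graph.degree if d == 0])

    provenance = {
        "params": asdict(params),
        "selected_lambda": stars.selected_lambda,
        "selected_index": stars.selected_index,
        "latent_rank": rank,
        "ebic_scores": {str(k): v for k, v in ebic_scores.items()},
        "n_input_taxa": p,
        "n_connected": graph.number_of_nodes(),
        "empty": graph.number_of_edges() == 0,
    }
    net = InteractionNetwork(graph, provenance)
    net.validate()
    return net
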