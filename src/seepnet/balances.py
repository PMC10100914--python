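"""Greedy balance selection for compositional taxon–response screening.

A balance between two disjoint taxon groups (sizes p and q) is the normalized
log-contrast

    B(x) = sqrt(pq / (p + q)) * [ mean_{j in num} ln x_j - mean_{k in den} ln x_k ]

computed on pseudocount-replaced counts.  The selection procedure mirrors the
forward search of compositional balance regression: on each training fold the
best single pair is found by exhaustive AUC scoring, then taxa are added
greedily to either side while the training AUC of the balance improves.
Repeating over many cross-validation splits yields, for every taxon, the
fraction of validation steps in which it landed on the side elevated in
"high" samples — the appearance frequency used to call signature taxa
(e.g. the high-methane-signature fungi screen at a 30% threshold).

The balance value itself is the classifier (a threshold-free ranking score),
so no inner model fit is needed; training AUC is the selection criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .containers import CountTable


@dataclass
class BalanceModel:
    """Disjoint numerator / denominator taxon groups of a balance."""

    numerator_taxa: list[str]
    denominator_taxa: list[str]

    def __post_init__(self) -> None:
        num, den = set(self.numerator_taxa), set(self.denominator_taxa)
        if not num or not den:
            raise ValueError("both groups must be non-empty")
        if num & den:
            raise ValueError("numerator and denominator overlap")

    @property
    def coefficient(self) -> float:
        p, q = len(self.numerator_taxa), len(self.denominator_taxa)
        return float(np.sqrt(p * q / (p + q)))


def balance_value(
    counts: CountTable | pd.DataFrame,
    model: BalanceModel,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample balance values on pseudocount-replaced counts."""
    frame = counts.counts if isinstance(counts, CountTable) else counts
    missing = (set(model.numerator_taxa) | set(model.denominator_taxa)) - set(frame.columns)
    if missing:
        raise ValueError(f"taxa not in table: {sorted(missing)}")
    logx = np.log(frame.to_numpy(dtype=float) + pseudocount)
    cols = {t: i for i, t in enumerate(frame.columns)}
    num = logx[:, [cols[t] for t in model.numerator_taxa]].mean(axis=1)
    den = logx[:, [cols[t] for t in model.denominator_taxa]].mean(axis=1)
    return pd.Series(model.coefficient * (num - den), index=frame.index, name="balance")


def _auc_columns(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Mann–Whitney AUC of each score column for the positive mask."""
    if scores.ndim == 1:
        scores = scores[:, None]
    n1 = int(positive.sum())
    n0 = len(positive) - n1
    ranks = rankdata(scores, axis=0)
    return (ranks[positive].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


def _greedy_fit(
    logx: np.ndarray,
    positive: np.ndarray,
    max_size: int,
    min_improvement: float,
) -> list[tuple[list[int], list[int], float]]:
    """Forward balance search on one training split.

    Returns the nested model sequence: one (numerator indices, denominator
    indices, oriented training AUC) triple per balance size from 2 up to
    ``max_size`` (stopping early when no candidate raises the training AUC
    by ``min_improvement``).  The final size is chosen later by held-out
    AUC, not here.
    """
    n, p = logx.shape
    pairs = list(itertools.combinations(range(p), 2))
    diffs = logx[:, [a for a, _ in pairs]] - logx[:, [b for _, b in pairs]]
    auc = _auc_columns(diffs, positive)
    oriented = np.maximum(auc, 1.0 - auc)
    best = int(np.argmax(oriented))
    j, k = pairs[best]
    if auc[best] >= 0.5:
        num, den = [j], [k]
    else:
        num, den = [k], [j]
    current = float(oriented[best])
    sequence = [(list(num), list(den), current)]

    while len(num) + len(den) < max_size:
        in_model = set(num) | set(den)
        cands = [t for t in range(p) if t not in in_model]
        if not cands:
            break
        m_num = logx[:, num].mean(axis=1)
        m_den = logx[:, den].mean(axis=1)
        xc = logx[:, cands]
        # candidate balances: taxon added to the numerator or denominator side
        add_num = (m_num[:, None] * len(num) + xc) / (len(num) + 1) - m_den[:, None]
        add_den = m_num[:, None] - (m_den[:, None] * len(den) + xc) / (len(den) + 1)
        auc_n = _auc_columns(add_num, positive)
        auc_d = _auc_columns(add_den, positive)
        ori_n = np.maximum(auc_n, 1.0 - auc_n)
        ori_d = np.maximum(auc_d, 1.0 - auc_d)
        bn, bd = int(np.argmax(ori_n)), int(np.argmax(ori_d))
        if ori_n[bn] >= ori_d[bd]:
            best_auc, side, taxon = float(ori_n[bn]), "num", cands[bn]
        else:
            best_auc, side, taxon = float(ori_d[bd]), "den", cands[bd]
        if best_auc < current + min_improvement:
            break
        (num if side == "num" else den).append(taxon)
        current = best_auc
        sequence.append((list(num), list(den), current))
    return sequence


@dataclass
class BalanceCVReport:
    """Appearance frequencies over all repeat × fold validation steps.

    ``frequencies`` counts a taxon only when it lands on the side elevated
    in "high" samples (the signature screen's statistic); ``appearance``
    counts it whichever side of the balance it joins (what a per-taxon
    appearance bar chart shows).
    """

    n_repeats: int
    n_folds: int
    frequencies: pd.Series  # per taxon: fraction of steps on the high side
    appearance: pd.Series  # per taxon: fraction of steps in the balance at all
    mean_cv_auc: float
    n_steps: int
    params: dict = field(default_factory=dict)


def greedy_balance_cv(
    counts: CountTable | pd.DataFrame,
    response: pd.Series,
    n_folds: int = 5,
    n_repeats: int = 100,
    max_size: int = 8,
    pseudocount: float = 1.0,
    min_improvement: float = 1e-4,
    seed: int = 0,
) -> BalanceCVReport:
    """Repeated cross-validated greedy balance selection.

    For every repeat a stratified ``n_folds`` split is drawn; on each
    training portion the forward search grows a nested balance sequence
    (sizes 2..``max_size``) and each size is scored by AUC on the held-out
    fold.  The working balance size is then chosen globally as the size
    with the best mean held-out AUC (overfitting control: decoy additions
    help the training AUC but not the held-out one), and appearance
    frequencies count, for every validation step, the taxa of that step's
    balance at the chosen size — separately for the side elevated in "high"
    training samples and for either side.
    """
    frame = counts.counts if isinstance(counts, CountTable) else counts
    response = response.reindex(frame.index)
    y = (response == "high").to_numpy()
    classes, class_counts = np.unique(response.to_numpy(), return_counts=True)
    if len(classes) < 2:
        raise ValueError("response must contain both classes")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > class_counts.min():
        raise ValueError("n_folds exceeds the size of the smaller class")

    logx = np.log(frame.to_numpy(dtype=float) + pseudocount)
    taxa = list(frame.columns)
    n_sizes = max_size - 1  # sizes 2..max_size
    steps: list[list[tuple[list[int], list[int], bool]]] = []
    auc_by_size: list[list[float]] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(logx, y):
            sequence = _greedy_fit(
                logx[train_idx], y[train_idx], max_size, min_improvement
            )
            models = []
            aucs = []
            for s in range(n_sizes):
                # greedy may stop early; reuse its largest model for bigger sizes
                num, den, _ = sequence[min(s, len(sequence) - 1)]
                b_train = logx[train_idx][:, num].mean(axis=1) \
                    - logx[train_idx][:, den].mean(axis=1)
                num_is_high = (b_train[y[train_idx]].mean()
                               - b_train[~y[train_idx]].mean()) >= 0
                b_test = logx[test_idx][:, num].mean(axis=1) \
                    - logx[test_idx][:, den].mean(axis=1)
                auc = float(_auc_columns(b_test, y[test_idx])[0])
                models.append((num, den, num_is_high))
                aucs.append(auc if num_is_high else 1.0 - auc)
            steps.append(models)
            auc_by_size.append(aucs)

    mean_auc_by_size = np.asarray(auc_by_size).mean(axis=0)
    best_size_idx = int(np.argmax(mean_auc_by_size))  # ties -> smaller size
    high_side_counts = np.zeros(len(taxa))
    any_side_counts = np.zeros(len(taxa))
    for models in steps:
        num, den, num_is_high = models[best_size_idx]
        high_side_counts[num if num_is_high else den] += 1
        any_side_counts[num] += 1
        any_side_counts[den] += 1
    n_steps = len(steps)

    return BalanceCVReport(
        n_repeats=n_repeats,
        n_folds=n_folds,
        frequencies=pd.Series(high_side_counts / n_steps, index=taxa, name="frequency"),
        appearance=pd.Series(any_side_counts / n_steps, index=taxa, name="appearance"),
        mean_cv_auc=float(mean_auc_by_size[best_size_idx]),
        n_steps=n_steps,
        params={
            "max_size": max_size,
            "selected_size": best_size_idx + 2,
            "mean_auc_by_size": mean_auc_by_size.tolist(),
            "pseudocount": pseudocount,
            "min_improvement": min_improvement,
            "seed": seed,
        },
    )


def signature_taxa(
    report: BalanceCVReport, threshold: float = 0.30, side: str = "high"
) -> set[str]:
    """Taxa whose appearance frequency reaches ``threshold``.

    ``side="high"`` (default) screens on the high-favoring-side frequency —
    the signature rule; ``side="any"`` screens on appearance in the balance
    regardless of side.
    """
    if report.n_steps == 0:
        raise ValueError("empty report")
    if side == "high":
        freq = report.frequencies
    elif side == "any":
        freq = report.appearance
    else:
        raise ValueError("side must be 'high' or 'any'")
    return set(freq.index[freq >= threshold])


def permutation_null(
    counts: CountTable | pd.DataFrame,
    response: pd.Series,
    n_permutations: int = 100,
    n_folds: int = 5,
    max_size: int = 8,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> BalanceCVReport:
    """Null calibration of appearance frequencies by label permutation.

    Labels are re-permuted for every repeat (a single fixed permutation can
    retain an apparent association that every CV split of the same data
    rediscovers, which is not a null); each permutation contributes one
    ``n_folds`` cross-validation round and frequencies aggregate over all
    permutation × fold steps.
    """
    frame = counts.counts if isinstance(counts, CountTable) else counts
    response = response.reindex(frame.index)
    rng = np.random.default_rng(seed)
    reports = []
    for perm in range(n_permutations):
        shuffled = pd.Series(rng.permutation(response.to_numpy()), index=frame.index)
        reports.append(greedy_balance_cv(
            frame, shuffled, n_folds=n_folds, n_repeats=1, max_size=max_size,
            pseudocount=pseudocount, seed=seed + perm,
        ))
    n_steps = sum(r.n_steps for r in reports)
    freq = sum(r.frequencies * r.n_steps for r in reports) / n_steps
    appear = sum(r.appearance * r.n_steps for r in reports) / n_steps
    return BalanceCVReport(
        n_repeats=n_permutations,
        n_folds=n_folds,
        frequencies=freq.rename("frequency"),
        appearance=appear.rename("appearance"),
        mean_cv_auc=float(np.mean([r.mean_cv_auc for r in reports])),
        n_steps=n_steps,
        params={"permutation_null": True, "seed": seed, "max_size": max_size},
    )
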