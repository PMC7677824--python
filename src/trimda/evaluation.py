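"""Evaluation protocols: miRNA-wise K-fold CV, new-disease recovery, ablation.

Cross-validation folds *miRNAs*, not pairs: all association entries in the
test-fold rows are zeroed in the training matrix, the model is refit, and
every pair in those rows becomes a test instance (held-out known
associations are the positives, everything else in the rows the
negatives). Scores are pooled across folds within a repeat; repeats differ
by re-randomized fold assignment. The new-disease protocol instead masks
one disease column at a time and records the ranks at which its true
miRNAs are recovered. The ablation study replaces one input (associations,
miRNA similarity, or disease similarity) with a random matrix of the same
type and re-runs CV, quantifying each data source's contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .core import fit, predict_scores
from .io_config import AssociationDataset, RunConfig
from .similarity import SimilarityMatrix

__all__ = [
    "CVSplit",
    "EvaluationResult",
    "make_cv_folds",
    "training_matrix",
    "default_scorer",
    "run_cv",
    "compute_auc",
    "compute_pr",
    "paired_ttest",
    "new_disease_ranks",
    "topt_cdf",
    "ablation_randomize",
    "randomize_input",
]


@dataclass
class CVSplit:
    """A seeded balanced partition of miRNA indices into K folds (1..K)."""

    fold_assignments: dict[int, int]
    seed: int

    def test_rows(self, fold: int) -> np.ndarray:
        return np.array(sorted(i for i, f in self.fold_assignments.items() if f == fold))

    @property
    def k(self) -> int:
        return max(self.fold_assignments.values())


@dataclass
class EvaluationResult:
    per_repeat_auc: list[float]
    mean_auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    pvalues_vs: dict[str, float] = field(default_factory=dict)


def make_cv_folds(n_m: int, k: int, seed: int) -> CVSplit:
    """Seeded uniform random partition with fold sizes differing by <= 1."""
    if not (2 <= k <= n_m):
        raise ValueError(f"need 2 <= k <= n_m, got k={k}, n_m={n_m}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_m)
    folds = {}
    for pos, idx in enumerate(perm):
        folds[int(idx)] = pos % k + 1
    return CVSplit(fold_assignments=folds, seed=seed)


def training_matrix(A: np.ndarray, test_rows: np.ndarray) -> np.ndarray:
    """Training copy of A with every entry in the test rows forced to 0."""
    A_train = A.copy()
    A_train[test_rows, :] = 0.0
    return A_train


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties credited 1/2 (computed from average ranks, which is
    exact under ties).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("compute_auc requires both classes present")
    ranks = stats.rankdata(scores)  # average ranks -> half credit for ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_pr(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """Precision-recall points, one per distinct score threshold.

    Thresholds descend, so recall is nondecreasing along the returned list;
    the final point has recall 1 and precision equal to the prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("compute_pr requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted == 1)
    fp = np.cumsum(l_sorted == 0)
    n_pos = tp[-1]
    # last index of each run of equal scores = the confusion matrix at that threshold
    distinct = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    points = [
        (float(tp[i] / (tp[i] + fp[i])), float(tp[i] / n_pos)) for i in distinct
    ]
    return points


def paired_ttest(auc_a: Sequence[float], auc_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on per-run AUC differences."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        raise ValueError("degenerate paired t-test: zero-variance differences")
    res = stats.ttest_rel(a, b)
    return float(res.pvalue)


def default_scorer(
    ds_train: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    config: RunConfig,
) -> np.ndarray:
    """Fit the factor model on the training data and return its scores."""
    model, _ = fit(ds_train, S_m, S_d, config)
    return predict_scores(model)


def _repeat_auc(
    dataset: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    config: RunConfig,
    fold_seed: int,
    collect_points: bool = False,
    scorer=default_scorer,
):
    """One repeat of K-fold CV: pooled scores over all test-row pairs."""
    A = dataset.A
    n_m = dataset.n_m
    for redraw in range(20):
        split = make_cv_folds(n_m, config.folds, fold_seed + 1_000_003 * redraw)
        if all(A[split.test_rows(f), :].sum() > 0 for f in range(1, config.folds + 1)):
            break
        warnings.warn("a fold had no positives; re-drawing the partition", stacklevel=2)
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for f in range(1, config.folds + 1):
        rows = split.test_rows(f)
        A_train = training_matrix(A, rows)
        assert A_train[rows, :].sum() == 0, "test-row associations leaked into training"
        ds_train = AssociationDataset.from_matrix(
            A_train, dataset.mirna_ids, dataset.disease_ids
        )
        scores = scorer(ds_train, S_m, S_d, config)
        all_scores.append(scores[rows, :].ravel())
        all_labels.append(A[rows, :].ravel().astype(int))
    pooled_s = np.concatenate(all_scores)
    pooled_l = np.concatenate(all_labels)
    auc = compute_auc(pooled_s, pooled_l)
    if collect_points:
        fpr, tpr, _ = _roc_points(pooled_s, pooled_l)
        return auc, list(zip(fpr, tpr)), compute_pr(pooled_s, pooled_l)
    return auc, None, None


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    l_sorted = labels[order]
    s_sorted = scores[order]
    tp = np.cumsum(l_sorted == 1)
    fp = np.cumsum(l_sorted == 0)
    distinct = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    tpr = tp[distinct] / max(tp[-1], 1)
    fpr = fp[distinct] / max(fp[-1], 1)
    return fpr.tolist(), tpr.tolist(), s_sorted[distinct].tolist()


def run_cv(
    dataset: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    config: RunConfig,
    scorer=default_scorer,
) -> EvaluationResult:
    """Repeated miRNA-wise K-fold cross-validation.

    Each repeat re-randomizes the fold assignment (the repeat index
    perturbs the seed), refits the model per fold on the row-masked
    training matrix, pools scores over all test-row pairs, and computes one
    AUC. ROC/PR coordinates are kept for the first repeat. ``scorer`` maps
    a training dataset to a full score matrix; the default fits the factor
    model, alternatives (an oracle, a random baseline) let the harness be
    validated independently of the model.
    """
    aucs: list[float] = []
    roc: list[tuple[float, float]] = []
    pr: list[tuple[float, float]] = []
    for rep in range(config.repeats):
        auc, roc_r, pr_r = _repeat_auc(
            dataset,
            S_m,
            S_d,
            config,
            config.seed + rep,
            collect_points=(rep == 0),
            scorer=scorer,
        )
        aucs.append(auc)
        if rep == 0:
            roc, pr = roc_r, pr_r
    return EvaluationResult(
        per_repeat_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        roc_points=roc,
        pr_points=pr,
    )


def new_disease_ranks(
    dataset: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    config: RunConfig,
    disease_subset: Optional[Sequence[str]] = None,
) -> dict[str, list[float]]:
    """Rank recovery for simulated new diseases, one column at a time.

    For each evaluated disease its column is zeroed (the disease becomes
    "new": no known miRNAs), the model is refit, and the ranks (1 = best,
    ties get the average rank) of the masked true miRNAs within the
    disease's score column are recorded.
    """
    if disease_subset is None:
        disease_subset = dataset.disease_ids
    d_index = {d: j for j, d in enumerate(dataset.disease_ids)}
    out: dict[str, list[float]] = {}
    for d in disease_subset:
        if d not in d_index:
            raise ValueError(f"unknown disease id {d!r}")
        j = d_index[d]
        true_rows = np.nonzero(dataset.A[:, j])[0]
        if true_rows.size == 0:
            warnings.warn(f"disease {d!r} has no known miRNAs; skipped", stacklevel=2)
            continue
        A_masked = dataset.A.copy()
        A_masked[:, j] = 0.0
        ds_masked = AssociationDataset.from_matrix(
            A_masked, dataset.mirna_ids, dataset.disease_ids
        )
        model, _ = fit(ds_masked, S_m, S_d, config)
        col = predict_scores(model)[:, j]
        ranks = stats.rankdata(-col)  # 1 = highest score; ties -> average
        out[d] = [float(ranks[i]) for i in true_rows]
    return out


def topt_cdf(rank_lists: dict[str, list[float]], t_max: int) -> np.ndarray:
    """CDF over pooled rank records: entry t-1 is P(rank <= t), t = 1..t_max."""
    all_ranks = np.array([r for ranks in rank_lists.values() for r in ranks])
    if all_ranks.size == 0:
        raise ValueError("no rank records")
    ts = np.arange(1, t_max + 1)
    return (all_ranks[None, :] <= ts[:, None]).mean(axis=1)


def ablation_randomize(
    dataset: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    config: RunConfig,
    target: Literal["associations", "mirna_sim", "disease_sim"],
    seed: int,
    scorer=default_scorer,
) -> EvaluationResult:
    """Replace one data source with a random matrix of the same type, then
    run the CV protocol unchanged.

    Similarities become seeded symmetric uniform[0,1] matrices with unit
    diagonal; the association matrix becomes a uniformly random 0/1 matrix
    with the same number of known pairs (density preserved exactly). A
    source whose randomization hurts the AUC most contributes the most
    signal.
    """
    dataset, S_m, S_d = randomize_input(dataset, S_m, S_d, target, seed)
    return run_cv(dataset, S_m, S_d, config, scorer=scorer)


def randomize_input(
    dataset: AssociationDataset,
    S_m: SimilarityMatrix,
    S_d: SimilarityMatrix,
    target: Literal["associations", "mirna_sim", "disease_sim"],
    seed: int,
) -> tuple[AssociationDataset, SimilarityMatrix, SimilarityMatrix]:
    """Replace one of the three inputs with its random counterpart."""
    rng = np.random.default_rng(seed)
    if target == "mirna_sim":
        S_m = _random_similarity(rng, S_m.ids)
    elif target == "disease_sim":
        S_d = _random_similarity(rng, S_d.ids)
    elif target == "associations":
        n_obs = int(dataset.A.sum())
        flat = rng.choice(dataset.n_m * dataset.n_d, size=n_obs, replace=False)
        A_rand = np.zeros(dataset.n_m * dataset.n_d)
        A_rand[flat] = 1.0
        dataset = AssociationDataset.from_matrix(
            A_rand.reshape(dataset.n_m, dataset.n_d),
            dataset.mirna_ids,
            dataset.disease_ids,
        )
    else:
        raise ValueError(f"unknown ablation target {target!r}")
    return dataset, S_m, S_d


def _random_similarity(rng: np.random.Generator, ids: Sequence[str]) -> SimilarityMatrix:
    n = len(ids)
    raw = rng.uniform(0.0, 1.0, size=(n, n))
    S = (raw + raw.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=list(ids), S=S).validate()
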