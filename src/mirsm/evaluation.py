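"""Evaluation protocols: ranking metrics, cross-validation and holdout tests.

Four cross-validation schemes are provided. In five-fold CV the confirmed
associations are partitioned into five near-equal parts; each part in turn
is removed from the training matrix, the model is refitted, and the held-out
associations are ranked against all unknown pairs. In global LOOCV every
confirmed association is held out one at a time with all unknown pairs as
candidates; the local variants restrict the candidate set to unknown pairs
sharing the held-out pair's miRNA (miRNA-fixed) or SM (SM-fixed). Two
holdout experiments complete the protocol: ranking an independent positive
set against all remaining pairs (experiment A), and classification metrics
against sampled negative sets at criterion-maximizing thresholds
(experiment B).

AUC is computed as the Mann-Whitney statistic with half credit for ties,
equivalent to the trapezoidal area under the ROC curve with tie-grouped
thresholds.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AssociationMatrix, DatasetBundle, ValidationError
from .model import AssociationCompletion
from .solver import SolverConfig

__all__ = [
    "EvaluationResult",
    "BinaryMetrics",
    "roc_auc",
    "binary_metrics",
    "best_threshold",
    "partition_sizes",
    "five_fold_cv",
    "loocv",
    "loocv_candidates",
    "experiment_a",
    "experiment_b",
]

logger = logging.getLogger(__name__)

#: scorer signature: (training associations, bundle providing similarities,
#: solver config) -> ns x nm score array
Scorer = Callable[[AssociationMatrix, DatasetBundle, SolverConfig], np.ndarray]


def _default_scorer(train: AssociationMatrix, bundle: DatasetBundle, config: SolverConfig) -> np.ndarray:
    model = AssociationCompletion(
        train, bundle.sm_similarities, bundle.mirna_similarities, config=config
    )
    return model.fit().score_values


class BinaryMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float
    accuracy: float
    mcc: float


@dataclasses.dataclass
class EvaluationResult:
    """Outcome of one evaluation protocol run."""

    scheme: str
    auc_mean: float
    auc_sd: float | None
    per_fold: list[tuple[str, float]]
    metrics_table: list[tuple[str, float, float, float, float, float]] = dataclasses.field(
        default_factory=list
    )
    seed: int | None = None

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold, columns=["fold", "auc"])

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.metrics_table,
            columns=["threshold", "precision", "recall", "f1", "accuracy", "mcc"],
        )

    def write_report(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.fold_frame().to_csv(directory / "folds.tsv", sep="\t", index=False)
        sd = "" if self.auc_sd is None else f"{self.auc_sd:.4f}"
        with open(directory / "summary.tsv", "w") as fh:
            fh.write("scheme\tauc_mean\tauc_sd\tn_folds\tseed\n")
            fh.write(f"{self.scheme}\t{self.auc_mean:.4f}\t{sd}\t{len(self.per_fold)}\t{self.seed}\n")
        if self.metrics_table:
            self.metrics_frame().to_csv(directory / "metrics.tsv", sep="\t", index=False)


def roc_auc(test_scores: Sequence[float], candidate_scores: Sequence[float]) -> float:
    """Area under the ROC curve for test (positive) vs candidate scores.

    Equals the Mann-Whitney statistic: the fraction of (test, candidate)
    pairs with the test score higher, ties counted one half.
    """
    t = np.asarray(test_scores, dtype=float)
    c = np.asarray(candidate_scores, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValidationError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([t, c]))
    r_pos = ranks[: t.size].sum()
    return float((r_pos - t.size * (t.size + 1) / 2) / (t.size * c.size))


def binary_metrics(
    positive_flags: Sequence[bool], scores: Sequence[float], threshold: float
) -> BinaryMetrics:
    """Confusion-matrix metrics with prediction positive iff score >= threshold.

    Undefined ratios (zero denominators) are reported as 0 and logged.
    """
    y = np.asarray(positive_flags, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("flags and scores must be aligned")
    if not (y.any() and (~y).any()):
        raise ValidationError("need at least one positive and one negative")
    pred = s >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.info("%s undefined (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = (tp + tn) / len(y)
    mcc = ratio(
        tp * tn - fp * fn,
        math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)),
        "mcc",
    )
    return BinaryMetrics(precision, recall, f1, accuracy, mcc)


def best_threshold(
    positive_flags: Sequence[bool], scores: Sequence[float], criterion: str
) -> float:
    """Observed score value maximizing the given criterion (f1/accuracy/mcc).

    Candidate thresholds are the distinct observed scores, swept in
    descending order; the first maximizer (highest threshold) is returned.
    """
    if criterion not in ("f1", "accuracy", "mcc"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    best_t, best_v = None, -np.inf
    for t in sorted(set(np.asarray(scores, dtype=float)), reverse=True):
        v = getattr(binary_metrics(positive_flags, scores, t), criterion)
        if v > best_v:
            best_t, best_v = t, v
    return float(best_t)


def partition_sizes(n: int, k: int = 5) -> list[int]:
    """Sizes of k near-equal parts of n items, smaller parts first.

    664 associations split five ways as [132, 133, 133, 133, 133].
    """
    base, rem = divmod(n, k)
    return [base] * (k - rem) + [base + 1] * rem


def _remove_pairs(assoc: AssociationMatrix, pairs: Sequence[tuple[int, int]]) -> AssociationMatrix:
    train = assoc.copy()
    for i, j in pairs:
        train.values[i, j] = 0
    return train


def five_fold_cv(
    bundle: DatasetBundle,
    config: SolverConfig | None = None,
    repeats: int = 100,
    seed: int = 0,
    scorer: Scorer | None = None,
) -> EvaluationResult:
    """Repeated five-fold cross-validation over the confirmed associations.

    Per repeat the known associations are randomly partitioned into five
    near-equal parts; per fold the test part is removed from the training
    matrix and its scores are ranked against all unknown pairs. The result
    is the mean over repeat-level AUC means, with the population SD across
    repeats.
    """
    config = config if config is not None else SolverConfig()
    scorer = scorer or _default_scorer
    assoc = bundle.associations
    known = assoc.known_pairs()
    if len(known) < 5:
        raise ValidationError("five-fold CV needs at least 5 known associations")
    unknown_idx = np.where(assoc.values.ravel() == 0)[0]
    rng = np.random.default_rng(seed)
    sizes = partition_sizes(len(known), 5)
    per_fold: list[tuple[str, float]] = []
    repeat_means = []
    for rep in range(repeats):
        order = rng.permutation(len(known))
        fold_aucs = []
        start = 0
        for f, size in enumerate(sizes):
            test = [known[i] for i in order[start : start + size]]
            start += size
            scores = scorer(_remove_pairs(assoc, test), bundle, config)
            flat = scores.ravel()
            auc = roc_auc([scores[i, j] for i, j in test], flat[unknown_idx])
            fold_aucs.append(auc)
            per_fold.append((f"repeat{rep}/fold{f}", auc))
        repeat_means.append(float(np.mean(fold_aucs)))
    return EvaluationResult(
        scheme="five_fold",
        auc_mean=float(np.mean(repeat_means)),
        auc_sd=float(np.std(repeat_means)),
        per_fold=per_fold,
        seed=seed,
    )


def loocv_candidates(
    assoc: AssociationMatrix, scheme: str, pair: tuple[int, int]
) -> list[tuple[int, int]]:
    """Candidate pairs for one LOOCV fold holding out ``pair``.

    ``global``: all unknown pairs; ``mirna_fixed``: unknown pairs in the
    held-out miRNA's column; ``sm_fixed``: unknown pairs in the held-out
    SM's row.
    """
    if scheme not in ("global", "mirna_fixed", "sm_fixed"):
        raise ValidationError(f"unknown LOOCV scheme {scheme!r}")
    i, j = pair
    zeros = assoc.values == 0
    if scheme == "global":
        return [tuple(p) for p in np.argwhere(zeros)]
    if scheme == "mirna_fixed":
        return [(int(r), j) for r in np.where(zeros[:, j])[0]]
    return [(i, int(c)) for c in np.where(zeros[i, :])[0]]


def loocv(
    bundle: DatasetBundle,
    config: SolverConfig | None = None,
    scheme: str = "global",
    scorer: Scorer | None = None,
) -> EvaluationResult:
    """Leave-one-out cross-validation over the confirmed associations.

    ``scheme`` selects the candidate set per fold: ``global`` (all unknown
    pairs), ``mirna_fixed`` (unknown pairs sharing the held-out miRNA) or
    ``sm_fixed`` (unknown pairs sharing the held-out SM). Folds with empty
    candidate sets are skipped and logged.
    """
    if scheme not in ("global", "mirna_fixed", "sm_fixed"):
        raise ValidationError(f"unknown LOOCV scheme {scheme!r}")
    config = config if config is not None else SolverConfig()
    scorer = scorer or _default_scorer
    assoc = bundle.associations
    known = assoc.known_pairs()
    if len(known) < 2:
        raise ValidationError("LOOCV needs at least 2 known associations")
    per_fold: list[tuple[str, float]] = []
    for i, j in known:
        cand = loocv_candidates(assoc, scheme, (i, j))
        if not cand:
            logger.warning("fold (%d, %d): empty candidate set, skipped", i, j)
            continue
        scores = scorer(_remove_pairs(assoc, [(i, j)]), bundle, config)
        per_fold.append(
            (f"({i},{j})", roc_auc([scores[i, j]], [scores[r, c] for r, c in cand]))
        )
    aucs = [a for _, a in per_fold]
    return EvaluationResult(
        scheme=f"{scheme}_loocv",
        auc_mean=float(np.mean(aucs)),
        auc_sd=None,
        per_fold=per_fold,
    )


def experiment_a(
    bundle: DatasetBundle,
    positive_test_pairs: Sequence[tuple[int, int]],
    config: SolverConfig | None = None,
    scorer: Scorer | None = None,
) -> EvaluationResult:
    """Train on the bundle's associations, rank an independent positive set.

    Candidates are all pairs that are neither training 1s nor test
    positives.
    """
    config = config if config is not None else SolverConfig()
    scorer = scorer or _default_scorer
    assoc = bundle.associations
    pos = set(map(tuple, positive_test_pairs))
    if any(assoc.values[i, j] == 1 for i, j in pos):
        raise ValidationError("positive test pairs must be disjoint from training 1s")
    scores = scorer(assoc, bundle, config)
    cand = [
        scores[i, j]
        for i in range(assoc.ns)
        for j in range(assoc.nm)
        if assoc.values[i, j] == 0 and (i, j) not in pos
    ]
    auc = roc_auc([scores[i, j] for i, j in pos], cand)
    return EvaluationResult("experiment_a", auc, None, [("all", auc)])


def experiment_b(
    bundle: DatasetBundle,
    positive_test_pairs: Sequence[tuple[int, int]],
    config: SolverConfig | None = None,
    repeats: int = 100,
    seed: int = 0,
    scorer: Scorer | None = None,
) -> EvaluationResult:
    """Classification-style holdout test against sampled negative sets.

    The model is fitted once on the bundle's associations. Per repeat an
    equal-sized negative set is sampled from the unknown pairs (disjoint
    from the training 1s and the positives); AUC and the metric rows at the
    three thresholds maximizing F1, accuracy and MCC are computed, then
    averaged over repeats.
    """
    config = config if config is not None else SolverConfig()
    scorer = scorer or _default_scorer
    assoc = bundle.associations
    pos = [tuple(p) for p in positive_test_pairs]
    pos_set = set(pos)
    if any(assoc.values[i, j] == 1 for i, j in pos):
        raise ValidationError("positive test pairs must be disjoint from training 1s")
    pool = [
        (i, j)
        for i in range(assoc.ns)
        for j in range(assoc.nm)
        if assoc.values[i, j] == 0 and (i, j) not in pos_set
    ]
    if len(pool) < len(pos):
        raise ValidationError("not enough unknown pairs to sample a negative set")
    scores = scorer(assoc, bundle, config)
    pos_scores = np.array([scores[i, j] for i, j in pos])
    rng = np.random.default_rng(seed)
    per_fold = []
    rows = np.zeros((3, 5))
    for rep in range(repeats):
        neg = [pool[t] for t in rng.choice(len(pool), size=len(pos), replace=False)]
        neg_scores = np.array([scores[i, j] for i, j in neg])
        per_fold.append((f"repeat{rep}", roc_auc(pos_scores, neg_scores)))
        flags = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
        allsc = np.concatenate([pos_scores, neg_scores])
        for t_idx, crit in enumerate(("f1", "accuracy", "mcc")):
            thr = best_threshold(flags, allsc, crit)
            rows[t_idx] += np.array(binary_metrics(flags, allsc, thr))
    rows /= repeats
    aucs = [a for _, a in per_fold]
    return EvaluationResult(
        scheme="experiment_b",
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs)),
        per_fold=per_fold,
        metrics_table=[
            (f"t{t_idx + 1}", *map(float, rows[t_idx])) for t_idx in range(3)
        ],
        seed=seed,
    )
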