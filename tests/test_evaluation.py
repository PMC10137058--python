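import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsm import (
    DatasetBundle,
    ValidationError,
    best_threshold,
    binary_metrics,
    experiment_a,
    experiment_b,
    five_fold_cv,
    loocv,
    roc_auc,
)
from mirsm.evaluation import loocv_candidates, partition_sizes

from conftest import make_similarity
from mirsm import AssociationMatrix


def brute_force_auc(test, cand):
    """Exhaustive pairwise-comparison oracle with half credit for ties."""
    wins = sum(1.0 if t > c else 0.5 if t == c else 0.0 for t in test for c in cand)
    return wins / (len(test) * len(cand))


# --- ranking metrics ------------------------------------------------------------


def test_roc_auc_examples():
    assert roc_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
    assert roc_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5
    assert roc_auc([0.9, 0.4], [0.5, 0.3, 0.1]) == pytest.approx(5 / 6)
    with pytest.raises(ValidationError):
        roc_auc([], [0.1])


@settings(deadline=None, derandomize=True)
@given(
    test=st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.9]), min_size=1, max_size=25),
    cand=st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.9]), min_size=1, max_size=25),
)
def test_roc_auc_matches_pairwise_oracle(test, cand):
    assert roc_auc(test, cand) == pytest.approx(brute_force_auc(test, cand))


def test_roc_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    for _ in range(20):
        t = rng.choice([0.1, 0.3, 0.5, 0.8], size=rng.integers(2, 20))
        c = rng.choice([0.1, 0.3, 0.5, 0.8], size=rng.integers(2, 20))
        labels = np.r_[np.ones(len(t)), np.zeros(len(c))]
        assert roc_auc(t, c) == pytest.approx(roc_auc_score(labels, np.r_[t, c]))


def test_roc_auc_monotone_invariance():
    rng = np.random.default_rng(1)
    t, c = rng.random(15), rng.random(30)
    assert roc_auc(t, c) == pytest.approx(roc_auc(np.exp(3 * t), np.exp(3 * c)))


def test_binary_metrics_hand_computed():
    # TP=3, FP=1, FN=1, TN=5 at threshold 0.5
    flags = [True] * 4 + [False] * 6
    scores = [0.9, 0.9, 0.9, 0.1, 0.8, 0.2, 0.2, 0.2, 0.2, 0.2]
    m = binary_metrics(flags, scores, 0.5)
    assert m.precision == pytest.approx(0.75)
    assert m.recall == pytest.approx(0.75)
    assert m.f1 == pytest.approx(0.75)
    assert m.accuracy == pytest.approx(0.8)
    # MCC = (3*5 - 1*1) / sqrt((3+1)(3+1)(5+1)(5+1)) = 14/24
    assert m.mcc == pytest.approx(14 / math.sqrt(4 * 4 * 6 * 6))


def test_binary_metrics_edge_cases():
    flags = [True, True, False, False]
    perfect = binary_metrics(flags, [0.9, 0.8, 0.2, 0.1], 0.5)
    assert perfect == (1.0, 1.0, 1.0, 1.0, 1.0)
    none_predicted = binary_metrics(flags, [0.9, 0.8, 0.2, 0.1], 2.0)
    assert none_predicted.recall == 0.0
    assert none_predicted.precision == 0.0  # zero denominator convention
    with pytest.raises(ValidationError):
        binary_metrics([True, True], [0.1, 0.2], 0.5)


def test_binary_metrics_matches_sklearn():
    from sklearn.metrics import f1_score, matthews_corrcoef, precision_score, recall_score

    rng = np.random.default_rng(2)
    flags = rng.random(40) < 0.4
    flags[:2] = [True, False]
    scores = rng.random(40)
    m = binary_metrics(flags, scores, 0.5)
    pred = scores >= 0.5
    assert m.precision == pytest.approx(precision_score(flags, pred, zero_division=0))
    assert m.recall == pytest.approx(recall_score(flags, pred))
    assert m.f1 == pytest.approx(f1_score(flags, pred))
    assert m.mcc == pytest.approx(matthews_corrcoef(flags, pred))


def test_best_threshold_exhaustive_oracle():
    rng = np.random.default_rng(3)
    flags = rng.random(25) < 0.3
    flags[:2] = [True, False]
    scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=25)
    for crit in ("f1", "accuracy", "mcc"):
        thr = best_threshold(flags, scores, crit)
        best = getattr(binary_metrics(flags, scores, thr), crit)
        for t in set(scores):
            assert best >= getattr(binary_metrics(flags, scores, t), crit) - 1e-12


def test_best_threshold_single_top_positive():
    flags = [True, False, False]
    scores = [0.9, 0.5, 0.1]
    for crit in ("f1", "accuracy", "mcc"):
        assert best_threshold(flags, scores, crit) == 0.9


# --- protocols (cheap injected scorers) ----------------------------------------


def toy_bundle(ns=6, nm=5, seed=0, density=0.3):
    rng = np.random.default_rng(seed)
    M = (rng.random((ns, nm)) < density).astype(np.int8)
    M[0, 0] = 1  # ensure at least one association
    assoc = AssociationMatrix(M, [f"s{i}" for i in range(ns)], [f"m{j}" for j in range(nm)])
    return DatasetBundle(
        assoc,
        [make_similarity(ns, ids=list(assoc.sm_ids), seed=seed)],
        [make_similarity(nm, ids=list(assoc.mirna_ids), seed=seed + 1)],
    )


def fixed_scorer(seed=0):
    def scorer(train, bundle, config):
        rng = np.random.default_rng(seed)
        return rng.random(train.values.shape)

    return scorer


def test_partition_sizes_published_split():
    assert partition_sizes(664, 5) == [132, 133, 133, 133, 133]
    assert partition_sizes(10, 5) == [2, 2, 2, 2, 2]
    assert sum(partition_sizes(17, 5)) == 17
    assert max(partition_sizes(17, 5)) - min(partition_sizes(17, 5)) == 1


def test_five_fold_partition_and_determinism():
    bundle = toy_bundle(seed=4)
    seen = []

    def recording_scorer(train, b, config):
        removed = set(bundle.associations.known_pairs()) - set(train.known_pairs())
        seen.append(removed)
        assert b is bundle  # similarity blocks untouched
        return fixed_scorer(1)(train, b, config)

    res = five_fold_cv(bundle, repeats=2, seed=9, scorer=recording_scorer)
    known = set(bundle.associations.known_pairs())
    for rep in range(2):
        folds = seen[5 * rep : 5 * rep + 5]
        assert set().union(*folds) == known
        assert sum(len(f) for f in folds) == len(known)  # pairwise disjoint
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1
    res2 = five_fold_cv(bundle, repeats=2, seed=9, scorer=fixed_scorer(1))
    assert res.auc_mean == res2.auc_mean and res.per_fold == res2.per_fold
    assert res.auc_sd >= 0


def test_five_fold_requires_enough_associations():
    bundle = toy_bundle(ns=3, nm=3, seed=5, density=0.1)
    if bundle.associations.n_known >= 5:
        pytest.skip("draw produced too many associations")
    with pytest.raises(ValidationError):
        five_fold_cv(bundle, repeats=1, seed=0, scorer=fixed_scorer())


def test_loocv_fold_count_and_candidates():
    bundle = toy_bundle(seed=6)
    n = bundle.associations.n_known
    res = loocv(bundle, scheme="global", scorer=fixed_scorer(2))
    assert len(res.per_fold) == n
    assoc = bundle.associations
    for (i, j) in assoc.known_pairs():
        assert len(loocv_candidates(assoc, "global", (i, j))) == (
            assoc.ns * assoc.nm - assoc.n_known
        )
        assert len(loocv_candidates(assoc, "sm_fixed", (i, j))) == int(
            (assoc.values[i, :] == 0).sum()
        )
        assert len(loocv_candidates(assoc, "mirna_fixed", (i, j))) == int(
            (assoc.values[:, j] == 0).sum()
        )


def test_loocv_skips_empty_candidate_folds():
    # one SM row entirely 1s: its sm_fixed folds have no candidates
    M = np.array([[1, 1], [1, 0]])
    assoc = AssociationMatrix(M, ["s1", "s2"], ["m1", "m2"])
    bundle = DatasetBundle(assoc, [make_similarity(2, ids=["s1", "s2"])],
                           [make_similarity(2, ids=["m1", "m2"])])
    res = loocv(bundle, scheme="sm_fixed", scorer=fixed_scorer(3))
    assert len(res.per_fold) == 1  # only (s2, m1) has a same-row candidate


def test_experiment_a_oracle_scorer():
    bundle = toy_bundle(seed=7)
    zeros = [tuple(p) for p in np.argwhere(bundle.associations.values == 0)]
    pos = zeros[:3]

    def oracle(train, b, config):
        s = np.zeros(train.values.shape)
        for i, j in pos:
            s[i, j] = 1.0
        return s

    res = experiment_a(bundle, pos, scorer=oracle)
    assert res.auc_mean == 1.0
    with pytest.raises(ValidationError):
        experiment_a(bundle, [bundle.associations.known_pairs()[0]], scorer=oracle)


def test_experiment_b_oracle_scorer_all_metrics_one():
    bundle = toy_bundle(seed=8)
    zeros = [tuple(p) for p in np.argwhere(bundle.associations.values == 0)]
    pos = zeros[:4]

    def oracle(train, b, config):
        s = np.zeros(train.values.shape)
        for i, j in pos:
            s[i, j] = 1.0
        return s

    res = experiment_b(bundle, pos, repeats=3, seed=1, scorer=oracle)
    assert res.auc_mean == 1.0
    for row in res.metrics_table:
        assert row[1:] == (1.0, 1.0, 1.0, 1.0, 1.0)
    assert [r[0] for r in res.metrics_table] == ["t1", "t2", "t3"]


def test_experiment_b_reproducible_and_pool_guard():
    bundle = toy_bundle(seed=9)
    zeros = [tuple(p) for p in np.argwhere(bundle.associations.values == 0)]
    pos = zeros[:2]
    a = experiment_b(bundle, pos, repeats=2, seed=5, scorer=fixed_scorer(4))
    b = experiment_b(bundle, pos, repeats=2, seed=5, scorer=fixed_scorer(4))
    assert a.auc_mean == b.auc_mean and a.metrics_table == b.metrics_table
    # pool too small: positives leave fewer unknowns than needed
    tiny = toy_bundle(ns=2, nm=2, seed=10, density=0.9)
    tiny_zeros = [tuple(p) for p in np.argwhere(tiny.associations.values == 0)]
    if len(tiny_zeros) >= 1:
        with pytest.raises(ValidationError):
            experiment_b(tiny, tiny_zeros, repeats=1, seed=0, scorer=fixed_scorer())
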