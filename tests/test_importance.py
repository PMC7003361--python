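"""Resampling, out-of-bag permutation scoring and importance accumulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecfs_dea.classifiers import BaseClassifierSpec, FittedClassifier
from ecfs_dea.importance import (
    ResamplingConfig,
    _stratified_in_bag,
    accumulate_importance,
    permute_and_score,
    rank_variables,
    round_seed_sequence,
    run_round,
    split_samples,
)

LDA = BaseClassifierSpec("lda")


def _cfg(kind="lda", rounds=5, seed=0, **kw):
    return ResamplingConfig(classifier=BaseClassifierSpec(kind, kw), rounds=rounds, seed=seed)


class _ConstantEstimator:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=np.int64)


def _stub(label, n_variables):
    return FittedClassifier(LDA, _ConstantEstimator(label), n_variables)


# ---------------------------------------------------------------- split_samples

def test_split_is_stratified_partition():
    labels = np.repeat([1, 0], 250)
    split = split_samples(labels, 0.5, seed=3)
    assert len(split.test_indices) == 250 and len(split.train_indices) == 250
    for part in (split.test_indices, split.train_indices):
        assert np.bincount(labels[part]).tolist() == [125, 125]
    union = np.union1d(split.train_indices, split.test_indices)
    assert np.array_equal(union, np.arange(500))


def test_split_seeds_change_membership_not_counts():
    labels = np.tile([0, 1], 40)
    a = split_samples(labels, 0.5, seed=1)
    b = split_samples(labels, 0.5, seed=2)
    assert not np.array_equal(a.test_indices, b.test_indices)
    assert np.bincount(labels[a.test_indices]).tolist() == np.bincount(labels[b.test_indices]).tolist()
    again = split_samples(labels, 0.5, seed=1)
    assert np.array_equal(a.test_indices, again.test_indices)


@given(
    n0=st.integers(3, 40),
    n1=st.integers(3, 40),
    frac=st.floats(0.2, 0.8),
    seed=st.integers(0, 2**20),
)
def test_split_partition_property(n0, n1, frac, seed):
    labels = np.array([0] * n0 + [1] * n1)
    try:
        split = split_samples(labels, frac, seed)
    except ValueError:
        return  # a class would be emptied; rejection is the contract
    assert np.array_equal(
        np.union1d(split.train_indices, split.test_indices), np.arange(n0 + n1)
    )
    assert np.intersect1d(split.train_indices, split.test_indices).size == 0
    assert np.sum(labels[split.test_indices] == 0) == round(n0 * frac)
    assert np.sum(labels[split.test_indices] == 1) == round(n1 * frac)


def test_split_rejects_tiny_class():
    with pytest.raises(ValueError, match="fewer than 2"):
        split_samples(np.array([0, 1, 1, 1]), 0.5, 0)


# ------------------------------------------------------------------- run_round

def test_in_bag_and_oob_sizes_for_balanced_250():
    y = np.repeat([0, 1], 125)
    in_bag, oob = _stratified_in_bag(y, 0.7, np.random.default_rng(0))
    assert len(in_bag) == 175 and len(oob) == 75
    assert np.array_equal(np.sort(np.concatenate([in_bag, oob])), np.arange(250))
    # stratification within one sample
    counts = np.bincount(y[in_bag])
    assert abs(counts[0] - counts[1]) <= 1


def test_stub_error_accounting_is_exact():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 3))
    y = np.repeat([0, 1], 20)
    rec = run_round(X, y, _cfg(rounds=1), round_seed_sequence(9, 0),
                    fitter=lambda Xb, yb, s: _stub(0, 3))
    oob_y = y[rec.out_of_bag]
    assert rec.err == np.mean(oob_y == 1)  # constant-0 stub misses exactly class 1
    # permuting any column cannot change a constant prediction
    assert np.array_equal(rec.permuted_err, np.full(3, rec.err))


def test_errors_are_multiples_of_one_over_oob(default_sim, sim_split):
    m, split = default_sim, sim_split
    rec = run_round(
        m.values[split.train_indices], m.labels[split.train_indices],
        _cfg(rounds=1, seed=2), round_seed_sequence(2, 0),
    )
    n_oob = len(rec.out_of_bag)
    assert float(rec.err * n_oob) == pytest.approx(round(rec.err * n_oob), abs=1e-9)
    scaled = np.asarray(rec.permuted_err) * n_oob
    assert np.allclose(scaled, np.round(scaled), atol=1e-9)


def test_round_error_matches_brute_force_recount(default_sim, sim_split):
    from ecfs_dea import classifiers as C

    m, split = default_sim, sim_split
    cfg = _cfg(rounds=1, seed=2)
    seed_seq = round_seed_sequence(2, 0)
    rec = run_round(m.values[split.train_indices], m.labels[split.train_indices], cfg, seed_seq)
    # replay: rebuild the same model from the recorded in-bag indices
    rng = np.random.default_rng(round_seed_sequence(2, 0))
    in_bag, oob = _stratified_in_bag(m.labels[split.train_indices], 0.7, rng)
    clf_seed = int(rng.integers(2**31))
    assert np.array_equal(in_bag, rec.in_bag) and np.array_equal(oob, rec.out_of_bag)
    model = C.fit(cfg.classifier, m.values[split.train_indices][in_bag],
                  m.labels[split.train_indices][in_bag], seed=clf_seed)
    pred = model.predict(m.values[split.train_indices][oob])
    miss = int(np.sum(pred != m.labels[split.train_indices][oob]))
    assert rec.err == miss / len(oob)


def test_batched_permutation_scores_equal_sequential_replay(default_sim, sim_split):
    """run_round's vectorized scoring must replay the documented RNG stream."""
    from ecfs_dea import classifiers as C

    m, split = default_sim, sim_split
    tX = m.values[split.train_indices][:, :7]  # keep it small
    ty = m.labels[split.train_indices]
    cfg = _cfg(rounds=1, seed=31)
    rec = run_round(tX, ty, cfg, round_seed_sequence(31, 0))
    rng = np.random.default_rng(round_seed_sequence(31, 0))
    in_bag, oob = _stratified_in_bag(ty, 0.7, rng)
    clf_seed = int(rng.integers(2**31))
    model = C.fit(cfg.classifier, tX[in_bag], ty[in_bag], seed=clf_seed)
    manual = [permute_and_score(model, tX[oob], ty[oob], i, rng) for i in range(7)]
    assert np.array_equal(rec.permuted_err, manual)


# ----------------------------------------------------------- permute_and_score

def test_constant_column_permutation_leaves_error_unchanged(separable_xy):
    from ecfs_dea import classifiers as C

    X, y = separable_xy
    X = np.hstack([X, np.full((len(y), 1), 3.14)])
    model = C.fit(LDA, X, y)
    base = float(np.mean(model.predict(X) != y))
    assert permute_and_score(model, X, y, 1, np.random.default_rng(0)) == base


def test_single_oob_sample_permutation_is_identity(separable_xy):
    from ecfs_dea import classifiers as C

    X, y = separable_xy
    model = C.fit(LDA, X, y)
    err = permute_and_score(model, X[:1], y[:1], 0, np.random.default_rng(5))
    assert err == float(model.predict(X[:1])[0] != y[0])


def test_permutation_replay_oracle_and_no_mutation(separable_xy):
    from ecfs_dea import classifiers as C

    rng0 = np.random.default_rng(77)
    X = rng0.normal(size=(30, 4))
    y = np.repeat([0, 1], 15)
    model = C.fit(BaseClassifierSpec("knn", {"k": 3}), X, y)
    before = X.copy()
    got = permute_and_score(model, X, y, 2, np.random.default_rng(123))
    assert np.array_equal(X, before)  # input untouched
    perm = np.random.default_rng(123).permutation(30)
    Xp = X.copy()
    Xp[:, 2] = Xp[perm, 2]
    assert got == float(np.mean(model.predict(Xp) != y))


# ------------------------------------------------------- accumulate_importance

def test_single_round_importance_equals_hand_driven_round(default_sim, sim_split):
    m, split = default_sim, sim_split
    tX, ty = m.values[split.train_indices], m.labels[split.train_indices]
    cfg = _cfg(rounds=1, seed=13)
    res = accumulate_importance(tX, ty, cfg)
    rec = run_round(tX, ty, cfg, round_seed_sequence(13, 0), index=0)
    assert np.array_equal(res.importance, rec.permuted_err - rec.err)
    assert np.all(res.importance >= -1) and np.all(res.importance <= 1)


@pytest.mark.parametrize("kind,params", [("lda", {}), ("knn", {}), ("svm", {}), ("rf", {"trees": 10})])
def test_constant_variable_has_exactly_zero_importance(kind, params, separable_xy):
    X, y = separable_xy
    X = np.hstack([X, np.full((len(y), 1), 2.0)])
    res = accumulate_importance(X, y, _cfg(kind, rounds=4, seed=5, **params))
    assert res.importance[1] == 0.0


def test_importance_is_exact_mean_of_round_differences(default_sim, sim_split):
    m, split = default_sim, sim_split
    tX, ty = m.values[split.train_indices][:, :6], m.labels[split.train_indices]
    res = accumulate_importance(tX, ty, _cfg(rounds=7, seed=21))
    recomputed = np.mean([r.permuted_err - r.err for r in res.rounds], axis=0)
    assert np.array_equal(res.importance, recomputed)
    assert len(res.rounds) == 7


def test_serial_and_parallel_runs_are_bit_identical(default_sim, sim_split):
    m, split = default_sim, sim_split
    tX, ty = m.values[split.train_indices][:, :6], m.labels[split.train_indices]
    cfg = _cfg(rounds=6, seed=17)
    serial = accumulate_importance(tX, ty, cfg, n_jobs=1)
    parallel = accumulate_importance(tX, ty, cfg, n_jobs=2)
    assert np.array_equal(serial.importance, parallel.importance)
    for a, b in zip(serial.rounds, parallel.rounds):
        assert np.array_equal(a.in_bag, b.in_bag)
        assert a.err == b.err and np.array_equal(a.permuted_err, b.permuted_err)


def test_same_seed_reproduces_bit_identical_result(default_sim, sim_split):
    m, split = default_sim, sim_split
    tX, ty = m.values[split.train_indices][:, :5], m.labels[split.train_indices]
    a = accumulate_importance(tX, ty, _cfg(rounds=5, seed=99))
    b = accumulate_importance(tX, ty, _cfg(rounds=5, seed=99))
    assert np.array_equal(a.importance, b.importance)


# -------------------------------------------------------------- rank_variables

def test_rank_orders_desc_and_breaks_ties_by_index():
    from ecfs_dea.importance import ImportanceResult

    cfg = _cfg(rounds=1)
    assert rank_variables(ImportanceResult(np.array([0.0, 0.3, 0.3]), [], cfg)) == [
        (1, 0.3), (2, 0.3), (0, 0.0),
    ]
    assert [i for i, _ in rank_variables(ImportanceResult(np.zeros(4), [], cfg))] == [0, 1, 2, 3]


# ------------------------------------------------- signal and null calibration

def test_lda_importance_finds_pair_and_nulls_center_on_zero(default_sim, sim_split):
    m, split = default_sim, sim_split
    tX, ty = m.values[split.train_indices], m.labels[split.train_indices]
    res = accumulate_importance(tX, ty, _cfg(rounds=150, seed=7))
    top = [i for i, _ in rank_variables(res)[:2]]
    assert sorted(top) == [0, 1]
    assert min(res.importance[0], res.importance[1]) > res.importance[2:].max()
    null_imp = res.importance[2:]
    se = null_imp.std(ddof=1) / np.sqrt(null_imp.size)
    assert abs(null_imp.mean()) <= 3 * max(se, 1e-12)
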