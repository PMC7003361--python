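"""Classifier-agnostic permutation variable importance over resampling rounds.

In each of r rounds a stratified 70% in-bag subsample of the training samples
is drawn and one base classifier is fitted on it over the entire variable
space. The remaining 30% out-of-bag (OOB) samples give the round's error rate
``Err_j``. For each variable i, the OOB values of column i are permuted exactly
once and the model re-scored, giving ``Err0_j(i)``. After r rounds the
importance of variable i is

    importance[i] = sum_j (Err0_j(i) - Err_j) / r

which can be negative and is an unbiased ~0 for uninformative variables.
Per-round seeds are derived from the master seed by a counter-based scheme
(round index -> independent stream), so results are identical whether rounds
run serially or in parallel, and extending r re-uses earlier rounds' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from . import classifiers
from .classifiers import BaseClassifierSpec, FittedClassifier
from .datamodel import DataSplit

# spawn-key namespaces under the master seed (must not collide)
_ROUND_STREAM = 0  # importance resampling rounds
_ENSEMBLE_STREAM = 1  # ensemble member training (see ensemble module)

# cap on the row count of one batched prediction call when scoring permuted copies
_MAX_BATCH_CELLS = 4_000_000


@dataclass
class ResamplingConfig:
    """Controls the resampling scheme shared by importance and ensemble phases."""

    classifier: BaseClassifierSpec
    rounds: int = 500
    in_bag_fraction: float = 0.7
    test_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0.0 < self.in_bag_fraction < 1.0:
            raise ValueError("in_bag_fraction must be in (0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class RoundRecord:
    """One resampling round: partition, OOB error, and per-variable permuted errors."""

    index: int
    in_bag: np.ndarray
    out_of_bag: np.ndarray
    err: float
    permuted_err: np.ndarray


@dataclass
class ImportanceResult:
    """Accumulated importance with the full per-round record and config echo."""

    importance: np.ndarray
    rounds: list[RoundRecord]
    config: ResamplingConfig
    variable_names: list[str] | None = None


def split_samples(labels: np.ndarray, test_fraction: float, seed: int) -> DataSplit:
    """Stratified train/test split: per-class test count = round(n_c * fraction)."""
    labels = np.asarray(labels, dtype=np.int64)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        n_test = round(idx.size * test_fraction)
        if n_test < 1 or n_test >= idx.size:
            raise ValueError(f"test_fraction {test_fraction} leaves class {c} empty on one side")
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return DataSplit(np.sort(np.concatenate(train)), np.sort(np.concatenate(test)))


def _stratified_in_bag(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Largest-remainder apportionment of round(fraction*n) in-bag slots per class.

    Remainder ties are broken by the round's RNG so that no class systematically
    receives the extra slot across rounds. Errors out if a class would be left
    out of the in-bag draw entirely.
    """
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    target = round(fraction * n)
    if not 0 < target < n:
        raise ValueError("in-bag fraction leaves in-bag or out-of-bag empty")
    class_idx = [np.flatnonzero(y == c) for c in (0, 1)]
    quotas = np.array([fraction * idx.size for idx in class_idx])
    base = np.floor(quotas).astype(int)
    remainders = quotas - base
    tiebreak = rng.random(2)
    leftover = target - int(base.sum())
    order = np.lexsort((tiebreak, -remainders))
    for c in order[:leftover]:
        base[c] += 1
    if np.any(base < 1) or np.any(base >= np.array([idx.size for idx in class_idx]) + 1):
        raise ValueError("impossible stratification: a class would be absent from the in-bag set")
    in_bag, oob = [], []
    for c in (0, 1):
        perm = rng.permutation(class_idx[c])
        in_bag.append(perm[: base[c]])
        oob.append(perm[base[c] :])
    return np.sort(np.concatenate(in_bag)), np.sort(np.concatenate(oob))


def permute_and_score(
    model: FittedClassifier,
    oob_X: np.ndarray,
    oob_y: np.ndarray,
    variable: int,
    rng: np.random.Generator,
) -> float:
    """Err0_j(i): OOB error after one random permutation of column ``variable``.

    Operates on a copy; the caller's arrays are untouched.
    """
    oob_X = np.asarray(oob_X, dtype=np.float64)
    if not 0 <= variable < oob_X.shape[1]:
        raise IndexError(f"variable {variable} out of range for {oob_X.shape[1]} variables")
    perm = rng.permutation(oob_X.shape[0])
    Xp = oob_X.copy()
    Xp[:, variable] = Xp[perm, variable]
    return float(np.mean(model.predict(Xp) != np.asarray(oob_y, dtype=np.int64)))


def _score_permutations_batched(
    model: FittedClassifier, oob_X: np.ndarray, oob_y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """All Err0_j(i) for one round, with one predict call per chunk of variables.

    Draws the p permutations in variable order from ``rng`` (identical stream to
    calling :func:`permute_and_score` for i = 0..p-1), then stacks the permuted
    copies so the estimator's per-call overhead is paid once per chunk. Since
    prediction is per-row for every supported classifier, the batched result is
    identical to the per-variable calls.
    """
    m, p = oob_X.shape
    perms = [rng.permutation(m) for _ in range(p)]
    oob_y = np.asarray(oob_y, dtype=np.int64)
    errs = np.empty(p)
    chunk = max(1, _MAX_BATCH_CELLS // max(1, m * p))
    for start in range(0, p, chunk):
        vars_here = range(start, min(start + chunk, p))
        stacked = np.repeat(oob_X[None, :, :], len(vars_here), axis=0)
        for k, i in enumerate(vars_here):
            stacked[k, :, i] = oob_X[perms[i], i]
        preds = model.predict(stacked.reshape(-1, p)).reshape(len(vars_here), m)
        errs[start : start + len(vars_here)] = (preds != oob_y).mean(axis=1)
    return errs


def run_round(
    train_X: np.ndarray,
    train_y: np.ndarray,
    config: ResamplingConfig,
    round_seed,
    *,
    index: int = 0,
    fitter=None,
) -> RoundRecord:
    """One resampling round.

    ``round_seed`` may be an int or a ``numpy.random.SeedSequence``. The round's
    RNG stream is consumed in a fixed, documented order: (1) in-bag tie-break
    and per-class subsampling, (2) the classifier seed, (3) one permutation per
    variable in ascending variable order.

    ``fitter`` (optional) replaces the default base-classifier fit with any
    callable ``(X, y, seed) -> model`` exposing ``predict``; used for test
    doubles and extension.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    rng = np.random.default_rng(round_seed)
    in_bag, oob = _stratified_in_bag(train_y, config.in_bag_fraction, rng)
    clf_seed = int(rng.integers(2**31))
    if fitter is None:
        model = classifiers.fit(config.classifier, train_X[in_bag], train_y[in_bag], seed=clf_seed)
    else:
        model = fitter(train_X[in_bag], train_y[in_bag], clf_seed)
    oob_X, oob_y = train_X[oob], train_y[oob]
    err = float(np.mean(model.predict(oob_X) != oob_y))
    permuted_err = _score_permutations_batched(model, oob_X, oob_y, rng)
    return RoundRecord(index=index, in_bag=in_bag, out_of_bag=oob, err=err, permuted_err=permuted_err)


def round_seed_sequence(master_seed: int, index: int, stream: int = _ROUND_STREAM):
    """Counter-based per-round seed: independent of execution order and worker count."""
    return np.random.SeedSequence(master_seed, spawn_key=(stream, index))


def accumulate_importance(
    train_X: np.ndarray,
    train_y: np.ndarray,
    config: ResamplingConfig,
    *,
    n_jobs: int = 1,
    variable_names: list[str] | None = None,
) -> ImportanceResult:
    """Run r independent rounds and average the permuted-error excesses.

    The result is bit-identical for any ``n_jobs`` because every round's RNG is
    derived from (config.seed, round index) alone.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    seeds = [round_seed_sequence(config.seed, j) for j in range(config.rounds)]
    if n_jobs == 1:
        rounds = [
            run_round(train_X, train_y, config, s, index=j) for j, s in enumerate(seeds)
        ]
    else:
        rounds = Parallel(n_jobs=n_jobs)(
            delayed(run_round)(train_X, train_y, config, s, index=j)
            for j, s in enumerate(seeds)
        )
    diffs = np.stack([rec.permuted_err - rec.err for rec in rounds])
    importance = diffs.mean(axis=0)
    return ImportanceResult(importance, list(rounds), config, variable_names)


def rank_variables(result: ImportanceResult) -> list[tuple[int, float]]:
    """(variable_index, importance) sorted by descending importance, ties by index."""
    imp = np.asarray(result.importance, dtype=np.float64)
    order = np.lexsort((np.arange(imp.size), -imp))
    return [(int(i), float(imp[i])) for i in order]
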