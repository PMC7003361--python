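"""Ensemble of r base classifiers trained on a selected feature.

Each member is fitted on an independent stratified in-bag subsample (same 70%
scheme as the importance phase) of the training samples restricted to the
selected variables, so that even deterministic learners like LDA yield r
distinct members. Aggregation is an unweighted majority vote; the continuous
score of a sample is the fraction of members voting class 1, which thresholded
strictly above 0.5 reproduces the hard vote (ties at exactly 0.5 go to class 0,
the lexicographically smaller original label).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from . import classifiers
from .classifiers import FittedClassifier
from .importance import (
    _ENSEMBLE_STREAM,
    ResamplingConfig,
    _stratified_in_bag,
    round_seed_sequence,
)


@dataclass
class FeatureSelection:
    """An ordered set of distinct variable indices (the selected feature)."""

    variable_indices: tuple[int, ...]
    variable_names: tuple[str, ...] | None = None
    n_variables_total: int | None = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.variable_indices)
        if not idx:
            raise ValueError("selection must be non-empty")
        if len(set(idx)) != len(idx):
            raise ValueError("selection contains duplicate variable indices")
        if any(i < 0 for i in idx):
            raise ValueError("selection indices must be non-negative")
        if self.n_variables_total is not None and any(
            i >= self.n_variables_total for i in idx
        ):
            raise ValueError("selection index out of range for the matrix")
        object.__setattr__(self, "variable_indices", idx)

    def __len__(self) -> int:
        return len(self.variable_indices)


@dataclass
class EnsembleModel:
    """r fitted members over an identical variable subspace + majority vote rule."""

    members: list[FittedClassifier]
    selection: FeatureSelection
    config: ResamplingConfig


def train_ensemble(
    train_X: np.ndarray,
    train_y: np.ndarray,
    selection: FeatureSelection,
    config: ResamplingConfig,
) -> EnsembleModel:
    """Fit config.rounds members, each on a fresh stratified in-bag subsample.

    Member seeds live in their own counter-based stream under config.seed,
    disjoint from the importance rounds' stream.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    if any(i >= train_X.shape[1] for i in selection.variable_indices):
        raise ValueError("selection index out of range for the training matrix")
    sub_X = train_X[:, list(selection.variable_indices)]
    members: list[FittedClassifier] = []
    for j in range(config.rounds):
        rng = np.random.default_rng(round_seed_sequence(config.seed, j, _ENSEMBLE_STREAM))
        in_bag, _ = _stratified_in_bag(train_y, config.in_bag_fraction, rng)
        clf_seed = int(rng.integers(2**31))
        members.append(
            classifiers.fit(config.classifier, sub_X[in_bag], train_y[in_bag], seed=clf_seed)
        )
    sel = FeatureSelection(
        selection.variable_indices,
        selection.variable_names,
        selection.n_variables_total or train_X.shape[1],
    )
    return EnsembleModel(members, sel, config)


def _subspace(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Accept either the full variable space or exactly the selected subspace."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    k = len(model.selection)
    if X.shape[1] == k:
        return X
    total = model.selection.n_variables_total
    if total is not None and X.shape[1] == total:
        return X[:, list(model.selection.variable_indices)]
    raise ValueError(
        f"X has {X.shape[1]} variables; expected {k} (selected subspace)"
        + (f" or {total} (full space)" if total is not None else "")
    )


def ensemble_score(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Per-sample fraction of members voting class 1 (in [0, 1])."""
    Xs = _subspace(model, X)
    votes = np.stack([m.predict(Xs) for m in model.members])
    return votes.mean(axis=0)


def ensemble_predict(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Majority-vote labels; a tied vote (possible for even r) goes to class 0."""
    return (ensemble_score(model, X) > 0.5).astype(np.int64)


def save_model(model: EnsembleModel, path) -> None:
    """Serialize an ensemble (pickle) with its config echo for provenance."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> EnsembleModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, EnsembleModel):
        raise TypeError(f"{path} does not contain an EnsembleModel")
    return model
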