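"""Repeated recursive-feature-elimination (RFE) signature selection.

Each run splits the cohort into disjoint stratified training, validation and
test sets (70/20/10), performs cross-validated RFE on the training set down
to a fixed feature count, trains a grid-tuned multilayer perceptron
classifier (MLPC) on the selected proteins (hyperparameters chosen on the
validation set), and scores it once on the untouched test set. Over many
seeded runs, per-protein selection frequencies are aggregated; the minimal
signature is the set of proteins selected in at least ``min_freq`` runs
(defaults: 100 runs, threshold 85).

An MLP exposes no per-feature importance, so the elimination ranking uses a
multinomial logistic-regression coefficient magnitude averaged over the
cross-validation folds; the MLP is used only for final classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from pharmotype._rng import child_seed

DEFAULT_GRID = (
    {"hidden_layer_sizes": (32,), "alpha": 1e-4},
    {"hidden_layer_sizes": (32,), "alpha": 1e-2},
    {"hidden_layer_sizes": (64,), "alpha": 1e-4},
    {"hidden_layer_sizes": (64,), "alpha": 1e-2},
)


@dataclass
class RfeRunResult:
    run_index: int
    seed: int
    selected: list[str]
    test_accuracy: float
    test_f1_weighted: float
    test_f1_macro: float
    cv_scores: list[float]
    hyperparameters: dict


@dataclass
class SignatureResult:
    frequencies: pd.Series          # per-protein selection count over runs
    signature: list[str]            # frequency >= min_freq
    n_runs: int
    min_freq: int
    runs: list[RfeRunResult] = field(default_factory=list)

    @property
    def score_summary(self) -> pd.DataFrame:
        df = pd.DataFrame([{"accuracy": r.test_accuracy,
                            "f1_weighted": r.test_f1_weighted,
                            "f1_macro": r.test_f1_macro} for r in self.runs])
        return df.agg(["mean", "std"])


def _split_three_way(
    x: np.ndarray, y: np.ndarray, split: tuple[float, float, float], seed: int,
) -> tuple[np.ndarray, ...]:
    f_train, f_val, f_test = split
    total = f_train + f_val + f_test
    if not np.isclose(total, 1.0):
        raise ValueError(f"split fractions must sum to 1, got {split}")
    idx = np.arange(len(y))
    idx_trainval, idx_test = train_test_split(
        idx, test_size=f_test / total, random_state=seed, stratify=y)
    idx_train, idx_val = train_test_split(
        idx_trainval, test_size=f_val / (f_train + f_val),
        random_state=seed + 1, stratify=y[idx_trainval])
    return idx_train, idx_val, idx_test


def _cv_rank_features(
    x: np.ndarray, y: np.ndarray, cv_folds: int, seed: int,
) -> np.ndarray:
    """Mean |coefficient| per feature of a multinomial logistic regression,
    averaged over stratified CV folds and classes."""
    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    importance = np.zeros(x.shape[1])
    for train_idx, _ in folds.split(x, y):
        model = LogisticRegression(max_iter=300, tol=1e-3, random_state=seed)
        model.fit(x[train_idx], y[train_idx])
        importance += np.abs(model.coef_).mean(axis=0)
    return importance / cv_folds


def rfe_run(
    matrix: pd.DataFrame,
    labels: pd.Series,
    run_seed: int,
    n_features: int = 30,
    split: tuple[float, float, float] = (0.7, 0.2, 0.1),
    cv_folds: int = 6,
    step_fraction: float = 0.1,
    grid: tuple[dict, ...] = DEFAULT_GRID,
    run_index: int = 0,
) -> RfeRunResult:
    """One seeded split -> CV-RFE -> grid-tuned MLPC -> test-score run."""
    samples = [s for s in matrix.columns if s in labels.index]
    y_all = labels.reindex(samples).to_numpy()
    classes, counts = np.unique(y_all, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples for stratification")
    x_all = matrix[samples].to_numpy(float).T  # samples x proteins
    proteins = np.asarray(matrix.index)
    n_features = min(n_features, len(proteins))

    idx_train, idx_val, idx_test = _split_three_way(x_all, y_all, split,
                                                    run_seed)
    scaler = StandardScaler().fit(x_all[idx_train])
    x_train = scaler.transform(x_all[idx_train])
    x_val = scaler.transform(x_all[idx_val])
    x_test = scaler.transform(x_all[idx_test])
    y_train, y_val, y_test = (y_all[idx_train], y_all[idx_val],
                              y_all[idx_test])

    # stepwise elimination, dropping step_fraction of remaining features
    keep = np.arange(len(proteins))
    while len(keep) > n_features:
        importance = _cv_rank_features(x_train[:, keep], y_train, cv_folds,
                                       run_seed)
        n_drop = min(max(1, int(step_fraction * len(keep))),
                     len(keep) - n_features)
        keep = keep[np.argsort(importance)[n_drop:]]
    selected = sorted(proteins[keep].tolist())
    sel_idx = np.sort(keep)

    # hyperparameter grid selected on the validation set; the chosen
    # configuration is refit on train+validation before the single test pass
    best, best_score = None, -np.inf
    for params in grid:
        mlp = MLPClassifier(max_iter=800, random_state=run_seed, **params)
        mlp.fit(x_train[:, sel_idx], y_train)
        score = accuracy_score(y_val, mlp.predict(x_val[:, sel_idx]))
        if score > best_score:
            best, best_score = params, score
    mlp = MLPClassifier(max_iter=800, random_state=run_seed, **best)
    x_trval = np.vstack([x_train, x_val])
    mlp.fit(x_trval[:, sel_idx], np.concatenate([y_train, y_val]))
    y_pred = mlp.predict(x_test[:, sel_idx])

    # cross-validation scores of the chosen configuration on the training set
    cv_scores = []
    folds = StratifiedKFold(n_splits=min(cv_folds, int(min(
        np.unique(y_train, return_counts=True)[1]))), shuffle=True,
        random_state=run_seed)
    for tr, te in folds.split(x_train[:, sel_idx], y_train):
        m = MLPClassifier(max_iter=800, random_state=run_seed, **best)
        m.fit(x_train[tr][:, sel_idx], y_train[tr])
        cv_scores.append(float(accuracy_score(
            y_train[te], m.predict(x_train[te][:, sel_idx]))))

    return RfeRunResult(
        run_index=run_index,
        seed=run_seed,
        selected=selected,
        test_accuracy=float(accuracy_score(y_test, y_pred)),
        test_f1_weighted=float(f1_score(y_test, y_pred, average="weighted")),
        test_f1_macro=float(f1_score(y_test, y_pred, average="macro")),
        cv_scores=cv_scores,
        hyperparameters=dict(best),
    )


def select_signature(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_runs: int = 100,
    min_freq: int = 85,
    n_features: int = 30,
    base_seed: int = 0,
    **run_kwargs,
) -> SignatureResult:
    """Aggregate ``n_runs`` seeded RFE runs into selection frequencies and
    the >= ``min_freq``-run signature."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = []
    frequencies = pd.Series(0, index=matrix.index, dtype=int)
    for i in range(n_runs):
        run = rfe_run(matrix, labels, child_seed(base_seed, "rfe", i),
                      n_features=n_features, run_index=i, **run_kwargs)
        runs.append(run)
        frequencies[run.selected] += 1
    signature = sorted(frequencies[frequencies >= min_freq].index.tolist())
    return SignatureResult(frequencies=frequencies, signature=signature,
                           n_runs=n_runs, min_freq=min_freq, runs=runs)
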