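"""Sequential floating forward selection (SFFS) inside nested cross-validation.

The selection criterion J(F) is the mean stratified k-fold cross-validated
accuracy of a classifier restricted to the feature subset F.  SFFS alternates
a forward inclusion step (add the feature that maximizes J) with conditional
backward exclusions (remove the least useful feature whenever doing so beats
the best subset of the smaller size already found — but never the feature
just added), until the requested subset size is reached.  Nested evaluation
runs the whole selection inside each outer training fold, so nothing from an
outer test fold ever influences the subset chosen for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import InvalidParameterError

#: default CV folds for both the selection criterion and the outer loop
DEFAULT_FOLDS = 10


@dataclass
class SelectionState:
    """SFFS bookkeeping: best subset and criterion value per subset size,
    plus an ordered trajectory of inclusion/exclusion moves."""

    n_features: int
    best_subset: dict[int, tuple[int, ...]] = field(default_factory=dict)
    best_j: dict[int, float] = field(default_factory=dict)
    trajectory: list[tuple[str, int, float]] = field(default_factory=list)

    def record(self, subset: tuple[int, ...], j: float, move: str, feat: int) -> None:
        k = len(subset)
        if j > self.best_j.get(k, -np.inf):
            self.best_j[k] = j
            self.best_subset[k] = subset
        self.trajectory.append((move, feat, j))


@dataclass
class SelectionResult:
    """Outcome of one SFFS run: the accuracy curve J(k) for k = 1..k_max,
    the per-size subsets, and the globally best subset (smallest size wins
    ties on the curve)."""

    accuracy_curve: list[float]
    subsets: dict[int, tuple[int, ...]]
    best_subset: tuple[int, ...]
    best_j: float
    classifier: str
    state: SelectionState


def criterion_J(
    X: np.ndarray,
    y: np.ndarray,
    subset,
    classifier: str = "rf",
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    classifier_params: dict | None = None,
) -> float:
    """Mean stratified k-fold CV accuracy of ``classifier`` on the subset's
    columns.  The fold count drops to the minority-class size if needed;
    deterministic for a fixed seed."""
    from .evaluation import fit_predict  # local import: evaluation also imports us

    subset = tuple(subset)
    if not subset:
        raise InvalidParameterError("criterion requires a non-empty feature subset")
    X = np.asarray(X, dtype=float)[:, list(subset)]
    y = np.asarray(y, dtype=int)
    n_folds = min(folds, int(np.min(np.bincount(y))))
    if n_folds < 2:
        raise InvalidParameterError("each class needs >= 2 members for CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        labels, _ = fit_predict(
            X[train], y[train], X[test], classifier, seed=seed,
            classifier_params=classifier_params,
        )
        accs.append(float(np.mean(labels == y[test])))
    return float(np.mean(accs))


def sffs(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "rf",
    k_max: int | None = None,
    seed: int = 0,
    folds: int = DEFAULT_FOLDS,
    floating: bool = True,
    classifier_params: dict | None = None,
) -> SelectionResult:
    """Run SFFS (or plain SFS with ``floating=False``) up to size ``k_max``.

    J is evaluated at most once per distinct subset (cached).  Ties in J are
    broken toward the lowest feature index; the returned ``best_subset`` is
    the subset attaining the maximum of the accuracy curve (smallest size on
    ties).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if k_max is None:
        k_max = n
    if not 1 <= k_max <= n:
        raise InvalidParameterError(f"k_max must be in [1, {n}], got {k_max}")

    cache: dict[frozenset, float] = {}

    def J(subset) -> float:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = criterion_J(
                X, y, sorted(key), classifier, folds, seed, classifier_params
            )
        return cache[key]

    state = SelectionState(n_features=n)
    current: list[int] = []

    while len(current) < k_max:
        # Step 1 — inclusion: the most significant feature outside the subset
        candidates = [f for f in range(n) if f not in current]
        j_add = [J(current + [f]) for f in candidates]
        best = int(np.argmax(j_add))  # argmax returns the first (lowest-index) max
        added = candidates[best]
        current = sorted(current + [added])
        state.record(tuple(current), j_add[best], "add", added)

        # Step 2 — conditional exclusion: drop the least significant feature
        # while doing so strictly beats the best known subset of that size
        first_pass = True
        while floating and len(current) > 2:
            pool = [f for f in current if not (first_pass and f == added)]
            j_del = [J([g for g in current if g != f]) for f in pool]
            best_d = int(np.argmax(j_del))
            k_small = len(current) - 1
            if j_del[best_d] > state.best_j.get(k_small, -np.inf):
                removed = pool[best_d]
                current = [g for g in current if g != removed]
                state.record(tuple(current), j_del[best_d], "remove", removed)
                first_pass = False
            else:
                break

    curve = [state.best_j[k] for k in range(1, k_max + 1)]
    best_k = 1 + int(np.argmax(curve))
    return SelectionResult(
        accuracy_curve=curve,
        subsets=dict(state.best_subset),
        best_subset=state.best_subset[best_k],
        best_j=curve[best_k - 1],
        classifier=classifier,
        state=state,
    )


@dataclass
class OuterFoldResult:
    """One outer fold of the nested scheme: the subset selected on the
    training part and the held-out predictions."""

    fold: int
    subset: tuple[int, ...]
    test_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "rf",
    k_max: int | None = None,
    seed: int = 0,
    outer_folds: int = DEFAULT_FOLDS,
    inner_folds: int = DEFAULT_FOLDS,
    classifier_params: dict | None = None,
) -> list[OuterFoldResult]:
    """Nested stratified CV: SFFS with an inner-CV criterion inside each
    outer training fold, refit on that fold, scored on the outer test fold.

    The outer test data never reaches subset selection or model fitting for
    its own fold, so the pooled outer metrics are leakage-free.
    """
    from .evaluation import fit_predict

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if len(y) < 20 or np.min(counts) < 10:
        raise InvalidParameterError(
            f"nested CV needs >= 20 samples with >= 10 per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    results: list[OuterFoldResult] = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        sel = sffs(
            X[train], y[train], classifier, k_max,
            seed=seed + fold, folds=inner_folds,
            classifier_params=classifier_params,
        )
        cols = list(sel.best_subset)
        labels, scores = fit_predict(
            X[train][:, cols], y[train], X[test][:, cols], classifier,
            seed=seed, classifier_params=classifier_params,
        )
        results.append(OuterFoldResult(
            fold=fold, subset=sel.best_subset, test_index=test,
            y_true=y[test], y_pred=labels, scores=scores,
        ))
    return results
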