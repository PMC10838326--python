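"""Dyad-grouped stratified repeated nested cross-validation around
class-weighted linear support vector machines.

The outer loop (default 11 folds x 10 repetitions) exclusively measures
generalizability; the inner loop (default 10 folds x 1 repetition) does
all hyper-parameter tuning on balanced accuracy.  Both members of a dyad
always share a fold at every level, and per-fold class composition stays
within one dyad of the global class proportions.  Preprocessing
(per-feature z-standardization, then median imputation of missing cells)
is fitted strictly on training rows of whatever loop is running; fitting
on rows that belong to the current test fold raises :class:`LeakageError`.

Base models are L2-regularized L2-loss linear SVMs (the LIBLINEAR
formulation) with inverse-class-frequency hyperplane weighting; the
stacker in :mod:`dyadsync.inference` reuses this engine with a
Gaussian-kernel hinge-loss SVM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, LinearSVC

from .types import CVScheme, FeatureSet, LabelVector, LinearModel, Metrics, ModelResult

__all__ = [
    "LeakageError",
    "DEFAULT_C_GRID",
    "build_cv_scheme",
    "inverse_frequency_weights",
    "train_weighted_linear_svm",
    "nested_cv_run",
    "compute_metrics",
    "Preprocessor",
]

#: 11 log-spaced regularization constants, 2^-6 ... 2^4
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-6, 5))


class LeakageError(RuntimeError):
    """A preprocessing statistic was about to be computed on test rows."""


# ---------------------------------------------------------------------------
# fold construction


def _stratified_group_folds(
    group_ids: Sequence[str],
    group_labels: Dict[str, int],
    n_folds: int,
    rng: np.random.Generator,
) -> Dict[str, int]:
    """Assign dyads to folds, stratified by class via largest remainder.

    Per-class fold counts differ by at most one dyad; the classes' "extra"
    dyads are placed on opposite folds so total fold sizes stay as equal
    as the arithmetic allows.  Ties are broken by a seeded shuffle of the
    dyads within each class before dealing.
    """
    classes = sorted(set(group_labels.values()))
    per_class: Dict[int, List[str]] = {c: [] for c in classes}
    for g in sorted(set(group_ids)):
        per_class[group_labels[g]].append(g)
    for c, dyads in per_class.items():
        if len(dyads) < n_folds:
            raise ValueError(
                f"class {c} has {len(dyads)} dyads, fewer than {n_folds} folds"
            )
    assignment: Dict[str, int] = {}
    for ci, c in enumerate(classes):
        dyads = list(per_class[c])
        rng.shuffle(dyads)
        n = len(dyads)
        base, extra = divmod(n, n_folds)
        counts = [base + 1] * extra + [base] * (n_folds - extra)
        if ci % 2 == 1:
            counts = counts[::-1]  # stack extras on opposite ends per class
        fold = 0
        for f, cnt in enumerate(counts):
            for _ in range(cnt):
                assignment[dyads[fold]] = f
                fold += 1
    return assignment


def build_cv_scheme(
    labels: LabelVector,
    outer_folds: int = 11,
    outer_permutations: int = 10,
    inner_folds: int = 10,
    inner_permutations: int = 1,
    seed: int = 0,
) -> CVScheme:
    """Repeated outer fold assignments honoring dyad grouping and class
    stratification.  Labels must be constant within dyads."""
    group_labels: Dict[str, int] = {}
    for g, y in zip(labels.group_ids, labels.labels):
        if g in group_labels and group_labels[g] != y:
            raise ValueError(f"label disagreement within dyad {g!r}")
        group_labels[g] = int(y)
    assignments = np.empty((outer_permutations, len(labels.labels)), dtype=int)
    for p in range(outer_permutations):
        rng = np.random.default_rng([seed, 0xCF, p])
        fold_of = _stratified_group_folds(labels.group_ids, group_labels, outer_folds, rng)
        assignments[p] = [fold_of[g] for g in labels.group_ids]
    return CVScheme(
        outer_folds,
        outer_permutations,
        inner_folds,
        inner_permutations,
        list(labels.group_ids),
        assignments,
        seed,
    )


# ---------------------------------------------------------------------------
# preprocessing (fitted inside each CV loop)


class Preprocessor:
    """Z-standardization per feature, then median imputation of NaN cells.

    Statistics come exclusively from the rows passed to :meth:`fit`; the
    optional ``forbidden_rows`` instrumentation raises :class:`LeakageError`
    if any fitting row is also a test row.
    """

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.sd_: Optional[np.ndarray] = None
        self.median_: Optional[np.ndarray] = None

    def fit(
        self,
        X: np.ndarray,
        rows: Optional[np.ndarray] = None,
        forbidden_rows: Optional[np.ndarray] = None,
    ) -> "Preprocessor":
        if rows is not None and forbidden_rows is not None:
            overlap = np.intersect1d(rows, forbidden_rows)
            if overlap.size:
                raise LeakageError(
                    f"preprocessing would be fitted on test rows {overlap.tolist()}"
                )
        Xf = X if rows is None else X[rows]
        with np.errstate(invalid="ignore"):
            self.mean_ = np.nanmean(Xf, axis=0)
            self.sd_ = np.nanstd(Xf, axis=0, ddof=0)
        self.mean_ = np.where(np.isfinite(self.mean_), self.mean_, 0.0)
        self.sd_ = np.where(np.isfinite(self.sd_) & (self.sd_ > 0), self.sd_, 1.0)
        Z = (Xf - self.mean_) / self.sd_
        with np.errstate(invalid="ignore"):
            self.median_ = np.nanmedian(Z, axis=0)
        self.median_ = np.where(np.isfinite(self.median_), self.median_, 0.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean_) / self.sd_
        return np.where(np.isfinite(Z), Z, self.median_)


# ---------------------------------------------------------------------------
# estimators


def inverse_frequency_weights(y: np.ndarray) -> Dict[int, float]:
    """Per-class weights proportional to inverse class frequency,
    normalized to mean 1."""
    classes, counts = np.unique(y, return_counts=True)
    raw = {int(c): len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    m = np.mean(list(raw.values()))
    return {c: w / m for c, w in raw.items()}


def train_weighted_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    class_weights: Optional[Dict[int, float]] = None,
    random_state: int = 0,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> LinearModel:
    """L2-regularized L2-loss linear SVM with per-class cost weighting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("X must contain no missing values (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from both classes")
    if class_weights is None:
        class_weights = inverse_frequency_weights(y)
    clf = LinearSVC(
        C=C,
        loss="squared_hinge",
        penalty="l2",
        class_weight=class_weights,
        tol=tol,
        max_iter=max_iter,
        random_state=random_state,
    )
    clf.fit(X, y)
    return LinearModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        class_weights=class_weights,
    )


class _FastLinearSVC:
    """Thin wrapper over the LIBLINEAR L2R-L2loss entry point.

    Identical solver and solution as :class:`sklearn.svm.LinearSVC` with
    the same settings, but skips the per-call input validation — the
    nested engine validates once and fits thousands of times.  Falls back
    to the public estimator if the fast entry point is unavailable.
    """

    def __init__(self, C: float, class_weight: Dict[int, float], random_state: int):
        self.C = C
        self.class_weight = class_weight
        self.random_state = random_state
        self.coef_: Optional[np.ndarray] = None
        self.intercept_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FastLinearSVC":
        try:
            from sklearn.svm._base import _fit_liblinear

            coef, intercept, _ = _fit_liblinear(
                np.ascontiguousarray(X, dtype=np.float64),
                np.asarray(y, dtype=np.float64),
                C=self.C,
                fit_intercept=True,
                intercept_scaling=1.0,
                class_weight=self.class_weight,
                penalty="l2",
                dual=True,
                verbose=0,
                max_iter=5000,
                tol=1e-6,
                random_state=self.random_state,
                multi_class="ovr",
                loss="squared_hinge",
            )
            self.coef_ = np.asarray(coef)
            self.intercept_ = np.atleast_1d(np.asarray(intercept, dtype=float))
        except Exception:
            clf = LinearSVC(
                C=self.C,
                loss="squared_hinge",
                penalty="l2",
                class_weight=self.class_weight,
                tol=1e-6,
                max_iter=20000,
                random_state=self.random_state,
            )
            clf.fit(X, y)
            self.coef_, self.intercept_ = clf.coef_, clf.intercept_
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_.ravel() + self.intercept_[0]


def _linear_factory(params: Dict[str, float], y_train: np.ndarray, random_state: int):
    return _FastLinearSVC(
        C=params["C"],
        class_weight=inverse_frequency_weights(y_train),
        random_state=random_state,
    )


def _rbf_factory(params: Dict[str, float], y_train: np.ndarray, random_state: int):
    return SVC(
        C=params["C"],
        kernel="rbf",
        gamma=params["gamma"],
        class_weight=inverse_frequency_weights(y_train),
        tol=1e-6,
        random_state=random_state,
    )


def _linear_grid(C_grid: Sequence[float]):
    def build(Xtr: np.ndarray) -> List[Dict[str, float]]:
        return [{"C": float(c)} for c in C_grid]

    return build


def median_heuristic_gamma(X: np.ndarray) -> float:
    """1 / median squared pairwise distance — the usual RBF width anchor."""
    n = len(X)
    if n < 2:
        return 1.0
    d2 = []
    for i in range(n):
        diff = X[i + 1 :] - X[i]
        d2.append((diff * diff).sum(axis=1))
    med = float(np.median(np.concatenate(d2)))
    return 1.0 / med if med > 0 else 1.0


def rbf_grid(C_grid: Sequence[float], gamma_factors: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0)):
    def build(Xtr: np.ndarray) -> List[Dict[str, float]]:
        g0 = median_heuristic_gamma(Xtr)
        return [
            {"C": float(c), "gamma": float(g0 * f)} for c in C_grid for f in gamma_factors
        ]

    return build


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(true_labels: np.ndarray, scores: np.ndarray, threshold: float = 0.0) -> Metrics:
    """Confusion-count metrics at a decision threshold plus rank AUC.

    Sensitivity/PPV refer to the positive (+1) class.  With a single-class
    truth the AUC is undefined (NaN) and the balanced accuracy reduces to
    the one defined rate.
    """
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    pred = np.where(s >= threshold, 1, -1)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    if np.isnan(sens):
        bac = spec
    elif np.isnan(spec):
        bac = sens
    else:
        bac = (sens + spec) / 2.0
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    auc = float(roc_auc_score(y, s)) if len(np.unique(y)) == 2 else float("nan")
    return Metrics(sens, spec, bac, auc, ppv, npv)


# ---------------------------------------------------------------------------
# the nested engine


def _fast_bac(y: np.ndarray, scores: np.ndarray) -> float:
    """Balanced accuracy at threshold 0 without the full metric panel."""
    pred = scores >= 0
    pos = y == 1
    rates = []
    if pos.any():
        rates.append(np.mean(pred[pos]))
    if (~pos).any():
        rates.append(np.mean(~pred[~pos]))
    return float(np.mean(rates)) if rates else float("nan")


def _select_params(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str],
    grid: List[Dict[str, float]],
    factory,
    inner_folds: int,
    inner_permutations: int,
    seed: int,
) -> Tuple[Dict[str, float], float]:
    """Pick the grid point with the best mean inner balanced accuracy.

    Preprocessing is refitted on each inner-training split and shared
    across the grid; ties go to the earlier (smaller) grid point.
    """
    group_labels = {g: int(yy) for g, yy in zip(groups, y)}
    splits = []
    for ip in range(inner_permutations):
        rng = np.random.default_rng([seed, 0x1F, ip])
        fold_of = _stratified_group_folds(groups, group_labels, inner_folds, rng)
        folds = np.array([fold_of[g] for g in groups])
        for f in range(inner_folds):
            te = folds == f
            tr = ~te
            prep = Preprocessor().fit(X, rows=np.where(tr)[0], forbidden_rows=np.where(te)[0])
            splits.append(
                (prep.transform(X[tr]), y[tr], prep.transform(X[te]), y[te])
            )
    best_params, best_bac = grid[0], -np.inf
    from sklearn import config_context

    with config_context(assume_finite=True):
        for params in grid:
            bacs = []
            for Xtr, ytr, Xte, yte in splits:
                clf = factory(params, ytr, random_state=seed)
                clf.fit(Xtr, ytr)
                bacs.append(_fast_bac(yte, clf.decision_function(Xte)))
            bac = float(np.nanmean(bacs))
            if bac > best_bac + 1e-12:
                best_params, best_bac = params, bac
    return best_params, best_bac


def nested_cv_run(
    features: Union[FeatureSet, np.ndarray],
    labels: LabelVector,
    scheme: CVScheme,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    estimator: str = "linear",
    grid_builder: Optional[Callable[[np.ndarray], List[Dict[str, float]]]] = None,
    model_name: Optional[str] = None,
) -> ModelResult:
    """Full nested cross-validation for one feature set.

    Per outer fold: preprocessing and hyper-parameter selection happen on
    the outer-training rows only (selection by mean inner balanced
    accuracy; ties go to the first — smallest — grid point), the winning
    model is refitted on the outer training set and scores the held-out
    participants.  Scores are aggregated across outer repetitions by
    mean, thresholded at 0, and the metric panel is computed from the
    aggregated out-of-fold predictions.  Deterministic given ``seed``.
    """
    if isinstance(features, FeatureSet):
        X = features.matrix
        feature_names = list(features.feature_names)
        name = model_name or features.model_name
    else:
        X = np.asarray(features, dtype=float)
        feature_names = None
        name = model_name or "model"
    y = labels.labels
    if X.shape[0] != len(y):
        raise ValueError("feature rows must align with labels")
    groups = np.asarray(labels.group_ids)

    factory = _linear_factory if estimator == "linear" else _rbf_factory
    if grid_builder is None:
        grid_builder = _linear_grid(C_grid) if estimator == "linear" else rbf_grid(C_grid)

    n = len(y)
    scores = np.full((n, scheme.outer_permutations), np.nan)
    fold_weights: List[np.ndarray] = []
    fold_biases: List[float] = []
    chosen: List[Dict[str, float]] = []

    for p in range(scheme.outer_permutations):
        folds = scheme.assignments[p]
        for f in range(scheme.outer_folds):
            te = folds == f
            tr = ~te
            tr_idx, te_idx = np.where(tr)[0], np.where(te)[0]
            grid = grid_builder(np.nan_to_num(X[tr_idx]))
            inner_seed = int(
                np.random.default_rng([seed, 0xAB, p, f]).integers(0, 2**31 - 1)
            )
            best_params, _ = _select_params(
                X[tr_idx],
                y[tr_idx],
                list(groups[tr_idx]),
                grid,
                factory,
                scheme.inner_folds,
                scheme.inner_permutations,
                inner_seed,
            )
            prep = Preprocessor().fit(X, rows=tr_idx, forbidden_rows=te_idx)
            clf = factory(best_params, y[tr_idx], random_state=seed)
            clf.fit(prep.transform(X[tr_idx]), y[tr_idx])
            scores[te_idx, p] = clf.decision_function(prep.transform(X[te_idx]))
            chosen.append(dict(best_params))
            if estimator == "linear":
                fold_weights.append(np.asarray(clf.coef_).ravel().copy())
                fold_biases.append(float(clf.intercept_[0]))

    if np.isnan(scores).any():
        raise RuntimeError("some participants received no out-of-fold score")
    aggregated = scores.mean(axis=1)
    predictions = np.where(aggregated >= 0, 1, -1)
    metrics = compute_metrics(y, aggregated)
    return ModelResult(
        model_name=name,
        participant_ids=list(labels.participant_ids),
        scores=scores,
        aggregated_scores=aggregated,
        predictions=predictions,
        metrics=metrics,
        fold_weights=np.array(fold_weights) if fold_weights else None,
        fold_biases=np.array(fold_biases) if fold_biases else None,
        chosen_params=chosen,
        feature_names=feature_names,
    )
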