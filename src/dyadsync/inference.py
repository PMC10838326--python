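"""Inference and interpretation around trained models.

Dyad-paired permutation tests for classifier significance, stacking of
base-model decision scores, feature-importance maps (cross-validation
ratio and sign-based consistency), decision-score/covariate correlations,
and plain-text report generation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from . import classification
from .types import (
    CVScheme,
    FeatureSet,
    ImportanceMap,
    LabelVector,
    ModelResult,
    PermutationResult,
    StackingInput,
)

__all__ = [
    "permutation_test",
    "permute_dyad_labels",
    "stack_models",
    "stacking_input_from_results",
    "importance_map",
    "correlate_scores_covariates",
    "write_model_result",
    "write_permutation_result",
    "report",
]

#: the two significance levels results are annotated at
ALPHA_LEVELS = (0.05, 0.005)


def permute_dyad_labels(labels: LabelVector, rng: np.random.Generator) -> LabelVector:
    """Shuffle dyad-type labels across dyads; dyad members move together,
    so class sizes are preserved exactly and no dyad is ever split."""
    dyads = sorted(set(labels.group_ids))
    dyad_label = {}
    for g, y in zip(labels.group_ids, labels.labels):
        dyad_label[g] = int(y)
    values = [dyad_label[d] for d in dyads]
    rng.shuffle(values)
    permuted = dict(zip(dyads, values))
    new = np.array([permuted[g] for g in labels.group_ids])
    return LabelVector(
        labels.scheme, new, labels.positive_class, list(labels.participant_ids), list(labels.group_ids)
    )


def permutation_test(
    features: Union[FeatureSet, np.ndarray],
    labels: LabelVector,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    outer_folds: int = 11,
    outer_permutations: int = 10,
    inner_folds: int = 10,
    inner_permutations: int = 1,
    C_grid: Sequence[float] = classification.DEFAULT_C_GRID,
    null_outer_permutations: Optional[int] = None,
    estimator: str = "linear",
) -> PermutationResult:
    """Label-permutation significance test of the nested-CV pipeline.

    Each permutation shuffles dyad labels across dyads (members permuted
    in pairs), rebuilds the fold structure for the permuted labels, reruns
    the full nested cross-validation and records the balanced accuracy.
    The p-value uses the add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` and so never reaches 0.

    ``null_outer_permutations`` optionally reduces the number of outer
    repetitions inside each null rerun (a cost dial for desk-scale runs;
    the observed statistic always uses the full ``outer_permutations``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def run(lbl: LabelVector, n_outer: int, run_seed: int) -> float:
        scheme = classification.build_cv_scheme(
            lbl, outer_folds, n_outer, inner_folds, inner_permutations, seed=run_seed
        )
        res = classification.nested_cv_run(
            features, lbl, scheme, C_grid=C_grid, seed=run_seed, estimator=estimator
        )
        return res.metrics.bac

    observed = run(labels, outer_permutations, seed)
    n_null_outer = null_outer_permutations or outer_permutations
    rng = np.random.default_rng([seed, 0x9E])
    null_bacs = np.empty(n_perm)
    for i in range(n_perm):
        permuted = permute_dyad_labels(labels, rng)
        null_bacs[i] = run(permuted, n_null_outer, int(rng.integers(0, 2**31 - 1)))
    return PermutationResult(observed, null_bacs, n_perm, alpha)


# ---------------------------------------------------------------------------
# stacking


def stacking_input_from_results(results: Sequence[ModelResult]) -> StackingInput:
    """Assemble the participants x models score matrix from base-model
    results (aggregated out-of-fold decision scores only)."""
    if not results:
        raise ValueError("need at least one base model result")
    pids = list(results[0].participant_ids)
    for r in results[1:]:
        if list(r.participant_ids) != pids:
            raise ValueError("base model results have misaligned participants")
    matrix = np.column_stack([r.aggregated_scores for r in results])
    return StackingInput(matrix, [r.model_name for r in results], pids)


def stack_models(
    inputs: StackingInput,
    labels: LabelVector,
    scheme: CVScheme,
    C_grid: Sequence[float] = classification.DEFAULT_C_GRID,
    gamma_factors: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    seed: int = 0,
    model_name: str = "stack",
) -> ModelResult:
    """Gaussian-kernel hinge-loss SVM over base-model decision scores,
    wrapped in the identical dyad-grouped nested CV as the base models.

    The kernel width grid is the median-heuristic gamma of each outer
    training set times ``gamma_factors``; C and gamma are tuned in the
    inner loop on balanced accuracy.
    """
    if list(inputs.participant_ids) != list(labels.participant_ids):
        raise ValueError("stacking inputs misaligned with labels")
    return classification.nested_cv_run(
        inputs.matrix,
        labels,
        scheme,
        C_grid=C_grid,
        seed=seed,
        estimator="rbf",
        grid_builder=classification.rbf_grid(C_grid, gamma_factors),
        model_name=model_name,
    )


# ---------------------------------------------------------------------------
# interpretability


def importance_map(
    per_fold_weights: np.ndarray, feature_names: Optional[Sequence[str]] = None
) -> ImportanceMap:
    """Stability-scaled feature importance across CV models.

    ``cv_ratio`` is the mean weight divided by its standard error across
    models (infinite — surfaced, not hidden — where the SE is 0);
    ``sign_consistency`` is the fraction of models agreeing with the
    majority sign, hence always in [0.5, 1].
    """
    W = np.asarray(per_fold_weights, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a models x features weight matrix with >= 2 models")
    n = W.shape[0]
    mean = W.mean(axis=0)
    se = W.std(axis=0, ddof=1) / np.sqrt(n)
    constant = W.max(axis=0) == W.min(axis=0)  # exact agreement: SE is 0
    se = np.where(constant, 0.0, se)
    mean = np.where(constant, W[0], mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(se > 0, mean / se, np.sign(mean) * np.inf)
    ratio = np.where((se == 0) & (mean == 0), 0.0, ratio)
    pos = (W >= 0).mean(axis=0)
    consistency = np.maximum(pos, 1.0 - pos)
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(W.shape[1])]
    return ImportanceMap(names, mean, ratio, consistency)


def correlate_scores_covariates(
    scores: np.ndarray,
    covariates: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate decision scores with covariates, FDR-adjusted across
    covariates (Benjamini-Hochberg).  Constant covariates yield NaN."""
    s = np.asarray(scores, dtype=float)
    if len(s) != len(covariates):
        raise ValueError("scores and covariates must align")
    rows = []
    pvals = []
    for col in covariates.columns:
        v = covariates[col].to_numpy(float)
        ok = np.isfinite(v) & np.isfinite(s)
        if ok.sum() < 3 or np.std(v[ok]) == 0:
            rows.append({"covariate": col, "r": float("nan"), "p_raw": float("nan")})
            pvals.append(float("nan"))
            continue
        if method == "pearson":
            r, p = sp_stats.pearsonr(s[ok], v[ok])
        elif method == "spearman":
            r, p = sp_stats.spearmanr(s[ok], v[ok])
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"covariate": col, "r": float(r), "p_raw": float(p)})
        pvals.append(float(p))
    out = pd.DataFrame(rows)
    finite = np.isfinite(pvals)
    adj = np.full(len(pvals), np.nan)
    if finite.any():
        adj[finite] = multipletests(np.asarray(pvals)[finite], method="fdr_bh")[1]
    out["p_adjusted"] = adj
    return out


# ---------------------------------------------------------------------------
# artifacts and report


def write_model_result(run_dir: str, result: ModelResult) -> None:
    """Persist one model's scores CSV, metrics JSON and per-fold weights."""
    os.makedirs(run_dir, exist_ok=True)
    long = pd.DataFrame(
        {
            "participant_id": np.repeat(result.participant_ids, result.scores.shape[1]),
            "permutation": np.tile(np.arange(result.scores.shape[1]), len(result.participant_ids)),
            "score": result.scores.ravel(),
        }
    )
    long.to_csv(os.path.join(run_dir, f"scores_{result.model_name}.csv"), index=False)
    with open(os.path.join(run_dir, f"metrics_{result.model_name}.json"), "w") as fh:
        json.dump(result.metrics.as_dict(), fh, indent=2, sort_keys=True)
    if result.fold_weights is not None:
        cols = result.feature_names or [f"f{i}" for i in range(result.fold_weights.shape[1])]
        pd.DataFrame(result.fold_weights, columns=cols).to_csv(
            os.path.join(run_dir, f"weights_{result.model_name}.csv"), index=False
        )


def write_permutation_result(run_dir: str, model_name: str, perm: PermutationResult) -> None:
    os.makedirs(run_dir, exist_ok=True)
    with open(os.path.join(run_dir, f"permutation_{model_name}.json"), "w") as fh:
        json.dump(
            {
                "observed_bac": perm.observed_bac,
                "p_value": perm.p_value,
                "n_perm": perm.n_perm,
                "alpha": perm.alpha,
                "null_bac_mean": float(np.mean(perm.null_bacs)),
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def report(run_dir: str) -> str:
    """Deterministic plain-text summary of a completed run directory.

    One metric row per model (sorted by balanced accuracy), permutation
    p-values annotated at both significance levels, and the top features
    by |cv ratio| where weights were stored.
    """
    if not os.path.isdir(run_dir):
        raise FileNotFoundError(f"run directory {run_dir!r} does not exist")
    metric_files = sorted(
        f for f in os.listdir(run_dir) if f.startswith("metrics_") and f.endswith(".json")
    )
    if not metric_files:
        raise FileNotFoundError(
            f"no artifacts under {run_dir!r}; expected metrics_<model>.json "
            "(plus optional permutation_<model>.json, weights_<model>.csv)"
        )
    rows = []
    for f in metric_files:
        model = f[len("metrics_") : -len(".json")]
        with open(os.path.join(run_dir, f)) as fh:
            m = json.load(fh)
        m["model"] = model
        perm_path = os.path.join(run_dir, f"permutation_{model}.json")
        if os.path.exists(perm_path):
            with open(perm_path) as fh:
                pj = json.load(fh)
            m["perm_p"] = pj["p_value"]
        rows.append(m)
    rows.sort(key=lambda r: (-(r.get("bac") or 0), r["model"]))
    lines = ["model        BAC%   AUC    sens%  spec%  PPV%   NPV%   perm p"]
    for r in rows:
        def pct(x):
            return f"{100 * x:5.1f}" if x is not None and np.isfinite(x) else "   na"

        p = r.get("perm_p")
        if p is None:
            ann = "     -"
        else:
            stars = "".join("*" for a in ALPHA_LEVELS if p <= a)
            ann = f"{p:6.4f}{stars}"
        lines.append(
            f"{r['model']:<12} {pct(r['bac'])}  {r['auc']:.3f}  {pct(r['sensitivity'])}  "
            f"{pct(r['specificity'])}  {pct(r['ppv'])}  {pct(r['npv'])}  {ann}"
        )
    lines.append("")
    lines.append(f"significance annotated at alpha = {ALPHA_LEVELS[0]} (*) and {ALPHA_LEVELS[1]} (**)")
    for f in metric_files:
        model = f[len("metrics_") : -len(".json")]
        wpath = os.path.join(run_dir, f"weights_{model}.csv")
        if os.path.exists(wpath):
            W = pd.read_csv(wpath)
            imp = importance_map(W.to_numpy(float), list(W.columns))
            frame = imp.to_frame()
            finite = frame[np.isfinite(frame["cv_ratio"])]
            top = finite.reindex(
                finite["cv_ratio"].abs().sort_values(ascending=False).index
            ).head(5)
            lines.append("")
            lines.append(f"top features by |cv ratio| — {model}:")
            for name, row in top.iterrows():
                lines.append(
                    f"  {name:<40} cv_ratio {row['cv_ratio']:+7.2f}  "
                    f"sign consistency {row['sign_consistency']:.2f}"
                )
    return "\n".join(lines) + "\n"
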