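"""Nested cross-validation around the scaling → selection → MKL pipeline.

Outer stratified k-fold estimates generalization error; inside each outer
training set the features are scaled, optionally Boruta-selected, and the
MKL hyperparameters (C, kernel kind, kernel parameter) are tuned on an inner
stratified k-fold by mean accuracy. Patients (SZ) are the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .boruta import BorutaConfig, run_boruta
from .features import FeatureTable, feature_category, parse_column
from .mkl import KernelGrouping, KernelSpec, decision_function, train_mkl
from .scaling import fit_scaler, transform

log = logging.getLogger(__name__)

__all__ = [
    "CvConfig",
    "FoldResult",
    "CvReport",
    "stratified_kfold",
    "group_columns",
    "compute_metrics",
    "hyperparameter_candidates",
    "nested_cv",
    "labels_to_signs",
]

POSITIVE_CLASS = "SZ"

_GROUP_ORDERS = {
    "paradigm": ("auditory_p300", "visual_p300", "mmn"),
    "channel": ("Fz", "Cz", "Pz"),
    "feature_type": ("latency_amplitude", "morphological", "frequency"),
}

_KIND_ORDER = {"linear": 0, "polynomial": 1, "gaussian": 2}


@dataclass(frozen=True)
class CvConfig:
    outer_k: int = 10
    inner_k: int = 5
    C_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 5.0, 10.0)
    sigma_grid: tuple[float, ...] = (10.0, 5.0, 1.0, 0.25, 0.5, 0.75)
    degree_grid: tuple[int, ...] = (2, 3)
    kernel_kinds: tuple[str, ...] = ("linear", "polynomial", "gaussian")
    grouping_mode: str = "paradigm"
    feature_selection: bool = True
    p_norm: float = 2.0
    mkl_max_iter: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("fold counts must be >= 2")
        if not (self.C_grid and self.kernel_kinds):
            raise ValueError("grids must be non-empty")
        if self.grouping_mode not in _GROUP_ORDERS:
            raise ValueError(f"unknown grouping mode {self.grouping_mode!r}")


@dataclass
class FoldResult:
    fold: int
    selected_features: list[str]
    selection_fallback: bool
    hyperparameters: dict
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    auc: float
    decision_values: np.ndarray = field(repr=False, default=None)
    true_signs: np.ndarray = field(repr=False, default=None)


@dataclass
class CvReport:
    folds: list[FoldResult]
    mean_acc: float
    mean_sen: float
    mean_spe: float
    mean_auc: float
    pooled_auc: float
    config: CvConfig
    seed: int

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": f.fold,
                    "n_selected": len(f.selected_features),
                    "fallback": f.selection_fallback,
                    **f.hyperparameters,
                    "tp": f.tp,
                    "fp": f.fp,
                    "tn": f.tn,
                    "fn": f.fn,
                    "acc": f.acc,
                    "sen": f.sen,
                    "spe": f.spe,
                    "auc": f.auc,
                }
                for f in self.folds
            ]
        )


def labels_to_signs(labels, positive: str = POSITIVE_CLASS) -> np.ndarray:
    """Map group labels to ±1 with the patient group positive."""
    return np.where(pd.Series(labels).to_numpy() == positive, 1.0, -1.0)


def stratified_kfold(labels, k: int, seed: int) -> np.ndarray:
    """Seeded stratified partition; returns a fold id per row."""
    y = pd.Series(labels).to_numpy()
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, fewer than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def group_columns(columns, mode: str) -> KernelGrouping:
    """Partition feature columns into the M kernels of one grouping mode."""
    if mode not in _GROUP_ORDERS:
        raise ValueError(f"unknown grouping mode {mode!r}")
    order = _GROUP_ORDERS[mode]
    buckets: dict[str, list[str]] = {name: [] for name in order}
    for col in columns:
        if mode == "paradigm":
            key = parse_column(col)[0]
        elif mode == "channel":
            key = parse_column(col)[2]
        else:
            key = feature_category(col)
        buckets[key].append(col)
    groups = []
    for name in order:
        if buckets[name]:
            groups.append((name, tuple(buckets[name])))
        else:
            log.warning("grouping %s: group %r empty after selection, dropped", mode, name)
    return KernelGrouping(groups=tuple(groups))


def compute_metrics(true_signs: np.ndarray, decision_values: np.ndarray) -> dict:
    """Confusion counts, Acc/Sen/Spe and rank (Mann-Whitney) AUC."""
    y = np.asarray(true_signs, dtype=float)
    f = np.asarray(decision_values, dtype=float)
    if y.size == 0:
        raise ValueError("empty fold")
    pred = np.where(f >= 0, 1.0, -1.0)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    acc = (tp + tn) / y.size
    sen = tp / n_pos if n_pos else float("nan")
    spe = tn / n_neg if n_neg else float("nan")
    if n_pos and n_neg:
        ranks = rankdata(f)  # average ranks count ties half
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    else:
        log.warning("single-class fold: AUC undefined")
        auc = float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "acc": acc,
        "sen": sen,
        "spe": spe,
        "auc": float(auc),
    }


def hyperparameter_candidates(config: CvConfig) -> list[dict]:
    """Grid in deterministic tie-break order: smallest C, then
    linear < polynomial < gaussian, then largest σ / smallest q first."""
    cands = []
    for C in sorted(config.C_grid):
        for kind in sorted(config.kernel_kinds, key=lambda k: _KIND_ORDER[k]):
            if kind == "linear":
                cands.append({"C": C, "kind": "linear"})
            elif kind == "polynomial":
                for q in sorted(config.degree_grid):
                    cands.append({"C": C, "kind": "polynomial", "degree": q})
            else:
                for s in sorted(config.sigma_grid, reverse=True):
                    cands.append({"C": C, "kind": "gaussian", "width": s})
    return cands


def _spec_for(cand: dict) -> KernelSpec:
    return KernelSpec(
        kind=cand["kind"],
        degree=cand.get("degree", 2),
        width=cand.get("width", 1.0),
    )


def _fit_and_score(X_train, y_train, X_test, cand, grouping, p_norm, max_iter):
    state = fit_scaler(X_train)
    model = train_mkl(
        transform(X_train, state),
        y_train,
        grouping,
        _spec_for(cand),
        C=cand["C"],
        p_norm=p_norm,
        max_iter=max_iter,
    )
    return decision_function(model, transform(X_test, state)), model


def nested_cv(
    table: FeatureTable,
    cv_config: CvConfig | None = None,
    boruta_config: BorutaConfig | None = None,
) -> CvReport:
    """Outer error-estimation loop around inner selection/tuning loops."""
    cfg = cv_config or CvConfig()
    X, y_signs = table.X, labels_to_signs(table.y)
    folds = stratified_kfold(table.y, cfg.outer_k, cfg.seed)
    seed_seq = np.random.SeedSequence(cfg.seed)
    fold_seeds = seed_seq.spawn(cfg.outer_k)
    results: list[FoldResult] = []
    candidates = hyperparameter_candidates(cfg)

    for fold in range(cfg.outer_k):
        test_mask = folds == fold
        X_tr, X_te = X[~test_mask], X[test_mask]
        y_tr, y_te = y_signs[~test_mask], y_signs[test_mask]

        # feature selection on the outer training set only
        fallback = False
        if cfg.feature_selection:
            bcfg = boruta_config or BorutaConfig()
            bcfg = BorutaConfig(
                max_runs=bcfg.max_runs,
                alpha=bcfg.alpha,
                n_trees=bcfg.n_trees,
                importance=bcfg.importance,
                tentative_policy=bcfg.tentative_policy,
                seed=int(fold_seeds[fold].generate_state(1)[0] % (2**31 - 1)),
            )
            state = fit_scaler(X_tr)
            res = run_boruta(transform(X_tr, state), y_tr, bcfg)
            selected = res.selected
            if not selected:
                log.warning("fold %d: selection accepted nothing, using all features", fold)
                selected = list(X.columns)
                fallback = True
        else:
            selected = list(X.columns)
        grouping = group_columns(selected, cfg.grouping_mode)
        cols = grouping.all_columns()

        # inner tuning by mean accuracy
        inner = stratified_kfold(y_tr, cfg.inner_k, seed=cfg.seed + 1000 + fold)
        best_score, best_cand = -np.inf, None
        for cand in candidates:
            accs = []
            for j in range(cfg.inner_k):
                val = inner == j
                f_val, _ = _fit_and_score(
                    X_tr.loc[~val, cols], y_tr[~val], X_tr.loc[val, cols],
                    cand, grouping, cfg.p_norm, cfg.mkl_max_iter,
                )
                accs.append(compute_metrics(y_tr[val], f_val)["acc"])
            score = float(np.mean(accs))
            if score > best_score:  # candidates are in tie-break order
                best_score, best_cand = score, cand

        # retrain on the full outer training set, score the held-out fold
        f_te, model = _fit_and_score(
            X_tr[cols], y_tr, X_te[cols], best_cand, grouping, cfg.p_norm,
            cfg.mkl_max_iter,
        )
        metrics = compute_metrics(y_te, f_te)
        results.append(
            FoldResult(
                fold=fold,
                selected_features=selected,
                selection_fallback=fallback,
                hyperparameters={**best_cand, "inner_acc": best_score},
                decision_values=f_te,
                true_signs=y_te,
                **metrics,
            )
        )

    def nanmean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    pooled_f = np.concatenate([r.decision_values for r in results])
    pooled_y = np.concatenate([r.true_signs for r in results])
    return CvReport(
        folds=results,
        mean_acc=nanmean([r.acc for r in results]),
        mean_sen=nanmean([r.sen for r in results]),
        mean_spe=nanmean([r.spe for r in results]),
        mean_auc=nanmean([r.auc for r in results]),
        pooled_auc=compute_metrics(pooled_y, pooled_f)["auc"],
        config=cfg,
        seed=cfg.seed,
    )
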