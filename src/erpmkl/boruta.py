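"""All-relevant feature selection with shadow variables.

Each run extends the undecided features with row-permuted copies (shadows),
fits a random forest, and scores a *hit* for every feature whose importance
exceeds the best shadow. Hit counts are tested against Binomial(runs, 1/2)
(two-sided, Bonferroni-corrected over the currently undecided features):
significantly high counts are accepted, significantly low ones rejected.
Shadows of decided features are dropped; the loop stops when nothing is
undecided or the run cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "BorutaConfig",
    "BorutaResult",
    "add_shadows",
    "run_boruta",
    "selection_frequency",
]

SHADOW_PREFIX = "shadow__"


@dataclass(frozen=True)
class BorutaConfig:
    max_runs: int = 500
    alpha: float = 0.01
    n_trees: int = 100
    importance: str = "permutation"  # "permutation" | "impurity"
    tentative_policy: str = "reject"  # "reject" | "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.importance not in ("permutation", "impurity"):
            raise ValueError(f"unknown importance mode {self.importance!r}")
        if self.tentative_policy not in ("reject", "median"):
            raise ValueError(f"unknown tentative policy {self.tentative_policy!r}")


@dataclass
class BorutaResult:
    """Accepted / rejected / tentative partition plus the run history."""

    accepted: list[str]
    rejected: list[str]
    tentative: list[str]
    hits: dict[str, int]
    runs: int
    importance_history: pd.DataFrame = field(repr=False, default=None)

    @property
    def selected(self) -> list[str]:
        """Features to carry forward: the accepted set."""
        return list(self.accepted)

    def to_frame(self) -> pd.DataFrame:
        """Per-feature summary (feature, status, hit count, median importance)."""
        rows = []
        for status, names in (
            ("accepted", self.accepted),
            ("tentative", self.tentative),
            ("rejected", self.rejected),
        ):
            for name in names:
                med = (
                    float(self.importance_history[name].median())
                    if self.importance_history is not None
                    and name in self.importance_history
                    else float("nan")
                )
                rows.append(
                    {
                        "feature": name,
                        "status": status,
                        "hits": self.hits.get(name, 0),
                        "median_importance": med,
                    }
                )
        return pd.DataFrame(rows)


def add_shadows(
    table: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Append an independently row-permuted copy of every column.

    Shadow columns are named ``shadow__<original>``; each is a permutation of
    its original's values, destroying any association with the outcome.
    """
    if table.shape[1] < 1:
        raise ValueError("table has no feature columns")
    rng = rng or np.random.default_rng()
    n = table.shape[0]
    shadows = {
        SHADOW_PREFIX + c: table[c].to_numpy()[rng.permutation(n)]
        for c in table.columns
    }
    return pd.concat([table, pd.DataFrame(shadows, index=table.index)], axis=1)


def _two_sided_binomial_p(hits: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for hit counts under Binomial(n, 1/2)."""
    lo = stats.binom.cdf(hits, n, 0.5)
    hi = stats.binom.sf(hits - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def _permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Out-of-bag mean-decrease-accuracy importance.

    For every tree, its out-of-bag rows are predicted once per column with
    that column permuted; the importance of a column is the mean accuracy
    drop across trees. Permuted copies are stacked so each tree is queried
    a handful of times rather than once per column.
    """
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    def _call(fn, *args):
        # the private helpers grew a sample_weight argument in newer sklearn
        try:
            return fn(*args, None)
        except TypeError:
            return fn(*args)

    n, d = X.shape
    n_boot = _call(_get_n_samples_bootstrap, n, forest.max_samples)
    # sub-trees predict encoded class indices, not the original labels
    y_enc = np.searchsorted(forest.classes_, y).astype(float)
    imp = np.zeros(d)
    used = 0
    for tree in forest.estimators_:
        oob = _call(_generate_unsampled_indices, tree.random_state, n, n_boot)
        if oob.size == 0:
            continue
        used += 1
        # float32 + check_input=False sidesteps per-call validation copies
        Xo = np.ascontiguousarray(X[oob], dtype=np.float32)
        yo = y_enc[oob]
        k = oob.size
        base = float(np.mean(tree.predict(Xo, check_input=False) == yo))
        chunk = max(1, int(1.2e7 / max(k * d, 1)))
        for start in range(0, d, chunk):
            cols = list(range(start, min(start + chunk, d)))
            stacked = np.repeat(Xo[None, :, :], len(cols), axis=0)
            for c, j in enumerate(cols):
                stacked[c, :, j] = Xo[rng.permutation(k), j]
            pred = tree.predict(
                np.ascontiguousarray(stacked.reshape(-1, d)), check_input=False
            ).reshape(len(cols), k)
            acc = np.mean(pred == yo[None, :], axis=1)
            imp[start : start + len(cols)] += base - acc
    if used == 0:
        raise RuntimeError("no tree had out-of-bag rows; cannot score importance")
    return imp / used


def run_boruta(
    table: pd.DataFrame,
    labels,
    config: BorutaConfig | None = None,
) -> BorutaResult:
    """Iterate shadow runs until every feature is accepted or rejected.

    Accepted features stay in the design matrix (they carry signal for the
    forest) but are no longer tested; rejected features and all shadows are
    removed between runs.
    """
    config = config or BorutaConfig()
    y = pd.Series(labels).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least two classes")
    if table.shape[0] < 10:
        raise ValueError("need at least 10 rows")
    if table.shape[0] != len(y):
        raise ValueError("row/label length mismatch")

    rng = np.random.default_rng(config.seed)
    features = list(table.columns)
    undecided = list(features)
    accepted: list[str] = []
    rejected: list[str] = []
    hits = {f: 0 for f in features}
    history: list[dict[str, float]] = []

    run = 0
    while undecided and run < config.max_runs:
        run += 1
        kept = accepted + undecided
        extended = add_shadows(table[undecided], rng)
        design = pd.concat([table[accepted], extended], axis=1)
        cols = list(design.columns)
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        Xd = design.to_numpy()
        forest.fit(Xd, y)
        if config.importance == "impurity":
            imp = forest.feature_importances_
        else:
            imp = _permutation_importance(forest, Xd, y, rng)
        imp_by_col = dict(zip(cols, imp))
        shadow_max = max(
            v for c, v in imp_by_col.items() if c.startswith(SHADOW_PREFIX)
        )
        record: dict[str, float] = {"_shadow_max": shadow_max}
        for f in undecided:
            record[f] = imp_by_col[f]
            if imp_by_col[f] > shadow_max:
                hits[f] += 1
        history.append(record)

        # decision round: Bonferroni over the features still undecided
        m = len(undecided)
        counts = np.array([hits[f] for f in undecided])
        pvals = _two_sided_binomial_p(counts, run)
        significant = pvals < config.alpha / m
        newly_accepted = [
            f for f, s, k in zip(undecided, significant, counts) if s and k > run / 2
        ]
        newly_rejected = [
            f for f, s, k in zip(undecided, significant, counts) if s and k <= run / 2
        ]
        accepted.extend(newly_accepted)
        rejected.extend(newly_rejected)
        undecided = [f for f in undecided if f not in set(newly_accepted + newly_rejected)]

    tentative = list(undecided)
    if tentative and config.tentative_policy == "median":
        hist = pd.DataFrame(history)
        med_shadow = float(hist["_shadow_max"].median())
        promoted = [
            f for f in tentative if float(hist[f].median()) > med_shadow
        ]
        accepted.extend(promoted)
        tentative = [f for f in tentative if f not in set(promoted)]

    hist_frame = pd.DataFrame(history) if history else pd.DataFrame()
    return BorutaResult(
        accepted=accepted,
        rejected=rejected,
        tentative=tentative,
        hits=hits,
        runs=run,
        importance_history=hist_frame,
    )


def selection_frequency(results: list[BorutaResult]) -> dict[str, int]:
    """Per feature, in how many results it was accepted (features seen at
    least once are reported; others count 0 implicitly)."""
    if not results:
        raise ValueError("need at least one result")
    freq: dict[str, int] = {}
    for res in results:
        for f in res.accepted:
            freq[f] = freq.get(f, 0) + 1
    return freq
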