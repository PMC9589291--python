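"""Random-forest models of cold responsiveness, with balancing and grid search.

The classifier distinguishes responsive (positive) from non-responsive
(negative) genes per time point from binary k-mer presence features.  Class
imbalance is handled by SMOTE up-sampling (or majority down-sampling) applied
INSIDE each cross-validation fold to the training portion only, so validation
genes are never resampled.  Hyperparameters come from a fixed 60-combination
grid evaluated by stratified five-fold CV where every gene is validated
exactly once; selection is by mean validation F1 with ties broken toward the
smaller model (fewer trees, then shallower depth).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .simulate import InsufficientExamplesError


@dataclass
class HyperparameterGrid:
    max_depth: tuple = (3, 5, 10)
    max_features: tuple = (0.1, 0.5, "sqrt", "log2", None)
    n_estimators: tuple = (10, 100, 500, 1000)

    def combinations(self) -> list[dict]:
        return [
            {"max_depth": d, "max_features": f, "n_estimators": n}
            for d, f, n in itertools.product(
                self.max_depth, self.max_features, self.n_estimators
            )
        ]


@dataclass
class ModelReport:
    time: str
    direction: str
    best_hyperparameters: dict
    cv_f1_folds: list[float]
    cv_f1: float
    test_f1: float
    feature_names: list[str]
    importances: np.ndarray
    importances_scaled: np.ndarray
    degenerate: bool = False  # no positive predicted on the test set
    extras: dict = field(default_factory=dict)

    def importance_frame(self):
        import pandas as pd

        order = np.argsort(-self.importances, kind="stable")
        return pd.DataFrame(
            {
                "kmer": [self.feature_names[i] for i in order],
                "gini": self.importances[order],
                "scaled_gini": self.importances_scaled[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling: convex interpolation to a random
    one of the k nearest minority neighbours.  Returns a balanced set."""
    rng = rng or np.random.default_rng(0)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientExamplesError("insufficient-examples: one class absent")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority].astype(float)
    k = min(k_neighbors, len(Xm) - 1)
    if k < 1:
        # single minority point: duplicate it
        synth = np.repeat(Xm, n_needed, axis=0)
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, neigh = nn.kneighbors(Xm)  # first neighbour is the point itself
        base = rng.integers(0, len(Xm), size=n_needed)
        pick = neigh[base, rng.integers(1, k + 1, size=n_needed)]
        lam = rng.random((n_needed, 1))
        synth = Xm[base] + lam * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out


def downsample(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly subsample the majority class (without replacement) to balance."""
    rng = rng or np.random.default_rng(0)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientExamplesError("insufficient-examples: one class absent")
    n_min = counts.min()
    keep = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    return X[keep], y[keep]


def balance(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "smote",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    if method == "smote":
        return smote(X, y, rng=rng)
    if method == "downsample":
        return downsample(X, y, rng=rng)
    raise ValueError(f"unknown balancing method {method!r}")


def _fit_forest(X, y, hp: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hp["n_estimators"],
        max_depth=hp["max_depth"],
        max_features=hp["max_features"],
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid | None = None,
    folds: int = 5,
    seed: int = 0,
    balance_method: str = "smote",
) -> tuple[dict, dict]:
    """Stratified k-fold grid search; balancing inside training folds only.

    Returns ``(best_hyperparameters, diagnostics)`` where diagnostics holds
    per-combination fold F1s, the fold assignment (every gene appears in
    exactly one validation fold) and per-fold balanced training sizes.
    """
    grid = grid or HyperparameterGrid()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise InsufficientExamplesError(
            f"insufficient-examples: need >= {folds} genes per class"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    fold_of = np.full(len(y), -1)
    balanced_sizes = []
    balanced_folds = []
    for f, (tr, va) in enumerate(splits):
        fold_of[va] = f
        Xb, yb = balance(X[tr], y[tr], method=balance_method, seed=seed + f)
        balanced_folds.append((Xb, yb, va))
        balanced_sizes.append(len(yb))

    # A forest with the same seed grows the same trees regardless of
    # n_estimators (tree seeds are drawn sequentially), so one max-size fit
    # per (depth, max_features, fold) scores every n_estimators checkpoint
    # exactly as separate fits would.
    n_sizes = sorted(grid.n_estimators)
    per_combo_f1: dict[tuple, list[float]] = {}
    for depth in grid.max_depth:
        for mf in grid.max_features:
            for f, (Xb, yb, va) in enumerate(balanced_folds):
                hp = {"max_depth": depth, "max_features": mf,
                      "n_estimators": n_sizes[-1]}
                clf = _fit_forest(Xb, yb, hp, seed=seed + 1000 * f)
                pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
                Xva = np.ascontiguousarray(X[va], dtype=np.float32)
                # raw per-tree leaf class counts, normalised = predict_proba
                rows = []
                for t in clf.estimators_:
                    v = t.tree_.predict(Xva)
                    v = v.reshape(len(Xva), -1)  # (n, n_classes)
                    rows.append(v[:, pos_col] / v.sum(axis=1))
                proba = np.stack(rows)
                csum = np.cumsum(proba, axis=0)
                for n in n_sizes:
                    pred = (csum[n - 1] / n > 0.5).astype(int)
                    per_combo_f1.setdefault((depth, mf, n), []).append(
                        f1_score(y[va], pred, zero_division=0.0)
                    )
    results = []
    for combo in grid.combinations():
        key = (combo["max_depth"], combo["max_features"], combo["n_estimators"])
        fold_f1 = per_combo_f1[key]
        results.append({"hyperparameters": combo,
                        "fold_f1": fold_f1,
                        "mean_f1": float(np.mean(fold_f1))})
    # best by mean F1; ties broken by fewer trees then shallower depth
    best = max(
        results,
        key=lambda r: (
            r["mean_f1"],
            -r["hyperparameters"]["n_estimators"],
            -r["hyperparameters"]["max_depth"],
        ),
    )
    diagnostics = {
        "results": results,
        "fold_of": fold_of,
        "balanced_train_sizes": balanced_sizes,
        "validation_sizes": [len(va) for _, va in splits],
    }
    return dict(best["hyperparameters"]), diagnostics


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo == 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def train_final_and_test(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    best_hp: dict,
    seed: int = 0,
    feature_names: list[str] | None = None,
    time: str = "",
    direction: str = "up",
    cv_f1_folds: list[float] | None = None,
    balance_method: str = "smote",
) -> ModelReport:
    """Fit the final model on all (balanced) training genes and score the
    held-out test set with F1 on the positive class."""
    Xb, yb = balance(X_train, y_train, method=balance_method, seed=seed)
    clf = _fit_forest(Xb, yb, best_hp, seed=seed)
    pred = clf.predict(X_test)
    test_f1 = float(f1_score(y_test, pred, zero_division=0.0))
    degenerate = bool(pred.sum() == 0)
    imp = clf.feature_importances_
    folds = cv_f1_folds or []
    return ModelReport(
        time=time,
        direction=direction,
        best_hyperparameters=dict(best_hp),
        cv_f1_folds=list(folds),
        cv_f1=float(np.mean(folds)) if folds else float("nan"),
        test_f1=test_f1,
        feature_names=feature_names or [f"f{i}" for i in range(X_train.shape[1])],
        importances=imp,
        importances_scaled=_minmax(imp),
        degenerate=degenerate,
    )


def tfbm_feature_matrix(
    genes,
    library,
    threshold: str | float = "family_p95",
    backgrounds: dict | None = None,
    log_odds_fraction: float = 0.8,
):
    """Binary genes x TFBM presence features.

    A TFBM "matches" a gene when some window of one of its regions scores
    above threshold.  With the default rule a window's one-hot PCC to the
    PWM must exceed the 95th-percentile family background from
    motif_similarity; with a float threshold a log-odds scan cutoff is used
    (score >= fraction of the maximal achievable log-odds).
    """
    from .similarity import family_background, scan_best_pcc, scan_best_logodds

    if not library:
        raise ValueError("no-features: empty TFBM library")
    names = [r.pwm.name or r.tf_name for r in library]
    X = np.zeros((len(genes), len(library)), dtype=np.uint8)
    if threshold == "family_p95":
        if backgrounds is None:
            families = {r.family for r in library}
            backgrounds = {
                fam: family_background(library, fam, scope="within_family")
                for fam in families
            }
        cutoffs = [backgrounds[r.family] for r in library]
    for i, g in enumerate(genes):
        seqs = [s for s in g.regions().values() if s]
        for j, rec in enumerate(library):
            if threshold == "family_p95":
                best = max((scan_best_pcc(s, rec.pwm) for s in seqs), default=-1.0)
                X[i, j] = 1 if best > cutoffs[j] else 0
            else:
                frac = float(threshold) if not isinstance(threshold, str) else log_odds_fraction
                best = max((scan_best_logodds(s, rec.pwm) for s in seqs), default=-np.inf)
                X[i, j] = 1 if best >= frac else 0
    if X.sum() == 0:
        raise ValueError("no-features: no TFBM matches anywhere")
    return X, names


def tfbm_model(
    genes,
    library,
    y: np.ndarray,
    grid: HyperparameterGrid | None = None,
    folds: int = 5,
    seed: int = 0,
    test_mask: np.ndarray | None = None,
    threshold: str | float = "family_p95",
    time: str = "",
    direction: str = "up",
) -> ModelReport:
    """TFBM-presence model: same pipeline as the k-mer models but features
    are PWM matches of a known-motif library."""
    X, names = tfbm_feature_matrix(genes, library, threshold=threshold)
    if test_mask is None:
        rng = np.random.default_rng(seed)
        test_mask = np.zeros(len(y), dtype=bool)
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            test_mask[idx[: max(1, len(idx) // 5)]] = True
    Xtr, ytr = X[~test_mask], y[~test_mask]
    Xte, yte = X[test_mask], y[test_mask]
    best_hp, diag = grid_search_cv(Xtr, ytr, grid=grid, folds=folds, seed=seed)
    best_folds = max(diag["results"], key=lambda r: r["mean_f1"])["fold_f1"]
    return train_final_and_test(
        Xtr, ytr, Xte, yte, best_hp, seed=seed, feature_names=names,
        time=time, direction=direction, cv_f1_folds=best_folds,
    )
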