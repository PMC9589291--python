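"""Minimal pCRE set selection from Gini-importance ramps.

Features are ranked by Gini importance (ties broken lexicographically by
k-mer sequence for stability).  Models are re-evaluated with the top 10,
30, 50, ... features; the F1-vs-feature-count trend is fit with the
Michaelis-Menten curve F1(n) = F1max * n / (K + n), and the minimal feature
count is the first evaluated n where the fitted derivative is near zero, or
where observed F1 first reaches a fraction (default 0.90) of the full-model
F1.  k-mers in the minimal set are the time point's pCREs; comparing
minimal sets across time points categorises each pCRE as general (all time
points), time-point-specific (exactly one) or non-specific (in between).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .models import _fit_forest, balance


@dataclass
class PerformanceRamp:
    points: list[tuple[int, float]]  # (n_features, mean CV F1), n increasing
    full_model_f1: float
    flagged: bool = False  # ramp started at all features (<10 available)


@dataclass
class MMFit:
    f1_max: float
    k_half: float
    rss: float
    converged: bool = True

    def predict(self, n):
        n = np.asarray(n, dtype=float)
        return self.f1_max * n / (self.k_half + n)

    def derivative(self, n):
        n = np.asarray(n, dtype=float)
        return self.f1_max * self.k_half / (self.k_half + n) ** 2


@dataclass
class PCRESet:
    time: str
    direction: str
    kmers: list[str]  # minimal set, in rank order
    scaled_importance: dict[str, float]
    rank: dict[str, int]
    category: dict[str, str]  # general / specific / non_specific


def rank_features(feature_names: list[str], importances: np.ndarray) -> list[str]:
    """Importance-descending order; ties broken by k-mer sequence."""
    order = sorted(range(len(feature_names)),
                   key=lambda i: (-importances[i], feature_names[i]))
    return [feature_names[i] for i in order]


def ramp_counts(n_features: int, start: int = 10, step: int = 20) -> list[int]:
    if n_features < start:
        return [n_features]
    return list(range(start, n_features + 1, step))


def performance_ramp(
    X: np.ndarray,
    y: np.ndarray,
    ranked_features: list[str],
    feature_names: list[str],
    best_hp: dict,
    full_model_f1: float,
    folds: int = 5,
    seed: int = 0,
    balance_method: str = "smote",
) -> PerformanceRamp:
    """CV F1 at increasing feature counts using the selected hyperparameters."""
    col = {f: j for j, f in enumerate(feature_names)}
    counts = ramp_counts(len(ranked_features))
    flagged = len(ranked_features) < 10
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    points = []
    for n in counts:
        cols = [col[f] for f in ranked_features[:n]]
        Xn = X[:, cols]
        f1s = []
        for f, (tr, va) in enumerate(splits):
            Xb, yb = balance(Xn[tr], y[tr], method=balance_method, seed=seed + f)
            clf = _fit_forest(Xb, yb, best_hp, seed=seed + 1000 * f)
            f1s.append(f1_score(y[va], clf.predict(Xn[va]), zero_division=0.0))
        points.append((n, float(np.mean(f1s))))
    return PerformanceRamp(points=points, full_model_f1=full_model_f1,
                           flagged=flagged)


def _mm(n, f1_max, k_half):
    return f1_max * n / (k_half + n)


def fit_mm(ramp: PerformanceRamp) -> MMFit:
    """Nonlinear least squares of the Michaelis-Menten curve to the ramp.

    Initialised at f1_max = max observed F1 and k_half = n at half of that;
    bounds f1_max in (0, 1], k_half > 0.  With exactly two points the two
    parameters interpolate the data exactly.
    """
    n = np.array([p[0] for p in ramp.points], dtype=float)
    f1 = np.array([p[1] for p in ramp.points], dtype=float)
    if len(n) == 1:
        return MMFit(f1_max=float(f1[0]), k_half=1e-9, rss=0.0, converged=False)
    fmax0 = max(float(f1.max()), 1e-6)
    half = fmax0 / 2.0
    above = np.flatnonzero(f1 >= half)
    k0 = float(n[above[0]]) if len(above) else float(n[-1])
    try:
        popt, _ = curve_fit(
            _mm, n, f1, p0=(fmax0, max(k0, 1e-6)),
            bounds=((1e-9, 1e-9), (1.0, np.inf)), maxfev=10000,
        )
        f1_max, k_half = float(popt[0]), float(popt[1])
        rss = float(np.sum((_mm(n, f1_max, k_half) - f1) ** 2))
        return MMFit(f1_max=f1_max, k_half=k_half, rss=rss)
    except RuntimeError:
        return MMFit(f1_max=fmax0, k_half=max(k0, 1e-9), rss=float("inf"),
                     converged=False)


def minimal_feature_count(
    ramp: PerformanceRamp,
    fit: MMFit | None = None,
    rule: str = "derivative",
    eps: float = 1e-4,
    fraction: float = 0.90,
) -> tuple[int, bool]:
    """Smallest evaluated feature count meeting the selection rule.

    derivative rule: fitted slope f1_max*k_half/(k_half+n)^2 < eps;
    fraction rule: observed F1 >= fraction * full-model F1.  Returns
    ``(n, flagged)`` where flagged means the rule was never satisfied and
    the largest evaluated n was returned.  A non-converged fit falls back
    to the fraction rule.
    """
    ns = [p[0] for p in ramp.points]
    if rule == "derivative":
        if fit is None or not fit.converged:
            return minimal_feature_count(ramp, fit, rule="fraction",
                                         eps=eps, fraction=fraction)
        for n in ns:
            if fit.derivative(n) < eps:
                return n, False
        return ns[-1], True
    if rule == "fraction":
        target = fraction * ramp.full_model_f1
        for n, f1 in ramp.points:
            if f1 >= target:
                return n, False
        return ns[-1], True
    raise ValueError(f"unknown rule {rule!r}")


def categorize(minimal_sets: dict[str, list[str]]) -> dict[str, str]:
    """Category of every pCRE from its exact-sequence membership across
    time-point minimal sets: all -> general, one -> specific, else
    non_specific."""
    if len(minimal_sets) < 2:
        raise ValueError("categorize requires minimal sets for >= 2 time points")
    n_tp = len(minimal_sets)
    membership: dict[str, int] = {}
    for kmers in minimal_sets.values():
        for km in set(kmers):
            membership[km] = membership.get(km, 0) + 1
    return {
        km: ("general" if c == n_tp else "specific" if c == 1 else "non_specific")
        for km, c in membership.items()
    }


def build_pcre_sets(
    minimal_sets: dict[str, list[str]],
    reports: dict[str, "object"],
    direction: str = "up",
) -> dict[str, PCRESet]:
    """Assemble per-time-point PCRESets with ranks, scaled importances and
    cross-time-point categories filled in from the model reports."""
    cats = categorize(minimal_sets)
    out = {}
    for tp, kmers in minimal_sets.items():
        rep = reports[tp]
        imp_frame = rep.importance_frame().set_index("kmer")
        out[tp] = PCRESet(
            time=tp,
            direction=direction,
            kmers=list(kmers),
            scaled_importance={k: float(imp_frame.loc[k, "scaled_gini"]) for k in kmers},
            rank={k: int(imp_frame.loc[k, "rank"]) for k in kmers},
            category={k: cats[k] for k in kmers},
        )
    return out
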