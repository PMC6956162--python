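"""Flexibility-age curve fitting, age prediction and group comparison.

Five model families relate the flexibility index to age: linear, quadratic,
logarithmic (a*ln(age)+b), exponential (a*exp(b*age)+c) and Von Bertalanffy
growth (A*(1-exp(-k*(age-t0)))).  Families are fitted by least squares and
compared by AIC = n*ln(RSS/n) + 2*n_params; the winning family's r-squared
is permutation-tested by shuffling ages.  Age prediction uses z-scored
features with a linear support-vector machine (multi-class, one-vs-one) or
support-vector regression with fold-wise hyperparameter selection; group
differences in FI are tested with the two-sided Wilcoxon rank-sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.optimize import curve_fit
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneOut,
    StratifiedKFold,
    KFold,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

FAMILIES = ("linear", "quadratic", "log", "exponential", "von_bertalanffy")


@dataclass
class AgeModelFit:
    family: str
    params: tuple[float, ...]
    aic: float
    rss: float
    r2: float
    perm_p: float | None = None

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return _predict(self.family, self.params, np.asarray(ages, dtype=float))


def _predict(family: str, params: tuple[float, ...], age: np.ndarray) -> np.ndarray:
    if family == "linear":
        a, b = params
        return a * age + b
    if family == "quadratic":
        a, b, c = params
        return a * age**2 + b * age + c
    if family == "log":
        a, b = params
        return a * np.log(age) + b
    if family == "exponential":
        a, b, c = params
        return a * np.exp(b * age) + c
    if family == "von_bertalanffy":
        A, k, t0 = params
        return A * (1.0 - np.exp(-k * (age - t0)))
    raise ValueError(f"unknown family {family!r}")


def _fit_family(family: str, ages: np.ndarray, y: np.ndarray) -> tuple[tuple, float]:
    if family == "linear":
        params = tuple(np.polyfit(ages, y, 1))
    elif family == "quadratic":
        params = tuple(np.polyfit(ages, y, 2))
    elif family == "log":
        params = tuple(np.polyfit(np.log(ages), y, 1))
    elif family == "exponential":
        p0 = (np.ptp(y) if np.ptp(y) > 0 else 1.0, -0.01, float(np.mean(y)))
        popt, _ = curve_fit(
            lambda x, a, b, c: a * np.exp(b * x) + c, ages, y, p0=p0, maxfev=5000
        )
        params = tuple(popt)
    elif family == "von_bertalanffy":
        p0 = (float(np.max(y)) or 1.0, 0.05, float(np.min(ages)) - 1.0)
        popt, _ = curve_fit(
            lambda x, A, k, t0: A * (1.0 - np.exp(-k * (x - t0))),
            ages, y, p0=p0, maxfev=5000,
        )
        params = tuple(popt)
    else:
        raise ValueError(family)
    rss = float(np.sum((y - _predict(family, params, ages)) ** 2))
    return params, rss


def fit_fi_age(
    ages: np.ndarray,
    fi: np.ndarray,
    families: tuple[str, ...] = FAMILIES,
    n_perm: int = 0,
    seed: int = 0,
) -> list[AgeModelFit]:
    """Fit the candidate families and rank them by AIC (best first).

    Non-converging families are excluded with a warning.  With ``n_perm``
    the best family's r-squared is permutation-tested against age shuffles
    (add-one p-value).
    """
    ages = np.asarray(ages, dtype=float)
    fi = np.asarray(fi, dtype=float)
    if len(ages) < 10:
        raise ValueError("need at least 10 participants for curve fitting")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    n = len(ages)
    tss = float(np.sum((fi - fi.mean()) ** 2))
    fits: list[AgeModelFit] = []
    for family in families:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, rss = _fit_family(family, ages, fi)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"family {family!r} failed to converge: {exc}")
            continue
        n_params = len(params)
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_params
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        fits.append(AgeModelFit(family, params, float(aic), rss, float(r2)))
    if not fits:
        raise RuntimeError("no model family converged")
    fits.sort(key=lambda f: f.aic)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        best = fits[0]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(ages)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, rss_p = _fit_family(best.family, perm, fi)
            except (RuntimeError, ValueError):
                continue
            r2_p = 1.0 - rss_p / tss if tss > 0 else 0.0
            if r2_p >= best.r2:
                count += 1
        best.perm_p = (1 + count) / (1 + n_perm)
    return fits


@dataclass
class PredictionReport:
    """Cross-validated prediction outcome (accuracy in %, or R-squared)."""

    scheme: str
    fold_scores: list[float] = field(default_factory=list)
    mean: float = 0.0
    sd: float = 0.0
    degenerate: bool = False


def classify_age_groups(
    features: np.ndarray,
    groups: np.ndarray,
    scheme: str = "5fold",
    n_repeats: int = 100,
    seed: int = 0,
) -> PredictionReport:
    """Multi-class linear SVM on z-scored features; accuracy in percent.

    ``scheme``: "5fold" (stratified, repeated over shuffled splits, mean
    and sd across repeats) or "loo".  Groups too small for the fold count
    raise with a hint to use leave-one-out.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(groups)
    _, counts = np.unique(y, return_counts=True)
    clf = lambda: make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if scheme == "loo":
        correct = []
        for tr, te in LeaveOneOut().split(X):
            model = clf().fit(X[tr], y[tr])
            correct.append(float(model.predict(X[te])[0] == y[te][0]))
        acc = 100.0 * float(np.mean(correct))
        return PredictionReport("loo", [acc], acc, 0.0)
    if scheme == "5fold":
        n_splits = 5
    else:
        raise ValueError(f"unknown scheme {scheme!r} (use '5fold' or 'loo')")
    if n_splits < 2:
        raise ValueError("k-fold cross-validation needs at least 2 folds")
    if counts.min() < n_splits:
        raise ValueError(
            f"smallest group has {counts.min()} member(s), too few for "
            f"{n_splits}-fold stratified CV; consider scheme='loo'"
        )
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=int(rng.integers(2**31)))
        correct = 0
        for tr, te in cv.split(X, y):
            model = clf().fit(X[tr], y[tr])
            correct += int((model.predict(X[te]) == y[te]).sum())
        accs.append(100.0 * correct / len(y))
    return PredictionReport("5fold", accs, float(np.mean(accs)),
                            float(np.std(accs)))


def regress_age(
    features: np.ndarray,
    ages: np.ndarray,
    scheme: str = "5fold",
    n_repeats: int = 10,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    seed: int = 0,
) -> PredictionReport:
    """Linear support-vector regression of age on z-scored features.

    Reports out-of-fold R-squared; the SVR cost parameter is selected per
    outer fold by an inner 3-fold grid search.  Constant features (or worse
    than the mean predictor) are reported as 0 with a degenerate flag.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float)
    if np.allclose(X.std(axis=0), 0):
        return PredictionReport(scheme, [0.0], 0.0, 0.0, degenerate=True)
    rng = np.random.default_rng(seed)
    scores = []
    n_outer = len(y) if scheme == "loo" else 5
    reps = 1 if scheme == "loo" else n_repeats
    for _ in range(reps):
        if scheme == "loo":
            splits = LeaveOneOut().split(X)
        else:
            splits = KFold(n_splits=n_outer, shuffle=True,
                           random_state=int(rng.integers(2**31))).split(X)
        pred = np.empty_like(y)
        for tr, te in splits:
            search = GridSearchCV(
                make_pipeline(StandardScaler(), SVR(kernel="linear")),
                {"svr__C": list(c_grid)}, cv=3, scoring="r2",
            )
            search.fit(X[tr], y[tr])
            pred[te] = search.predict(X[te])
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    mean = float(np.mean(scores))
    degenerate = mean <= 0.0
    if degenerate:
        mean = 0.0
    return PredictionReport(scheme, scores, mean, float(np.std(scores)),
                            degenerate=degenerate)


def compare_groups(fi_a: np.ndarray, fi_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on FI values."""
    fi_a = np.asarray(fi_a, dtype=float)
    fi_b = np.asarray(fi_b, dtype=float)
    if len(fi_a) < 3 or len(fi_b) < 3:
        raise ValueError("each group needs at least 3 members")
    if np.all(fi_a == fi_a[0]) and np.all(fi_b == fi_a[0]):
        warnings.warn("all FI values identical; rank-sum test is degenerate")
        return 0.0, 1.0
    res = sstats.mannwhitneyu(fi_a, fi_b, alternative="two-sided",
                              method="auto")
    return float(res.statistic), float(res.pvalue)
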