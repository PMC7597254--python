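"""Exhaustive ROI-subset search with repeated cross-validated classification.

The two-class task is emotional stress (ES) vs. physical stress (PS), with
one delta-StO2 feature per ROI.  With seven ROIs there are
7 + 21 + 35 + 35 + 21 + 7 + 1 = 127 non-empty feature subsets — small
enough for exhaustive search, so every subset is scored by repeated
stratified 5-fold cross-validation and the best-scoring subset is
reported per feature dimension and globally.

The score is the *classification rate*: per-class recall (predicted-in-
class over actual-in-class), averaged over the two classes and over CV
repeats, reported in percent.  Features are standardised with statistics
fitted on each training fold only.

No multiple-testing correction is applied across the 127 subsets — the
best-subset rate is a selection maximum and optimistically biased as an
estimate of out-of-sample performance; treat it as a ranking, not an
unbiased accuracy.

A two-sample t-test comparing the right-cheek (ROI2) and left-cheek
(ROI4) delta features (over all rows, ES rows and PS rows) checks whether
cheek lateralisation is statistically supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIERS",
    "CVRate",
    "SubsetSearchResult",
    "TTestReport",
    "enumerate_subsets",
    "cv_rate",
    "exhaustive_search",
    "compare_classifiers",
    "cheek_ttest",
]

N_ROIS = 7
ROI_COLUMNS = [f"ROI{i}" for i in range(1, N_ROIS + 1)]
CLASSES = ("ES", "PS")

#: per-dimension subset counts for 7 ROIs: C(7, k)
DIMENSION_COUNTS = (7, 21, 35, 35, 21, 7, 1)


def _make_classifier(spec: str, seed: int):
    """Instantiate a classifier by id.  SVM defaults: C=1, RBF gamma =
    1/(d*var) (scikit-learn's 'scale'); ensemble = bagged trees."""
    rng = int(seed) % (2**31)
    factories = {
        "svm-rbf": lambda: SVC(C=1.0, kernel="rbf", gamma="scale"),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "logreg": lambda: LogisticRegression(max_iter=1000),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "tree": lambda: DecisionTreeClassifier(random_state=rng),
        "ensemble": lambda: BaggingClassifier(
            DecisionTreeClassifier(), n_estimators=50, random_state=rng
        ),
    }
    if spec not in factories:
        raise KeyError(f"unknown classifier {spec!r}; have {sorted(factories)}")
    return factories[spec]()


CLASSIFIERS = ("svm-rbf", "lda", "logreg", "knn", "tree", "ensemble")


def enumerate_subsets(n_rois: int = N_ROIS) -> list[tuple[int, ...]]:
    """All non-empty subsets of ROI indices 1..n, by size then lexicographic."""
    if n_rois < 1:
        raise ValueError(f"need at least one ROI, got {n_rois}")
    out: list[tuple[int, ...]] = []
    for k in range(1, n_rois + 1):
        out.extend(combinations(range(1, n_rois + 1), k))
    return out


@dataclass(frozen=True)
class CVRate:
    """Mean classification rate (percent) with per-class recalls."""

    rate: float
    class_rates: dict[str, float]
    folds: int
    repeats: int
    classifier: str


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    if "stress" not in table.columns:
        raise ValueError("feature table needs a 'stress' label column")
    labels = table["stress"].to_numpy()
    if not set(labels) <= set(CLASSES):
        raise ValueError(f"labels must be in {CLASSES}")
    return labels, table


def cv_rate(
    table: pd.DataFrame,
    subset: tuple[int, ...],
    classifier: str = "svm-rbf",
    folds: int = 5,
    repeats: int = 50,
    seed: int = 0,
) -> CVRate:
    """Repeated stratified k-fold classification rate for one ROI subset.

    Each repeat draws a fresh stratified fold assignment (seeded); within
    each fold, features are standardised with train-fold statistics before
    fitting.  Per-class recalls are pooled over the folds of a repeat and
    averaged over repeats; the headline rate is the mean of the two class
    recalls.  Fold assignments depend only on ``seed``/``repeats``, so
    different classifiers under the same seed see identical splits.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    labels, table = _validate_table(table)
    cols = [f"ROI{i}" for i in subset]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks columns {missing}")
    X = table[cols].to_numpy(dtype=float)
    y = (labels == "PS").astype(int)  # ES=0, PS=1
    n = len(y)
    if n < folds:
        raise ValueError(f"{n} samples cannot be split into {folds} folds")

    ss = np.random.SeedSequence([int(seed) % (2**31), folds, repeats])
    fold_seeds = ss.generate_state(repeats)
    per_class = np.zeros((repeats, 2))
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(fold_seeds[r] % (2**31))
        )
        correct = np.zeros(2)
        total = np.zeros(2)
        for train, test in skf.split(X, y):
            scaler = StandardScaler().fit(X[train])
            clf = _make_classifier(classifier, int(fold_seeds[r] % (2**31)))
            clf.fit(scaler.transform(X[train]), y[train])
            pred = clf.predict(scaler.transform(X[test]))
            for cls in (0, 1):
                sel = y[test] == cls
                total[cls] += sel.sum()
                correct[cls] += (pred[sel] == cls).sum()
        per_class[r] = correct / total
    mean_class = per_class.mean(axis=0) * 100.0
    return CVRate(
        rate=float(mean_class.mean()),
        class_rates={"ES": float(mean_class[0]), "PS": float(mean_class[1])},
        folds=folds, repeats=repeats, classifier=classifier,
    )


@dataclass
class SubsetSearchResult:
    """Outcome of the exhaustive 127-subset search."""

    table: pd.DataFrame          # one row per subset
    folds: int
    repeats: int
    classifier: str

    @property
    def best(self) -> pd.Series:
        """Globally best subset row (highest mean rate; ties resolve to the
        smaller, lexicographically earlier subset via row order)."""
        return self.table.loc[self.table["rate"].idxmax()]

    def dimension_averages(self) -> pd.Series:
        """Mean rate per feature-dimension size."""
        return self.table.groupby("dimension")["rate"].mean()

    def dimension_maxima(self) -> pd.DataFrame:
        """Best rate and argmax subset within each dimension."""
        idx = self.table.groupby("dimension")["rate"].idxmax()
        return self.table.loc[idx, ["dimension", "subset", "rate"]].set_index("dimension")

    def dimension_counts(self) -> pd.Series:
        return self.table.groupby("dimension").size()


def exhaustive_search(
    table: pd.DataFrame,
    classifier: str = "svm-rbf",
    folds: int = 5,
    repeats: int = 50,
    seed: int = 0,
    n_rois: int = N_ROIS,
) -> SubsetSearchResult:
    """Score every non-empty ROI subset by repeated cross-validation.

    Subsets are evaluated in deterministic order under a shared seed, so
    fold assignments are identical across subsets and the search is
    reproducible.  Rows are ordered by size then lexicographically; for a
    full 7-ROI table the per-dimension row counts are (7, 21, 35, 35, 21,
    7, 1).
    """
    rows = []
    for subset in enumerate_subsets(n_rois):
        res = cv_rate(table, subset, classifier, folds, repeats, seed)
        rows.append({
            "subset": subset, "dimension": len(subset), "rate": res.rate,
            "rate_ES": res.class_rates["ES"], "rate_PS": res.class_rates["PS"],
        })
    df = pd.DataFrame(rows)
    return SubsetSearchResult(df, folds=folds, repeats=repeats, classifier=classifier)


def compare_classifiers(
    table: pd.DataFrame,
    subset: tuple[int, ...],
    algorithms: tuple[str, ...] = CLASSIFIERS,
    folds: int = 5,
    repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Apply the same CV protocol to several algorithms on one subset.

    Identical seeds give identical fold assignments across algorithms, so
    differences reflect the classifiers, not the splits.
    """
    rows = []
    for algo in algorithms:
        res = cv_rate(table, subset, algo, folds, repeats, seed)
        rows.append({
            "algorithm": algo, "rate": res.rate,
            "rate_ES": res.class_rates["ES"], "rate_PS": res.class_rates["PS"],
        })
    return pd.DataFrame(rows).set_index("algorithm")


@dataclass(frozen=True)
class TTestReport:
    """Two-sample t-test between right-cheek and left-cheek features."""

    h: int
    p: float
    ci: tuple[float, float]
    t: float

    @classmethod
    def from_samples(cls, a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                     paired: bool = False) -> "TTestReport":
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if min(a.size, b.size) < 2:
            raise ValueError("need at least 2 observations per group")
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
        ci = res.confidence_interval(1 - alpha)
        p = float(res.pvalue)
        return cls(h=int(p < alpha), p=p, ci=(float(ci.low), float(ci.high)),
                   t=float(res.statistic))


def cheek_ttest(
    table: pd.DataFrame, alpha: float = 0.05, paired: bool = False
) -> dict[str, TTestReport]:
    """Compare ROI2 (right cheek) vs ROI4 (left cheek) delta features.

    Three contrasts: all rows, ES rows only, PS rows only.  Default is the
    two-sample equal-variance t-test (a paired variant is available since
    the rows are per-participant); ``h = 1`` iff ``p < alpha``.
    """
    labels, table = _validate_table(table)
    for col in ("ROI2", "ROI4"):
        if col not in table.columns:
            raise KeyError(f"feature table lacks {col}")
    out = {}
    selections = {
        "All": np.ones(len(table), dtype=bool),
        "ES": labels == "ES",
        "PS": labels == "PS",
    }
    for name, sel in selections.items():
        out[name] = TTestReport.from_samples(
            table.loc[sel, "ROI2"].to_numpy(), table.loc[sel, "ROI4"].to_numpy(),
            alpha=alpha, paired=paired,
        )
    return out
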