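"""Linear discriminant analysis with leave-one-out cross-validation and
two-group discriminant-function construction.

The confirmatory step of the workflow: the exploratory species
hypothesis (cluster labels) is tested by equal-prior LDA, with LOOCV
giving a conservative confusion matrix whose overall accuracy carries an
exact (Clopper–Pearson) binomial confidence interval. For pairs of
look-alike species a published-style linear discriminant function is
built on a small trait subset: a Fisher axis scaled to unit pooled
within-group score SD, with the intercept placed so the two group score
means are exactly ±d and classification is by score sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "LDAModel",
    "fit_lda",
    "loocv_confusion",
    "ConfusionMatrix",
    "accuracy_ci",
    "DiscriminantFunction",
    "build_two_group",
    "forward_select",
]


@dataclass
class LDAModel:
    """Gaussian LDA with pooled within-class covariance.

    Equal priors by default: prediction is the class whose mean is
    nearest in pooled Mahalanobis distance.
    """

    classes: list
    means: pd.DataFrame          # class × trait
    pooled_cov: pd.DataFrame     # trait × trait, (n − g) denominator
    priors: np.ndarray
    traits: list[str]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        cov_inv = np.linalg.inv(self.pooled_cov.to_numpy())
        mu = self.means.to_numpy()
        # discriminant score: x'Σ⁻¹μ_k − ½μ_k'Σ⁻¹μ_k + log π_k
        lin = X @ cov_inv @ mu.T
        const = -0.5 * np.einsum("ij,jk,ik->i", mu, cov_inv, mu) + np.log(self.priors)
        scores = lin + const
        idx = np.argmax(scores, axis=1)
        return np.asarray([self.classes[i] for i in idx])


def fit_lda(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    priors: np.ndarray | None = None,
    ridge: float = 0.0,
) -> LDAModel:
    """Fit class means and pooled within-class covariance.

    Needs ≥ 2 classes with ≥ 2 members each and complete cases. A
    singular pooled covariance raises with a hint to reduce traits
    (or pass a small ``ridge`` to regularize the diagonal).
    """
    X = pd.DataFrame(X)
    labels = pd.Series(np.asarray(labels), index=X.index)
    if X.isna().any().any():
        raise ValueError("complete cases required: X contains missing values")
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 members: {small}")
    n, p = X.shape
    g = len(classes)
    means = X.groupby(labels).mean().loc[classes]
    pooled = np.zeros((p, p))
    for c in classes:
        sub = X[labels == c].to_numpy(dtype=float)
        dev = sub - sub.mean(axis=0)
        pooled += dev.T @ dev
    pooled /= n - g
    if ridge:
        pooled += ridge * np.eye(p)
    if np.linalg.cond(pooled) > 1e12:
        raise ValueError(
            "pooled within-class covariance is singular; drop collinear "
            "traits or pass ridge > 0"
        )
    if priors is None:
        priors = np.full(g, 1.0 / g)
    priors = np.asarray(priors, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    return LDAModel(
        classes=classes,
        means=means,
        pooled_cov=pd.DataFrame(pooled, index=X.columns, columns=X.columns),
        priors=priors,
        traits=list(X.columns),
    )


@dataclass
class ConfusionMatrix:
    """True × predicted counts with overall accuracy and its exact CI."""

    counts: pd.DataFrame
    accuracy: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts.to_numpy()))

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ci": [self.ci_lower, self.ci_upper],
            "level": self.level,
            "n": self.total,
            "counts": self.counts.to_dict(),
        }


def accuracy_ci(correct: int, total: int, level: float = 0.95) -> tuple[float, float, float]:
    """Accuracy with its Clopper–Pearson exact binomial interval."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("need 0 ≤ correct ≤ total")
    lo, hi = proportion_confint(correct, total, alpha=1 - level, method="beta")
    return correct / total, float(lo), float(hi)


def confusion_from_counts(counts: pd.DataFrame, level: float = 0.95) -> ConfusionMatrix:
    """Wrap an existing square count table (e.g. a printed one)."""
    mat = counts.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square")
    correct, total = int(np.trace(mat)), int(mat.sum())
    acc, lo, hi = accuracy_ci(correct, total, level)
    return ConfusionMatrix(counts, acc, lo, hi, level)


def loocv_confusion(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    priors: np.ndarray | None = None,
    level: float = 0.95,
) -> ConfusionMatrix:
    """Leave-one-out cross-validated confusion matrix.

    Every row is predicted by a model fit on all other rows (covariance
    refit per fold); classes need ≥ 3 members so no fold drops a class
    below 2.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    labels = pd.Series(np.asarray(labels))
    counts_per_class = labels.value_counts()
    if (counts_per_class < 3).any():
        small = counts_per_class[counts_per_class < 3].index.tolist()
        raise ValueError(f"LOOCV needs every class n ≥ 3; too small: {small}")
    classes = sorted(pd.unique(labels))
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for i in range(len(X)):
        keep = X.index != i
        model = fit_lda(X[keep], labels[keep], priors=priors)
        pred = model.predict(X.iloc[[i]].to_numpy())[0]
        table.loc[labels.iloc[i], pred] += 1
    return confusion_from_counts(table, level)


@dataclass
class DiscriminantFunction:
    """Named linear score separating exactly two groups by sign.

    ``score = Σ coef_t · trait_t + intercept``; the positive side is
    ``positive_species``. Built so the pooled within-group score SD is 1
    and the two group score means are +d and −d (midpoint exactly 0).
    """

    traits: list[str]
    coefficients: np.ndarray
    intercept: float
    positive_species: str
    negative_species: str
    group_stats: dict = field(default_factory=dict)  # species → {mean, min, max, n}

    def score(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = np.asarray(pd.DataFrame(X)[self.traits] if isinstance(X, pd.DataFrame) else X,
                       dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X @ self.coefficients + self.intercept

    def classify(self, X) -> np.ndarray:
        s = self.score(X)
        return np.where(s > 0, self.positive_species, self.negative_species)

    def to_json_dict(self) -> dict:
        return {
            "traits": self.traits,
            "coefficients": dict(zip(self.traits, map(float, self.coefficients))),
            "intercept": self.intercept,
            "positive_species": self.positive_species,
            "negative_species": self.negative_species,
            "group_stats": self.group_stats,
        }


def build_two_group(
    X: pd.DataFrame, labels: pd.Series | np.ndarray, traits: list[str] | None = None
) -> DiscriminantFunction:
    """Fisher discriminant between exactly two groups on a trait subset.

    The axis w ∝ S_pooled⁻¹ (μ₁ − μ₂) is scaled so the pooled
    within-group score SD is 1; the intercept centres the midpoint of
    the group score means at exactly 0, so the means come out as +d and
    −d with 2d the pooled Mahalanobis distance between the groups. The
    first class in sorted order takes the positive side.
    """
    X = pd.DataFrame(X)
    labels = pd.Series(np.asarray(labels), index=X.index)
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if traits is not None:
        X = X[list(traits)]
    for c in classes:
        if (labels == c).sum() < X.shape[1] + 2:
            raise ValueError(f"class {c!r} needs n ≥ n_traits + 2")
    model = fit_lda(X, labels)
    mu = model.means
    diff = (mu.loc[classes[0]] - mu.loc[classes[1]]).to_numpy()
    cov = model.pooled_cov.to_numpy()
    w = np.linalg.solve(cov, diff)
    w = w / np.sqrt(w @ cov @ w)  # unit pooled within-group score SD
    midpoint = 0.5 * (mu.loc[classes[0]].to_numpy() + mu.loc[classes[1]].to_numpy())
    intercept = -float(midpoint @ w)
    fn = DiscriminantFunction(
        traits=list(X.columns),
        coefficients=w,
        intercept=intercept,
        positive_species=str(classes[0]),
        negative_species=str(classes[1]),
    )
    scores = fn.score(X)
    for c in classes:
        s = scores[np.asarray(labels == c)]
        fn.group_stats[str(c)] = {
            "mean": float(s.mean()),
            "min": float(s.min()),
            "max": float(s.max()),
            "n": int(len(s)),
        }
    return fn


def _loocv_sign_success(X: pd.DataFrame, labels: pd.Series, traits: list[str]) -> float:
    """LOOCV success rate of sign classification by build_two_group."""
    hits = 0
    for i in range(len(X)):
        keep = np.arange(len(X)) != i
        try:
            fn = build_two_group(X.iloc[keep], labels.iloc[keep], traits)
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf
        hits += fn.classify(X.iloc[[i]])[0] == labels.iloc[i]
    return hits / len(X)


def forward_select(
    X: pd.DataFrame, labels: pd.Series | np.ndarray, max_traits: int
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection of the trait subset maximizing LOOCV
    sign-classification success of the two-group discriminant.

    Ties break by trait-name order; the full trajectory (subset size,
    trait added, success) is returned. ``max_traits`` beyond the
    available columns is clipped with a warning.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    labels = pd.Series(np.asarray(labels))
    if max_traits > X.shape[1]:
        import warnings

        warnings.warn(f"max_traits clipped to {X.shape[1]}", stacklevel=2)
        max_traits = X.shape[1]
    selected: list[str] = []
    trajectory = []
    if max_traits == 0:
        base = max((labels == c).mean() for c in pd.unique(labels))
        trajectory.append({"n_traits": 0, "added": None, "success": float(base)})
        return selected, pd.DataFrame(trajectory)
    while len(selected) < max_traits:
        best_trait, best_success = None, -np.inf
        for t in sorted(c for c in X.columns if c not in selected):
            success = _loocv_sign_success(X, labels, selected + [t])
            if success > best_success:
                best_trait, best_success = t, success
        if best_trait is None or not np.isfinite(best_success):
            break
        selected.append(best_trait)
        trajectory.append(
            {"n_traits": len(selected), "added": best_trait, "success": float(best_success)}
        )
    return selected, pd.DataFrame(trajectory)
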