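"""Input-pattern analysis of the Monte-Carlo stimuli.

The stimuli matrix (iterations x 16 production rates) is mean-normalized
per column, projected onto its leading principal components, and the
response classes are overlaid on the PC1-PC2 plane.  Separability of the
two classes in that plane is quantified by the cross-validated balanced
accuracy of a linear discriminant (0.5 is chance, 1.0 perfect), with the
silhouette score exported alongside.  Input potency is ranked by the
point-biserial correlation between each raw production rate and the
dichotomous response class,

    r_pb = (M - S) / sigma * sqrt(n1 * n0 / n^2),

with M and S the class means, n1/n0 the class counts and sigma the
population standard deviation — algebraically identical to the Pearson
correlation with 0/1-coded labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .montecarlo import PRO_MOMP, StimuliMatrix

__all__ = [
    "PCAResult",
    "PBCCResult",
    "normalize_stimuli",
    "principal_components",
    "separability_score",
    "point_biserial",
    "rank_inputs",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # iterations x n_components
    loadings: np.ndarray  # variables x n_components, orthonormal columns
    explained_variance_fraction: np.ndarray
    columns: tuple[str, ...]

    @property
    def plane(self) -> np.ndarray:
        """Scores on the first two components."""
        return self.scores[:, :2]


@dataclass
class PBCCResult:
    """Point-biserial coefficients per production rate, sorted descending."""

    table: pd.DataFrame  # index: rate names; columns r_pb, mean_momp, mean_survival, sigma
    n_momp: int
    n_survival: int

    @property
    def r_pb(self) -> pd.Series:
        return self.table["r_pb"]

    def top(self, k: int = 3) -> list[str]:
        return list(self.table.index[:k])


def _as_matrix(stimuli) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(stimuli, StimuliMatrix):
        return stimuli.values, stimuli.columns
    arr = np.atleast_2d(np.asarray(stimuli, dtype=float))
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def normalize_stimuli(stimuli) -> np.ndarray:
    """Divide each column by its mean (output column means are exactly 1)."""
    values, _ = _as_matrix(stimuli)
    means = values.mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("column means must be positive")
    return values / means


def principal_components(normalized: np.ndarray, n_components: int = 2) -> PCAResult:
    """Standard PCA of the mean-centered columns, deterministic sign.

    Component signs follow the largest-|loading|-positive convention.  A
    rank-deficient input yields fewer components (with the reduction
    reflected in the explained-variance vector length).
    """
    if isinstance(normalized, StimuliMatrix):
        columns = normalized.columns
        X = normalize_stimuli(normalized)
    else:
        X = np.atleast_2d(np.asarray(normalized, dtype=float))
        columns = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more rows than columns required")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(
            f"rank-deficient input: retaining {k} of {n_components} components",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # variables x components
    # sign convention: the loading of largest magnitude is positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_,
        columns=columns,
    )


def separability_score(
    scores_2d: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    with_silhouette: bool = False,
):
    """Cross-validated balanced accuracy of a linear separator in the plane."""
    X = np.asarray(scores_2d, dtype=float)
    if X.ndim != 2:
        raise ValueError("2-D scores required")
    y = np.asarray([1 if l == PRO_MOMP else 0 for l in labels]) if np.asarray(
        labels
    ).dtype.kind in "UOS" else np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc = cross_val_score(
        LinearDiscriminantAnalysis(), X, y, cv=cv, scoring="balanced_accuracy"
    )
    score = float(acc.mean())
    if with_silhouette:
        return score, float(silhouette_score(X, y))
    return score


def point_biserial(values: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation with the population (divide-by-n) sigma."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    pos = lab == (PRO_MOMP if lab.dtype.kind in "UOS" else 1)
    n1 = int(pos.sum())
    n0 = int(len(v) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both response classes must be present")
    sigma = v.std()  # population standard deviation
    if sigma == 0:
        raise ValueError("zero variance: point-biserial undefined")
    M = v[pos].mean()
    S = v[~pos].mean()
    n = n1 + n0
    return float((M - S) / sigma * np.sqrt(n1 * n0 / n**2))


def rank_inputs(stimuli, labels: np.ndarray) -> PBCCResult:
    """Point-biserial coefficient per raw production-rate column, descending."""
    values, columns = _as_matrix(stimuli)
    lab = np.asarray(labels)
    pos = lab == (PRO_MOMP if lab.dtype.kind in "UOS" else 1)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("at least two rows per class required")
    rows = []
    for j, name in enumerate(columns):
        v = values[:, j]
        rows.append(
            {
                "rate": name,
                "r_pb": point_biserial(v, pos.astype(int)),
                "mean_momp": float(v[pos].mean()),
                "mean_survival": float(v[~pos].mean()),
                "sigma": float(v.std()),
            }
        )
    table = pd.DataFrame(rows).set_index("rate").sort_values("r_pb", ascending=False)
    return PBCCResult(table=table, n_momp=n1, n_survival=n0)
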