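"""Multivariate analysis of the 13-measure table: scaling, PCA, Fisher LDA.

PCA (on z-scored columns) shows which measures drive the spread of T-cell
responses; Fisher LDA tests how well the four visually-defined signature
classes can be recovered from the measures alone, reporting per-class
resubstitution accuracy, LD scores and 95% confidence ellipses per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["scale_features", "run_pca", "PCAResult", "run_lda",
           "DiscriminantResult", "confidence_ellipse", "Ellipse",
           "load_measures_csv"]


def scale_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (sample SD, n-1); drop zero-variance columns.

    Raises on fewer than two rows; warns naming any dropped column.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two observations to scale")
    sd = matrix.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}")
        matrix = matrix.drop(columns=dead)
        sd = sd.drop(index=dead)
    return (matrix - matrix.mean(axis=0)) / sd


def _orient_columns(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    signs = np.sign(vectors[np.argmax(np.abs(vectors), axis=0),
                            np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


@dataclass
class PCAResult:
    """Principal components of a scaled feature matrix."""

    scores: pd.DataFrame          # n_obs x n_components
    loadings: pd.DataFrame        # n_features x n_components, orthonormal
    variance_explained_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def run_pca(scaled: pd.DataFrame, tol: float = 1e-10) -> PCAResult:
    """PCA by SVD of the (scaled) data matrix.

    Components beyond the numerical rank are omitted; loadings are
    orthonormal with the sign convention that each vector's largest-
    magnitude element is positive; variance-explained percentages sum
    to 100 over the retained components.
    """
    x = scaled.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > tol * s[0])) if s.size else 0
    s, vt = s[:rank], vt[:rank]
    loadings = _orient_columns(vt.T)
    scores = x @ loadings
    var = s ** 2
    names = [f"PC{i+1}" for i in range(rank)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=scaled.index, columns=names),
        loadings=pd.DataFrame(loadings, index=scaled.columns, columns=names),
        variance_explained_pct=100.0 * var / var.sum(),
    )


@dataclass
class DiscriminantResult:
    """Fisher LDA fit: scalings, scores, predictions and accuracies."""

    scalings: pd.DataFrame        # n_features x n_discriminants
    scores: pd.DataFrame          # n_obs x n_discriminants
    predicted: pd.Series
    observed: pd.Series
    confusion: pd.DataFrame       # observed rows x predicted columns
    class_accuracy_pct: pd.Series
    overall_accuracy_pct: float
    class_means: pd.DataFrame
    priors: pd.Series
    regularized: bool = False

    def summary(self) -> str:
        lines = ["Fisher linear discriminant analysis",
                 f"  observations: {len(self.observed)}",
                 f"  discriminants: {self.scalings.shape[1]}",
                 f"  overall accuracy: {self.overall_accuracy_pct:.1f}%"]
        for cls, acc in self.class_accuracy_pct.items():
            lines.append(f"  {cls:>10s}: {acc:.1f}% "
                         f"(n={int((self.observed == cls).sum())})")
        return "\n".join(lines)


def run_lda(scaled: pd.DataFrame, labels, priors: str = "proportional",
            ridge: float = 1e-8) -> DiscriminantResult:
    """Fisher LDA of the scaled measures against the signature labels.

    Solves the between/within generalized eigenproblem (at most
    ``n_classes - 1`` discriminants); class predictions use Gaussian
    posteriors with priors proportional to the observed class frequencies
    (``priors="equal"`` for flat priors). Accuracy is resubstitution. If
    the pooled within-class covariance is singular, a ridge of ``ridge``
    is added (and flagged in the result).
    """
    y = pd.Series(np.asarray(labels), index=scaled.index, name="label")
    counts = y.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >=2 classes with >=2 members each")
    pr = (counts / counts.sum() if priors == "proportional"
          else pd.Series(1.0 / len(counts), index=counts.index))
    x = scaled.to_numpy(dtype=float)

    lda = LinearDiscriminantAnalysis(solver="eigen", priors=pr.sort_index().to_numpy())
    regularized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sps.LinAlgWarning if hasattr(sps, "LinAlgWarning") else Warning)
            lda.fit(x, y.to_numpy())
    except Exception:
        regularized = True
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=ridge,
                                         priors=pr.sort_index().to_numpy())
        lda.fit(x, y.to_numpy())

    n_disc = min(len(counts) - 1, scaled.shape[1])
    scalings = _orient_columns(lda.scalings_[:, :n_disc])
    names = [f"LD{i+1}" for i in range(n_disc)]
    scores = x @ scalings
    pred = pd.Series(lda.predict(x), index=scaled.index, name="predicted")

    classes = list(lda.classes_)
    confusion = (pd.crosstab(y, pred)
                 .reindex(index=classes, columns=classes, fill_value=0))
    class_acc = pd.Series(
        {c: 100.0 * confusion.loc[c, c] / confusion.loc[c].sum()
         if confusion.loc[c].sum() else np.nan for c in classes})
    overall = 100.0 * float((pred.to_numpy() == y.to_numpy()).mean())
    means = (pd.DataFrame(scores, index=scaled.index, columns=names)
             .groupby(y).mean())
    return DiscriminantResult(
        scalings=pd.DataFrame(scalings, index=scaled.columns, columns=names),
        scores=pd.DataFrame(scores, index=scaled.index, columns=names),
        predicted=pred, observed=y, confusion=confusion,
        class_accuracy_pct=class_acc, overall_accuracy_pct=overall,
        class_means=means, priors=pr, regularized=regularized)


@dataclass
class Ellipse:
    """Confidence ellipse of a 2-D point cloud."""

    center: np.ndarray
    semi_axes: np.ndarray   # major, minor
    angle_rad: float        # orientation of the major axis
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])
        p = d @ rot.T
        return (p[:, 0] / self.semi_axes[0]) ** 2 + (p[:, 1] / self.semi_axes[1]) ** 2 <= 1.0


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Gaussian confidence ellipse of 2-D scores at the chi-square(2) quantile.

    Collinear (rank-deficient) clouds yield a flagged degenerate ellipse.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("need >=3 two-dimensional points")
    center = p.mean(axis=0)
    cov = np.cov(p, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = sps.chi2.ppf(level, df=2)
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
    semi = np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=center, semi_axes=semi, angle_rad=angle,
                   degenerate=degenerate)


def load_measures_csv(path, column_map: dict | None = None,
                      label_column: str = "label") -> tuple[pd.DataFrame, pd.Series]:
    """Load an external per-cell measures table (e.g. a published dataset).

    ``column_map`` renames the file's columns to the canonical measure
    names; the label column supplies the visual classification. Returns
    (measures DataFrame, labels Series) with rows holding any NaN measure
    dropped.
    """
    from .features import MEASURE_COLUMNS
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measures file lacks columns {missing}; "
                         "provide a column_map")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    keep = df[MEASURE_COLUMNS].notna().all(axis=1)
    df = df[keep]
    return df[MEASURE_COLUMNS].reset_index(drop=True), \
        df[label_column].reset_index(drop=True)
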