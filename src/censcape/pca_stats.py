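"""PCA of enrichment profiles and between-group statistics.

The enrichment matrix rows are windows, columns are k-mer z-scores.
Columns are centred but not rescaled (entries are already z-scores on a
common scale). Component signs are fixed so that each component's
largest-magnitude loading is positive, which makes scores reproducible
across runs and row orderings.

Group differences on a principal component are summarised with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test, annotated with the
conventional star notation:

    p > 0.05          ns
    0.01   < p <= 0.05    *
    0.001  < p <= 0.01    **
    0.0001 < p <= 0.001   ***
    p <= 0.0001           ****

and with a logistic regression of group membership on the component
scores (likelihood-ratio test against the intercept-only model, with
perfect separation detected and flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.tools.sm_exceptions import PerfectSeparationError

try:  # statsmodels >= 0.13 warns instead of raising in some optimizers
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
except ImportError:  # pragma: no cover
    class PerfectSeparationWarning(UserWarning):
        pass

__all__ = [
    "PcaModel",
    "EllipseSpec",
    "GroupComparison",
    "LogisticModel",
    "EnrichmentPCA",
    "fit_pca",
    "data_ellipse",
    "ellipse_contains",
    "compare_group_means",
    "p_to_stars",
    "logistic_group_model",
]


@dataclass
class PcaModel:
    """Loadings, scores and explained variances of a centred PCA."""

    loadings: np.ndarray  # (n_features, n_components)
    explained_variance: np.ndarray  # per component, ddof=1 scale
    scores: np.ndarray  # (n_rows, n_components)
    column_means: np.ndarray


@dataclass
class EllipseSpec:
    """Normal-theory data ellipse of a 2-D point cloud."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis
    level: float


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p: float
    stars: str


@dataclass
class LogisticModel:
    coefficients: np.ndarray  # per PC-score predictor
    intercept: float
    llr_p: float
    separated: bool


class EnrichmentPCA(TransformerMixin, BaseEstimator):
    """PCA with column centering only and a deterministic sign convention.

    Fitted attributes follow scikit-learn conventions: ``components_``
    (n_components x n_features, sign-fixed), ``loadings_`` (its
    transpose), ``explained_variance_`` (ddof=1 scale, non-increasing),
    ``mean_`` and ``scores_`` (training scores).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        if not np.isfinite(X).all():
            raise ValueError("non-finite entries in input matrix")
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        components = pca.components_.copy()
        for i in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[i])))
            if components[i, j] < 0:
                components[i] *= -1
                scores[:, i] *= -1
        self.components_ = components
        self.loadings_ = components.T
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        self.scores_ = scores
        self.n_features_in_ = X.shape[1]
        return scores

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if not np.isfinite(X).all():
            raise ValueError("non-finite entries in input matrix")
        return (X - self.mean_) @ self.components_.T

    def model(self) -> PcaModel:
        return PcaModel(
            loadings=self.loadings_,
            explained_variance=self.explained_variance_,
            scores=self.scores_,
            column_means=self.mean_,
        )


def fit_pca(matrix, n_components: int | None = None) -> PcaModel:
    """Centred (not rescaled) PCA of an enrichment matrix via SVD."""
    est = EnrichmentPCA(n_components=n_components)
    est.fit(matrix)
    return est.model()


def data_ellipse(points, level: float = 0.95) -> EllipseSpec:
    """Normal-theory ellipse enclosing ``level`` of a bivariate normal cloud.

    Centre is the sample mean; axes and orientation come from the
    eigendecomposition of the sample covariance, scaled by
    sqrt(chi2.ppf(level, df=2)).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a data ellipse")
    if not (0 <= level < 1):
        raise ValueError("level must be in [0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(np.maximum(vals, 0.0) * q)
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle=angle,
        level=level,
    )


def ellipse_contains(spec: EllipseSpec, points) -> np.ndarray:
    """Boolean mask of points inside (or on) the ellipse."""
    pts = np.asarray(points, dtype=np.float64) - np.asarray(spec.center)
    c, s = np.cos(spec.angle), np.sin(spec.angle)
    u = pts @ np.array([[c, -s], [s, c]])  # rotate into ellipse frame
    a, b = spec.semi_axes
    if a == 0 or b == 0:
        return np.zeros(len(pts), dtype=bool)
    return (u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 <= 1.0


def p_to_stars(p: float) -> str:
    """Significance stars for a p-value (ns, *, **, ***, ****)."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def compare_group_means(
    scores_a, scores_b, group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two score samples.

    The exact null distribution is used when both groups have at most
    25 observations and the pooled sample is tie-free; otherwise the
    normal approximation with continuity correction is used.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        statistic=float(res.statistic),
        p=p,
        stars=p_to_stars(p),
    )


def logistic_group_model(scores, is_member) -> LogisticModel:
    """Logistic regression of group membership on PC scores.

    Fits the maximum-likelihood model and reports the likelihood-ratio
    p-value against the intercept-only model. Perfect separation is
    detected and flagged rather than reported as divergent coefficients
    (the flagged fit still carries a valid likelihood-ratio statistic,
    which only understates the evidence).
    """
    X = np.asarray(scores, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(is_member).astype(np.float64)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("membership must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, Xc).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        # refit with a bounded quasi-Newton run: coefficients are not
        # trustworthy (flagged below) but the achieved likelihood still
        # yields a conservative likelihood-ratio statistic
        separated = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, method="bfgs", maxiter=500)
    fitted = res.predict(Xc)
    if fitted[y == 1].min() > fitted[y == 0].max():
        # a threshold on the fitted index separates the classes exactly
        separated = True
    params = np.asarray(res.params, dtype=np.float64)
    return LogisticModel(
        coefficients=params[1:],
        intercept=float(params[0]),
        llr_p=float(res.llr_pvalue),
        separated=separated,
    )
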