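"""Ordination and supervised discrimination of tangent-space shape scores.

Tangent coordinates for k planar landmarks live in 2k dimensions but span a
subspace of rank at most 2k - 4, so a covariance computed on raw coordinates
is always singular.  Discrimination therefore happens on retained principal
components: PCA first, then linear discriminant analysis (canonical variates)
in the reduced space, with Mahalanobis distances and Gaussian posterior
probabilities from the pooled within-group covariance.  Leave-one-out
cross-validation refits the whole reduction + discriminant per fold and
summarizes performance as a confusion matrix with hit ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

__all__ = [
    "PCAModel",
    "LDAModel",
    "ConfusionMatrix",
    "HitRatios",
    "pca_fit",
    "lda_fit",
    "mahalanobis_to_groups",
    "posterior_probabilities",
    "classify",
    "loo_crossvalidate",
    "hit_ratios",
]

_EIGEN_RTOL = 1e-10  # relative eigenvalue cutoff for the auto PC-retention rule
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class PCAModel:
    """Principal components of a score matrix (covariance eigenbasis)."""

    mean_row: np.ndarray        # (p,)
    axes: np.ndarray            # (m, p), orthonormal rows, descending variance
    eigenvalues: np.ndarray     # (m,), non-negative, descending
    percent_variance: np.ndarray
    scores: np.ndarray          # (n, m) projections of the training data

    @property
    def n_components(self) -> int:
        return self.axes.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.mean_row) @ self.axes.T


def pca_fit(scores: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Eigendecomposition of the column-mean-centred covariance.

    Axis signs are fixed (largest-magnitude loading positive) so repeated
    runs give identical score files.
    """
    x = np.asarray(scores, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    m_max = min(n - 1, p)
    m = m_max if n_components is None else min(n_components, m_max)
    axes, eig = vt[:m], eig[:m]
    # deterministic sign: largest-|loading| entry of each axis is positive
    flip = np.sign(axes[np.arange(m), np.argmax(np.abs(axes), axis=1)])
    flip[flip == 0] = 1.0
    axes = axes * flip[:, None]
    total = float(np.sum(s**2 / (n - 1)))
    percent = 100.0 * eig / total if total > 0 else np.zeros(m)
    return PCAModel(
        mean_row=mean,
        axes=axes,
        eigenvalues=eig,
        percent_variance=percent,
        scores=xc @ axes.T,
    )


@dataclass(frozen=True)
class LDAModel:
    """Linear discriminant model fitted on retained principal components.

    ``pc_transform`` maps raw rows into the m-dimensional retained-PC space;
    ``group_means`` and the pooled within-group ``pooled_covariance`` (n - G
    denominator) live there.  ``discriminant_axes`` are the canonical variate
    directions from the generalized eigenproblem of between- vs within-group
    scatter — up to G - 1 of them.
    """

    groups: tuple[str, ...]
    priors: np.ndarray
    pc_transform: PCAModel
    group_means: np.ndarray          # (G, m)
    pooled_covariance: np.ndarray    # (m, m)
    discriminant_axes: np.ndarray    # (m, n_axes) columns
    _cho: tuple = field(repr=False, default=())   # cached Cholesky factor

    @property
    def n_components(self) -> int:
        return self.group_means.shape[1]

    def transform(self, rows: np.ndarray) -> np.ndarray:
        """Raw-space rows -> retained-PC space."""
        return self.pc_transform.transform(rows)

    def discriminant_scores(self, rows: np.ndarray) -> np.ndarray:
        """Raw-space rows -> canonical variate scores."""
        return self.transform(rows) @ self.discriminant_axes


def _resolve_priors(
    priors: str | Mapping[str, float] | Sequence[float],
    groups: tuple[str, ...],
    counts: np.ndarray,
) -> np.ndarray:
    if isinstance(priors, str):
        if priors == "proportional":
            p = counts / counts.sum()
        elif priors == "equal":
            p = np.full(len(groups), 1.0 / len(groups))
        else:
            raise ValueError(f"priors must be 'proportional', 'equal' or explicit, got {priors!r}")
    elif isinstance(priors, Mapping):
        p = np.array([float(priors[g]) for g in groups])
    else:
        p = np.asarray(priors, dtype=float)
        if p.shape != (len(groups),):
            raise ValueError("explicit priors must have one entry per group")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("priors must be non-negative and sum to 1")
    return p / p.sum()


def lda_fit(
    scores: np.ndarray,
    labels: Sequence[str],
    priors: str | Mapping[str, float] | Sequence[float] = "proportional",
    n_components: int | str = "auto",
) -> LDAModel:
    """Fit a linear discriminant on PCA-reduced scores.

    The auto retention rule keeps components whose eigenvalue exceeds
    1e-10 x the largest, capped at min(p, n - G - 1); this guards against
    the structural rank deficiency of tangent shape coordinates.  Pass an
    integer to retain a fixed number of components instead.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n, p = x.shape
    if labels.shape[0] != n:
        raise ValueError("labels length must match number of rows")
    groups, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    for grp, cnt in zip(groups, counts):
        if cnt < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 members")

    cap = min(p, n - g - 1)
    if cap < 1:
        raise ValueError("too few rows relative to groups for any retained component")
    pca = pca_fit(x)
    if n_components == "auto":
        keep = np.flatnonzero(pca.eigenvalues > _EIGEN_RTOL * pca.eigenvalues[0])
        m = min(len(keep), cap)
    else:
        m = int(n_components)
        if not 1 <= m <= min(p, n - 1):
            raise ValueError(f"n_components must be in [1, {min(p, n - 1)}]")
    pca = PCAModel(
        mean_row=pca.mean_row,
        axes=pca.axes[:m],
        eigenvalues=pca.eigenvalues[:m],
        percent_variance=pca.percent_variance[:m],
        scores=pca.scores[:, :m],
    )
    z = pca.scores  # (n, m), centred

    means = np.vstack([z[inverse == i].mean(axis=0) for i in range(g)])
    sw = np.zeros((m, m))
    for i in range(g):
        d = z[inverse == i] - means[i]
        sw += d.T @ d
    pooled = sw / (n - g)

    eigvals = linalg.eigvalsh(pooled)
    if eigvals[0] <= _EIGEN_RTOL * max(eigvals[-1], 0.0):
        raise ValueError(
            "pooled within-group covariance is singular (not positive-definite) "
            "after reduction; retain fewer components (smaller n_components)"
        )
    cho = linalg.cho_factor(pooled, lower=True)

    # canonical variates: between-group scatter against within-group scatter
    grand = z.mean(axis=0)
    sb = np.zeros((m, m))
    for i in range(g):
        d = (means[i] - grand)[:, None]
        sb += counts[i] * (d @ d.T)
    n_axes = min(g - 1, m)
    vals, vecs = linalg.eigh(sb, sw)
    order = np.argsort(vals)[::-1][:n_axes]
    axes = vecs[:, order]
    axes = axes / np.linalg.norm(axes, axis=0, keepdims=True)

    return LDAModel(
        groups=tuple(groups.tolist()),
        priors=_resolve_priors(priors, tuple(groups.tolist()), counts),
        pc_transform=pca,
        group_means=means,
        pooled_covariance=pooled,
        discriminant_axes=axes,
        _cho=cho,
    )


def _chol(model: LDAModel):
    if model._cho:
        return model._cho
    return linalg.cho_factor(model.pooled_covariance, lower=True)


def mahalanobis_to_groups(model: LDAModel, row: np.ndarray) -> np.ndarray:
    """Mahalanobis distance from one reduced-space row to every group mean."""
    row = np.asarray(row, dtype=float)
    if row.shape != (model.n_components,):
        raise ValueError(f"row must have dimension {model.n_components}, got {row.shape}")
    diffs = model.group_means - row
    solved = linalg.cho_solve(_chol(model), diffs.T)
    return np.sqrt(np.einsum("ij,ji->i", diffs, solved))


def posterior_probabilities(model: LDAModel, row: np.ndarray) -> np.ndarray:
    """Group-membership posteriors: prior_g * exp(-MD_g^2 / 2), normalized.

    Computed in log space with a log-sum-exp guard so that a row far from
    every group still yields a proper probability vector.
    """
    md = mahalanobis_to_groups(model, row)
    with np.errstate(divide="ignore"):
        logp = np.log(model.priors) - 0.5 * md**2
    return np.exp(logp - logsumexp(logp))


def classify(model: LDAModel, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign reduced-space rows to the highest-posterior group.

    Ties (posteriors equal to relative tolerance 1e-12) go to the first
    group in label order and are flagged.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    labels = np.empty(len(rows), dtype=object)
    ties = np.zeros(len(rows), dtype=bool)
    for i, row in enumerate(rows):
        pp = posterior_probabilities(model, row)
        best = int(np.argmax(pp))
        tied = np.flatnonzero(pp >= pp[best] * (1.0 - _TIE_RTOL))
        if len(tied) > 1:
            best = int(tied[0])
            ties[i] = True
        labels[i] = model.groups[best]
    return labels, ties


# ---------------------------------------------------------------------------
# Cross-validation and hit ratios


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-validation counts: rows = true group, columns = predicted group."""

    groups: tuple[str, ...]
    counts: np.ndarray  # (G, G) integer

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.groups), len(self.groups)):
            raise ValueError("counts must be square with one row/column per group")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_misclassified(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    @property
    def per_group_hit_ratio(self) -> np.ndarray:
        """Per-group percent correct, full precision; NaN for an empty row."""
        row_sums = self.counts.sum(axis=1)
        diag = np.diag(self.counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_sums > 0, 100.0 * diag / row_sums, np.nan)

    @property
    def overall_hit_ratio(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.n_total

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.groups), columns=list(self.groups))
        df["HR (%)"] = pd.Series(np.round(self.per_group_hit_ratio), index=df.index).astype("Int64")
        return df


@dataclass(frozen=True)
class HitRatios:
    """Hit ratios in display form: per-group integers, overall at 2 decimals."""

    per_group: dict[str, float]          # full precision
    per_group_display: dict[str, int]    # rounded to nearest integer
    overall: float                       # rounded to 2 decimals
    n_misclassified: int
    empty_groups: tuple[str, ...]        # groups with no specimens (undefined HR)


def hit_ratios(confusion: ConfusionMatrix) -> HitRatios:
    """Per-group and overall hit ratios from a confusion matrix."""
    ratios = confusion.per_group_hit_ratio
    empty = tuple(g for g, r in zip(confusion.groups, ratios) if np.isnan(r))
    per_group = {g: float(r) for g, r in zip(confusion.groups, ratios) if not np.isnan(r)}
    display = {g: int(round(r)) for g, r in per_group.items()}
    return HitRatios(
        per_group=per_group,
        per_group_display=display,
        overall=round(confusion.overall_hit_ratio, 2),
        n_misclassified=confusion.n_misclassified,
        empty_groups=empty,
    )


def loo_crossvalidate(
    scores: np.ndarray,
    labels: Sequence[str],
    priors: str | Mapping[str, float] | Sequence[float] = "proportional",
    n_components: int | str = "auto",
) -> ConfusionMatrix:
    """Leave-one-out cross-validated classification.

    Each fold refits the PCA reduction and the discriminant on the remaining
    n - 1 rows and classifies the held-out row by highest posterior.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = tuple(np.unique(labels).tolist())
    idx = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    mask = np.ones(len(x), dtype=bool)
    for i in range(len(x)):
        mask[i] = False
        model = lda_fit(x[mask], labels[mask], priors=priors, n_components=n_components)
        pred, _ = classify(model, model.transform(x[i]))
        mask[i] = True
        counts[idx[labels[i]], idx[pred[0]]] += 1
    return ConfusionMatrix(groups=groups, counts=counts)
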