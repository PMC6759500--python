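"""Group-level inference: F tests with sphericity correction and canonical
discriminant analysis of band-condition identification profiles.

The repeated-measures ANOVA treats band condition as a single within-subject
factor and applies the Greenhouse–Geisser correction: the sphericity index
ε, estimated from the double-centered condition covariance, multiplies both
degrees of freedom before the p-value is computed (ε = 1 under perfect
sphericity, floor 1/(k−1)).  Fractional dfs in reported F tables are the
footprint of this correction.

Canonical discriminant analysis solves the generalized eigenproblem of the
between-group scatter against the within-group scatter,
``B v = λ W v``, yielding up to min(groups − 1, variables) functions that
maximally separate the groups.  Raw coefficients are scaled to unit pooled
within-group variance of the scores; standardized coefficients multiply the
raw ones by pooled within-group standard deviations; structure coefficients
are the plain correlations of each variable with each canonical score.
Axis signs are arbitrary and fixed so each function's largest-magnitude
standardized coefficient is positive.

No multiple-testing correction is applied anywhere: p-values are raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

logger = logging.getLogger("emochimera")


class MissingDataError(ValueError):
    """Raised when a repeated-measures layout has incomplete cases."""


class SingularScatterError(np.linalg.LinAlgError):
    """Within-group scatter is singular; supply ridge > 0 to regularize."""


@dataclass(frozen=True)
class AnovaResult:
    """An F test with (possibly fractional, ε-corrected) degrees of freedom."""

    df_num: float
    df_den: float
    f_value: float
    p_value: float
    epsilon: float = 1.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"F({self.df_num:.4g}, {self.df_den:.4g}) = {self.f_value:.4g}, "
                f"p = {self.p_value:.4g}, GG eps = {self.epsilon:.4g}")


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser ε from a participant × condition matrix.

    ε = (Σ λ_i)² / ((k−1) Σ λ_i²) with λ_i the eigenvalues of the
    double-centered condition covariance; computed via traces.  Bounded in
    [1/(k−1), 1]; equals 1 exactly when k = 2.
    """
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    if k == 2:
        return 1.0
    s = np.cov(data, rowvar=False)
    # double-center
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s_dc) ** 2
    den = (k - 1) * np.sum(s_dc ** 2)
    eps = float(num / den) if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(data) -> AnovaResult:
    """One-within-factor repeated-measures ANOVA with GG correction.

    ``data`` is a complete participant × condition matrix.  The F statistic
    partitions total variability into subject, condition and residual sums
    of squares: F = MS_condition / MS_residual with dfs (k−1), (n−1)(k−1),
    both multiplied by the Greenhouse–Geisser ε for the p-value.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise MissingDataError("need a 2-D matrix with >= 2 participants and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise MissingDataError("incomplete cases: matrix contains non-finite entries")
    n, k = x.shape
    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_cond
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    f = ms_cond / ms_err if ms_err > 0 else np.inf
    eps = gg_epsilon(x)
    df_num, df_den = eps * df_cond, eps * df_err
    p = float(scipy.stats.f.sf(f, df_num, df_den))
    return AnovaResult(df_num=df_num, df_den=df_den, f_value=float(f), p_value=p, epsilon=eps)


def oneway_anova(groups) -> AnovaResult:
    """Standard between/within one-way ANOVA over a list of samples."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise MissingDataError("need >= 2 groups with >= 2 observations each")
    f, p = scipy.stats.f_oneway(*samples)
    n = sum(s.size for s in samples)
    return AnovaResult(df_num=len(samples) - 1, df_den=n - len(samples),
                       f_value=float(f), p_value=float(p), epsilon=1.0)


@dataclass(frozen=True)
class CanonicalResult:
    """Canonical discriminant solution.

    ``eigenvalues`` descending; coefficient matrices are variable × function;
    ``scores`` is observation × function; ``group_labels`` records the
    distinct groups in sorted order.
    """

    eigenvalues: np.ndarray
    raw_coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    structure_coefficients: np.ndarray
    scores: np.ndarray
    group_labels: tuple = field(default=())

    @property
    def n_functions(self) -> int:
        return self.eigenvalues.size


def canonical_discriminant(X, groups, ridge: float = 0.0) -> CanonicalResult:
    """Canonical discriminant analysis of ``X`` (n × p) against group labels.

    Solves ``B v = λ W v`` for the between- and within-group scatter
    matrices and keeps the top min(g − 1, p) functions.  Raw coefficients
    are normalized so canonical scores have unit pooled within-group
    variance.  A singular within scatter raises ``SingularScatterError``
    unless ``ridge`` adds a diagonal ε·I regularizer.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(groups)
    if X.ndim != 2 or labels.shape[0] != X.shape[0]:
        raise ValueError("X must be n x p with one group label per row")
    uniq = np.unique(labels)
    g, (n, p) = uniq.size, X.shape
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= p:
        logger.warning("only %d observations for %d variables; solution may be unstable", n, p)

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in uniq:
        sub = X[labels == lab]
        m = sub.mean(axis=0)
        dev = sub - m
        W += dev.T @ dev
        d = (m - grand)[:, None]
        B += sub.shape[0] * (d @ d.T)
    if ridge > 0:
        W = W + ridge * np.eye(p)
    else:
        w_eigs = np.linalg.eigvalsh(W)
        if w_eigs[0] <= 1e-10 * max(w_eigs[-1], 1.0):
            raise SingularScatterError(
                "within-group scatter is singular; pass ridge > 0 to regularize"
            )
    try:
        # generalized symmetric-definite eigenproblem: B v = lambda W v
        eigvals, eigvecs = scipy.linalg.eigh(B, W)
    except scipy.linalg.LinAlgError as exc:
        raise SingularScatterError(
            "within-group scatter is singular; pass ridge > 0 to regularize"
        ) from exc
    order = np.argsort(eigvals)[::-1][: min(g - 1, p)]
    eigvals = np.clip(eigvals[order], 0.0, None)
    raw = eigvecs[:, order]

    s_w = W / (n - g)  # pooled within-group covariance
    # unit pooled within-group variance of scores
    score_sd = np.sqrt(np.einsum("ij,jk,ki->i", raw.T, s_w, raw))
    raw = raw / score_sd
    std = raw * np.sqrt(np.diag(s_w))[:, None]

    # fix arbitrary axis signs: largest |standardized coefficient| positive
    flip = np.sign(std[np.argmax(np.abs(std), axis=0), np.arange(raw.shape[1])])
    flip[flip == 0] = 1.0
    raw, std = raw * flip, std * flip

    scores = (X - grand) @ raw
    structure = np.empty_like(std)
    for j in range(p):
        for m_ in range(raw.shape[1]):
            structure[j, m_] = np.corrcoef(X[:, j], scores[:, m_])[0, 1]

    return CanonicalResult(
        eigenvalues=eigvals,
        raw_coefficients=raw,
        standardized_coefficients=std,
        structure_coefficients=structure,
        scores=scores,
        group_labels=tuple(uniq.tolist()),
    )
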