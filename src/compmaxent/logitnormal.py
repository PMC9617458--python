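"""Logit-normal baseline for interaction inference.

The logistic-normal (logit-normal) distribution models a composition by
placing a Gaussian on the additive log-ratios
``y = [log(s_1/s_N), ..., log(s_{N-1}/s_N)]``.  The feature of interest
for network inference is the precision matrix ``K* = -Sigma_LN^{-1}``
of the transformed data, which approximates pairwise maximum-entropy
interactions.  To compare head-to-head with CME, ``K*`` is treated as a
tilde-parameter matrix and symmetrized into a full N x N
zero-diagonal interaction matrix by the same refinement transformation
CME uses.

Unlike CME, the log-ratio transform cannot natively handle zeros; a
pseudocount replacement is applied when zeros are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import refine_parameters
from .types import CompositionTable, TildeParameters

__all__ = ["LogitNormalFit", "logratio_transform", "fit_logit_normal"]


@dataclass
class LogitNormalFit:
    """Moments and interaction matrices of a logit-normal fit."""

    M_LN: np.ndarray       # (N-1,) mean of log-ratios
    Sigma_LN: np.ndarray   # (N-1, N-1) covariance of log-ratios
    K_star: np.ndarray     # -(Sigma_LN)^{-1}
    K_full: np.ndarray     # N x N symmetric, zero diagonal
    pseudocount: float

    def __post_init__(self) -> None:
        if np.max(np.abs(self.Sigma_LN - self.Sigma_LN.T)) > 1e-10 * max(
            1.0, np.max(np.abs(self.Sigma_LN))
        ):
            raise ValueError("Sigma_LN must be symmetric")


def logratio_transform(
    table: CompositionTable, pseudocount: float = 0.0
) -> np.ndarray:
    """Additive log-ratio transform against the last component.

    ``y_j = log((s_j + pseudocount) / (s_N + pseudocount))``.  Zeros in
    the table require a positive pseudocount — the log-ratio family is
    undefined on the simplex boundary.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    v = table.values
    if pseudocount == 0.0 and np.any(v == 0.0):
        raise ValueError(
            "table contains zeros: the log-ratio transform is undefined at "
            "the simplex boundary; supply a positive pseudocount"
        )
    shifted = v + pseudocount
    return np.log(shifted[:, :-1] / shifted[:, -1:])


def _auto_pseudocount(table: CompositionTable) -> float:
    v = table.values
    if not np.any(v == 0.0):
        return 0.0
    positive = v[v > 0]
    return float(positive.min() / 2.0)


def fit_logit_normal(
    table: CompositionTable,
    pseudocount: float | None = None,
    shrinkage: float | None = None,
) -> LogitNormalFit:
    """Fit the logit-normal moments and extract interaction matrices.

    ``pseudocount=None`` chooses half the smallest positive value when
    zeros are present (0 otherwise).  ``shrinkage=None`` adds a small
    diagonal ridge ``1e-8 * trace/(N-1)`` to ``Sigma_LN`` only when it
    is numerically singular; pass an explicit value to force it.
    """
    d, n = table.n_samples, table.n_components
    if d <= n and shrinkage is None:
        raise ValueError(
            f"need more samples ({d}) than components ({n}) for an "
            "invertible log-ratio covariance, or enable shrinkage"
        )
    if pseudocount is None:
        pseudocount = _auto_pseudocount(table)
    y = logratio_transform(table, pseudocount)
    m = y.mean(axis=0)
    cov = np.cov(y, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if shrinkage is not None:
        cov = cov + shrinkage * np.eye(n - 1)
    else:
        # fall back to a tiny ridge only if the covariance is singular
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            eps = 1e-8 * np.trace(cov) / (n - 1)
            cov = cov + eps * np.eye(n - 1)
    try:
        k_star = -np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular log-ratio covariance; enable shrinkage or provide "
            "more samples"
        ) from exc
    tilde = TildeParameters(
        h_tilde=np.zeros(n - 1), K_tilde=k_star, n_components=n
    )
    k_full = refine_parameters(tilde).K
    return LogitNormalFit(
        M_LN=m,
        Sigma_LN=cov,
        K_star=k_star,
        K_full=k_full,
        pseudocount=float(pseudocount),
    )
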