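"""The compositional maximum-entropy (CME) model and its parameter maps.

The model is the maximum-entropy distribution on the probability simplex
constrained to match the first and second moments of the data:

    P(s) = Z^{-1} exp[ sum_i (h_i + 1/2 sum_{j != i} K_ij s_j) s_i ],

with s on the simplex.  Because sum_i s_i = 1, the parameterization is
redundant; the gauge h[N-1] = 0, K_ii = 0 fixes it.  This module holds
the density exponent, the moment constraints, and the two parameter
transformations: full -> tilde (eliminating component N for the
conditional distributions) and tilde -> refined (recovering the
symmetric, interpretable K and the influence weights Q).
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

from .types import (
    CMEParameters,
    CompositionTable,
    MomentSummary,
    TildeParameters,
    validate_composition,
)

__all__ = [
    "compute_moments",
    "log_unnormalized_density",
    "tilde_from_interactions",
    "tilde_from_refined",
    "refine_parameters",
    "influence_weights",
]


def compute_moments(table: CompositionTable) -> MomentSummary:
    """Empirical first and second moments of a composition table.

    Returns ``M_i = mean(s_i)``, ``chi_ij = mean(s_i s_j)`` and the
    covariance ``Sigma = chi - M M^T``.  The compositional closure
    identities (``sum(M) = 1``, rows of ``Sigma`` sum to 0) hold by
    construction.
    """
    if not isinstance(table, CompositionTable):
        table = CompositionTable(np.atleast_2d(table),
                                 [f"c{i+1}" for i in range(np.atleast_2d(table).shape[1])])
    s = table.values
    m = s.mean(axis=0)
    chi = (s.T @ s) / s.shape[0]
    chi = 0.5 * (chi + chi.T)
    return MomentSummary(M=m, chi=chi, Sigma=chi - np.outer(m, m))


def log_unnormalized_density(s, params: CMEParameters) -> float:
    """Exponent of the CME density at composition ``s`` (without log Z).

    Computes ``sum_i (h_i + 1/2 sum_{j != i} K_ij s_j) s_i``; with the
    zero-diagonal convention this is ``h.s + s.K.s / 2``.
    """
    s = validate_composition(s)
    if s.shape[0] != params.n_components:
        raise ValueError(
            f"composition has {s.shape[0]} parts, model has "
            f"{params.n_components}"
        )
    return float(params.h @ s + 0.5 * s @ params.K @ s)


def tilde_from_interactions(h: np.ndarray, K: np.ndarray) -> TildeParameters:
    """Map full (h, K) — possibly asymmetric K — to tilde parameters.

    Eliminating ``s_N = 1 - sum_{i<N} s_i`` from the density exponent
    gives the reduced natural parameters

        h~_i = h_i + (K_iN + K_Ni)/2,
        K~_ij = K_ij - K_iN - K_Nj       (i, j = 1..N-1, incl. diagonal),

    up to an additive constant absorbed by normalization.
    """
    h = np.asarray(h, dtype=float)
    K = np.asarray(K, dtype=float)
    n = h.shape[0]
    m = n - 1
    h_t = h[:m] + 0.5 * (K[:m, m] + K[m, :m])
    K_t = K[:m, :m] - K[:m, m][:, None] - K[m, :m][None, :]
    return TildeParameters(h_tilde=h_t, K_tilde=K_t, n_components=n)


def tilde_from_refined(params: CMEParameters) -> TildeParameters:
    """Tilde parameters of a refined (symmetric, gauge-fixed) model."""
    return tilde_from_interactions(params.h, params.K)


def refine_parameters(
    tilde: TildeParameters, names: list[str] | None = None
) -> CMEParameters:
    """Recover interpretable parameters from (possibly asymmetric) tilde ones.

        K_ij = (K~_ij + K~_ji - K~_ii - K~_jj)/2   (i, j < N),
        K_iN = K_Ni = -K~_ii / 2,
        h_i  = h~_i - K_iN,   h_N = 0,   K_ii = 0.

    The result is always symmetric with zero diagonal; on gauge-fixed
    refined parameters this inverts :func:`tilde_from_refined` exactly.
    """
    m = tilde.n_components - 1
    n = tilde.n_components
    Kt = tilde.K_tilde
    d = np.diag(Kt)
    K = np.zeros((n, n))
    K[:m, :m] = 0.5 * (Kt + Kt.T - d[:, None] - d[None, :])
    K[:m, m] = -0.5 * d
    K[m, :m] = -0.5 * d
    np.fill_diagonal(K, 0.0)
    h = np.zeros(n)
    h[:m] = tilde.h_tilde - K[:m, m]
    return CMEParameters(h=h, K=K, names=names)


def influence_weights(h: np.ndarray) -> np.ndarray:
    """Softmax influence weights ``Q_i = e^{h_i} / sum_j e^{h_j}``.

    ``Q_i`` compares the relative probability of a configuration
    dominated by component i; it is invariant to adding a constant to
    every ``h_i`` (the residual gauge freedom of the model).
    """
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("h must be finite")
    return softmax(h)
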