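"""Monte-Carlo simulation from a fitted CME model.

The chain is a pairwise-exchange Metropolis sampler: a proposal picks
two components and transfers a uniformly drawn amount between them,
which preserves the sum-to-one constraint exactly (proposals that would
drive a coordinate negative are rejected, which keeps the kernel
symmetric).  Acceptance uses only differences of the unnormalized
log-density, so the intractable normalizer Z never appears.  The
proposal width adapts toward a 30-50% acceptance rate during burn-in
and is frozen afterwards to preserve detailed balance.

For small models (N <= 4) :func:`brute_force_moments` computes the
exact moments by deterministic tensor-product Gauss-Legendre quadrature
over the simplex with automatic order doubling; it is the ground truth
against which the sampler is validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .model import compute_moments
from .types import CMEParameters, CompositionTable, MomentSummary

__all__ = [
    "SamplerConfig",
    "sample",
    "estimate_moments",
    "brute_force_moments",
]


@dataclass
class SamplerConfig:
    """Chain settings for the pairwise-exchange Metropolis sampler.

    ``burn_in`` and ``thin`` default (when None) to ``10000 * N`` steps
    and ``N`` steps per retained draw; ``step_scale`` is the initial
    proposal half-width as a fraction of the simplex edge, adapted
    during burn-in.
    """

    n_samples: int = 10000
    burn_in: int | None = None
    thin: int | None = None
    step_scale: float = 0.1
    seed: int = 0
    adapt: bool = True
    #: fraction of proposals drawn at full range (transfer ~ U(-1, 1))
    #: regardless of the adapted width; these let the chain hop between
    #: well-separated modes (e.g. simplex vertices under strong
    #: competition) and keep the kernel symmetric.
    big_step_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin is not None and self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.step_scale <= 1.0:
            raise ValueError("step_scale must be in (0, 1]")
        if not 0.0 <= self.big_step_prob < 1.0:
            raise ValueError("big_step_prob must be in [0, 1)")

    def resolved(self, n: int) -> tuple[int, int]:
        burn = 10000 * n if self.burn_in is None else self.burn_in
        thin = n if self.thin is None else self.thin
        return burn, thin


def sample(params: CMEParameters, config: SamplerConfig) -> CompositionTable:
    """Draw approximately CME-distributed compositions.

    Deterministic given ``config.seed``.  Every draw lies exactly on
    the simplex (the proposal conserves the sum).
    """
    n = params.n_components
    if n > 20 or np.max(np.abs(params.K)) > 50:
        warnings.warn(
            "Monte-Carlo simulation is expensive for large or strongly "
            "interacting models; expect long autocorrelation times",
            stacklevel=2,
        )
    burn, thin = config.resolved(n)
    total = burn + config.n_samples * thin
    rng = np.random.default_rng(config.seed)

    h, K = params.h, params.K
    s = rng.dirichlet(np.ones(n))
    Ks = K @ s
    step = float(config.step_scale)
    draws = np.empty((config.n_samples, n))
    kept = 0
    acc_small = 0
    n_small = 0
    window = 500

    block = 65536
    t = 0
    while t < total:
        nb = min(block, total - t)
        ii = rng.integers(0, n, size=nb)
        jj = rng.integers(0, n - 1, size=nb)
        jj = jj + (jj >= ii)
        deltas = rng.uniform(-1.0, 1.0, size=nb)
        big = rng.random(size=nb) < config.big_step_prob
        logu = np.log(rng.random(size=nb))
        for q in range(nb):
            i, j = ii[q], jj[q]
            d = deltas[q] if big[q] else deltas[q] * step
            si, sj = s[i] + d, s[j] - d
            accepted = False
            if si >= 0.0 and sj >= 0.0:
                dlp = d * (h[i] - h[j] + Ks[i] - Ks[j]) - d * d * K[i, j]
                if dlp >= 0.0 or logu[q] < dlp:
                    s[i], s[j] = si, sj
                    Ks += d * (K[:, i] - K[:, j])
                    accepted = True
            t_step = t + q
            if t_step >= burn:
                k = t_step - burn
                if (k + 1) % thin == 0:
                    draws[kept] = s
                    kept += 1
            elif config.adapt and not big[q]:
                n_small += 1
                acc_small += accepted
                if n_small == window:
                    rate = acc_small / window
                    if rate > 0.5:
                        step = min(step * 1.15, 1.0)
                    elif rate < 0.3:
                        step = max(step * 0.85, 1e-5)
                    acc_small = 0
                    n_small = 0
        t += nb

    draws = np.clip(draws, 0.0, None)
    draws /= draws.sum(axis=1, keepdims=True)
    names = params.names or [f"s{i + 1}" for i in range(n)]
    return CompositionTable(draws, names)


def estimate_moments(
    params: CMEParameters, config: SamplerConfig, n_batches: int = 20
) -> MomentSummary:
    """Monte-Carlo estimate of model means and covariances.

    Runs :func:`sample` and summarizes the draws, attaching batch-means
    standard errors (``se_M``, ``se_Sigma``) so agreement checks can be
    phrased in sampling-error units.
    """
    table = sample(params, config)
    mom = compute_moments(table)
    v = table.values
    nb = min(n_batches, v.shape[0])
    usable = (v.shape[0] // nb) * nb
    batches = v[:usable].reshape(nb, -1, v.shape[1])
    bM = batches.mean(axis=1)  # (nb, n)
    centered = batches - mom.M[None, None, :]
    bS = np.einsum("bki,bkj->bij", centered, centered) / batches.shape[1]
    se_M = bM.std(axis=0, ddof=1) / np.sqrt(nb)
    se_S = bS.std(axis=0, ddof=1) / np.sqrt(nb)
    mom.se_M = se_M
    mom.se_Sigma = se_S
    return mom


def _simplex_grid(n_free: int, order: int):
    """Tensor Gauss-Legendre nodes/weights on the simplex interior.

    Returns free coordinates (P, n_free) and quadrature weights (P,)
    including the Jacobian of the nested variable limits
    s_k in [0, 1 - s_1 - ... - s_{k-1}].
    """
    x, w = leggauss(order)
    x = 0.5 * (x + 1.0)
    w = 0.5 * w
    coords = np.zeros((1, 0))
    weights = np.ones(1)
    remaining = np.ones(1)
    for _ in range(n_free):
        scale = remaining[:, None] * x[None, :]  # (P, order)
        weights = (weights[:, None] * (remaining[:, None] * w[None, :])).ravel()
        coords = np.concatenate(
            [
                np.repeat(coords, order, axis=0),
                scale.reshape(-1, 1),
            ],
            axis=1,
        )
        remaining = (remaining[:, None] - scale).ravel()
    return coords, weights


def _moments_at_order(params: CMEParameters, order: int) -> MomentSummary:
    n = params.n_components
    free, w = _simplex_grid(n - 1, order)
    s = np.concatenate([free, (1.0 - free.sum(axis=1))[:, None]], axis=1)
    expo = s @ params.h + 0.5 * np.einsum("pi,ij,pj->p", s, params.K, s)
    expo -= expo.max()
    dens = w * np.exp(expo)
    Z = dens.sum()
    M = (dens[:, None] * s).sum(axis=0) / Z
    chi = np.einsum("p,pi,pj->ij", dens, s, s) / Z
    chi = 0.5 * (chi + chi.T)
    return MomentSummary(M=M, chi=chi, Sigma=chi - np.outer(M, M))


def brute_force_moments(
    params: CMEParameters, rtol: float = 1e-9, max_order: int = 256
) -> MomentSummary:
    """Deterministic quadrature moments of the CME density (N <= 4).

    Iterated Gauss-Legendre quadrature with the nested simplex limits;
    the order is doubled until every moment entry changes by less than
    ``rtol``.  Refuses N > 4 (cost grows as order^(N-1)).
    """
    n = params.n_components
    if n > 4:
        raise ValueError(
            "brute-force quadrature is limited to N <= 4 components"
        )
    order = 16
    prev = _moments_at_order(params, order)
    while order < max_order:
        order *= 2
        cur = _moments_at_order(params, order)
        delta = max(
            np.max(np.abs(cur.M - prev.M)),
            np.max(np.abs(cur.chi - prev.chi)),
        )
        if delta < rtol:
            return cur
        prev = cur
    warnings.warn(
        f"simplex quadrature did not reach rtol={rtol} at order {max_order}; "
        "returning the highest-order estimate",
        stacklevel=2,
    )
    return prev
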