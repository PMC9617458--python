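"""Core data containers for compositional maximum-entropy modeling.

A *composition* is a nonnegative vector summing to one (a point on the
probability simplex); a :class:`CompositionTable` is a stack of D such
vectors with named components — the universal input of this package.
Model parameters come in two coordinate systems:

* :class:`TildeParameters` — the reduced (N-1)-dimensional natural
  parameters of the per-component conditional distributions obtained
  after eliminating the redundant component via the sum-to-one
  constraint.  These are what the pseudolikelihood optimizer touches.
* :class:`CMEParameters` — the refined, reportable parameterization:
  a symmetric interaction matrix ``K`` with zero diagonal, node
  influences ``h`` gauge-fixed by ``h[N-1] = 0``, and softmax influence
  weights ``Q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SUM_TOL",
    "Composition",
    "CompositionTable",
    "MomentSummary",
    "TildeParameters",
    "CMEParameters",
    "validate_composition",
]

#: Rows whose sum deviates from 1 by at most this are silently renormalized;
#: larger deviations are rejected.  Real relative-abundance tables carry
#: rounding error at roughly this scale.
SUM_TOL = 1e-6

#: A composition is just a 1-D float array on the simplex; see
#: :func:`validate_composition`.
Composition = np.ndarray


def validate_composition(s, *, sum_tol: float = SUM_TOL) -> np.ndarray:
    """Validate and return a single composition as a float array.

    Entries must be nonnegative and sum to 1 within ``sum_tol``; a sum
    within tolerance is renormalized exactly to 1.  Exact zeros are
    allowed: the model is defined on the closed simplex.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1:
        raise ValueError(f"composition must be 1-D, got shape {s.shape}")
    if np.any(~np.isfinite(s)):
        raise ValueError("composition contains non-finite entries")
    if np.any(s < -1e-12):
        raise ValueError(
            f"composition has negative entries (min {s.min():.3g})"
        )
    s = np.clip(s, 0.0, None)
    total = s.sum()
    if abs(total - 1.0) > sum_tol:
        raise ValueError(
            f"composition sums to {total!r}, which deviates from 1 by more "
            f"than the tolerance {sum_tol}; renormalize the input explicitly "
            "if the data are raw abundances"
        )
    if abs(total - 1.0) > 1e-13:
        s = s / total
    return s


@dataclass
class CompositionTable:
    """D samples of an N-part composition, with named components.

    Parameters
    ----------
    values : (D, N) array
        Relative abundances; each row must lie on the simplex within
        :data:`SUM_TOL` (and is renormalized exactly).
    names : sequence of str
        Unique component names, one per column.
    sample_ids : sequence of str, optional
        Row labels, kept through I/O round trips.
    """

    values: np.ndarray
    names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        d, n = v.shape
        if n < 2:
            raise ValueError(f"need at least 2 components, got {n}")
        if d < 1:
            raise ValueError("need at least 1 sample")
        self.names = [str(x) for x in self.names]
        if len(self.names) != n:
            raise ValueError(
                f"{len(self.names)} component names for {n} columns"
            )
        if len(set(self.names)) != n:
            raise ValueError("component names must be unique")
        if np.any(~np.isfinite(v)):
            raise ValueError("table contains non-finite entries")
        if np.any(v < -1e-12):
            bad = int(np.argmax(np.any(v < -1e-12, axis=1)))
            raise ValueError(f"negative abundance in sample row {bad}")
        v = np.clip(v, 0.0, None)
        sums = v.sum(axis=1)
        bad = np.abs(sums - 1.0) > SUM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"row {i} sums to {sums[i]!r} (deviation > {SUM_TOL}); "
                "rows must be compositions summing to 1"
            )
        # renormalize only rows with a material deviation, so that
        # already-closed tables survive I/O round trips bit-for-bit
        off = np.abs(sums - 1.0) > 1e-13
        if np.any(off):
            v = v.copy()
            v[off] /= sums[off, None]
        self.values = v
        if self.sample_ids is not None:
            self.sample_ids = [str(x) for x in self.sample_ids]
            if len(self.sample_ids) != d:
                raise ValueError("sample_ids length does not match rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def reorder(self, order: np.ndarray | list[int]) -> "CompositionTable":
        """Return a table with columns permuted by ``order``."""
        order = np.asarray(order, dtype=int)
        return CompositionTable(
            self.values[:, order],
            [self.names[i] for i in order],
            self.sample_ids,
        )

    def with_reference_last(
        self, reference: str | None
    ) -> tuple["CompositionTable", np.ndarray]:
        """Move ``reference`` (a component name) to the last column.

        Returns the reordered table and the permutation applied, so
        results can be mapped back.  ``None`` keeps the current order.
        """
        n = self.n_components
        if reference is None:
            return self, np.arange(n)
        if reference not in self.names:
            raise KeyError(f"unknown component {reference!r}")
        k = self.names.index(reference)
        order = np.array([i for i in range(n) if i != k] + [k])
        return self.reorder(order), order


@dataclass
class MomentSummary:
    """First and second moments of a compositional sample.

    ``M[i] = <s_i>``, ``chi[i, j] = <s_i s_j>``, and
    ``Sigma = chi - M M^T``.  The sum-to-one constraint imposes closure:
    ``sum(M) = 1``, each row of ``chi`` sums to the corresponding
    ``M[i]``, and each row of ``Sigma`` sums to 0.

    ``se_M`` / ``se_Sigma`` hold Monte-Carlo standard errors when the
    summary was estimated from a Markov chain (batch means), else None.
    """

    M: np.ndarray
    chi: np.ndarray
    Sigma: np.ndarray
    se_M: np.ndarray | None = None
    se_Sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        n = self.M.shape[0]
        if self.chi.shape != (n, n) or self.Sigma.shape != (n, n):
            raise ValueError("moment matrices must be N x N")

    @property
    def n_components(self) -> int:
        return self.M.shape[0]


@dataclass
class TildeParameters:
    """Natural parameters of the N-1 conditional distributions.

    ``h_tilde[i]`` and row ``K_tilde[i, :]`` (including the diagonal
    ``K_tilde[i, i]``) parameterize the conditional density of component
    i given the rest; component N has been eliminated by the simplex
    constraint, so everything is indexed over the first N-1 components.
    """

    h_tilde: np.ndarray
    K_tilde: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        self.h_tilde = np.asarray(self.h_tilde, dtype=float)
        self.K_tilde = np.asarray(self.K_tilde, dtype=float)
        m = self.n_components - 1
        if self.h_tilde.shape != (m,):
            raise ValueError(
                f"h_tilde must have length N-1={m}, got {self.h_tilde.shape}"
            )
        if self.K_tilde.shape != (m, m):
            raise ValueError(
                f"K_tilde must be (N-1)x(N-1)={m}x{m}, got {self.K_tilde.shape}"
            )
        if not (
            np.all(np.isfinite(self.h_tilde))
            and np.all(np.isfinite(self.K_tilde))
        ):
            raise ValueError("tilde parameters must be finite")


@dataclass
class CMEParameters:
    """Refined, reportable model parameters.

    ``K`` is the symmetric pairwise interaction matrix with zero
    diagonal (``K[i, j] > 0``: components i and j tend to coexist;
    ``< 0``: mutually exclusive).  ``h`` are node influences with the
    gauge ``h[N-1] = 0``; ``Q`` are the softmax influence weights
    (positive, summing to 1).
    """

    h: np.ndarray
    K: np.ndarray
    Q: np.ndarray = field(default=None)  # type: ignore[assignment]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        from .model import influence_weights  # local import: avoid cycle

        self.h = np.asarray(self.h, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        n = self.h.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("K must be N x N matching h")
        if not (np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.K))):
            raise ValueError("parameters must be finite")
        scale = max(1.0, float(np.max(np.abs(self.K), initial=0.0)))
        if np.max(np.abs(self.K - self.K.T)) > 1e-8 * scale:
            raise ValueError("K must be symmetric")
        if np.max(np.abs(np.diag(self.K))) > 1e-8 * scale:
            raise ValueError("K must have zero diagonal")
        if abs(self.h[-1]) > 1e-8 * max(1.0, np.max(np.abs(self.h))):
            raise ValueError("gauge requires h[N-1] = 0")
        # enforce the invariants exactly
        self.K = 0.5 * (self.K + self.K.T)
        np.fill_diagonal(self.K, 0.0)
        self.h = self.h.copy()
        self.h[-1] = 0.0
        if self.Q is None:
            self.Q = influence_weights(self.h)
        else:
            self.Q = np.asarray(self.Q, dtype=float)
        if self.names is not None:
            self.names = [str(x) for x in self.names]
            if len(self.names) != n:
                raise ValueError("names length does not match h")

    @property
    def n_components(self) -> int:
        return self.h.shape[0]
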