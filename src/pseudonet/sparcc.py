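"""Compositional correlation (co-abundance) estimation for count tables.

Sequencing counts are compositional: only the relative abundances within a
sample are informative, so naive Pearson correlation of counts or fractions is
biased by the closure constraint.  The SparCC approach works on log-ratio
variances instead.  Writing ``u_j`` for the fraction of taxon ``j`` in a
sample, the variance of the pairwise log-ratio decomposes as

    t_jk = Var(log(u_j/u_k)) = sigma_j^2 + sigma_k^2 - 2 rho_jk sigma_j sigma_k

where ``sigma_j^2`` is the variance of the (unobserved) log basis abundance
and ``rho_jk`` the basis correlation.  Under the sparsity assumption — most
pairs are uncorrelated — the row totals of the log-ratio variance matrix give
a linear system for the basis variances, from which pairwise correlations are
back-solved.  Strongly correlated pairs violate the assumption, so they are
excluded one at a time and the system re-solved, up to a configured number of
iterations.

The estimate here is a deterministic point estimate on pseudocount-smoothed
fractions (no Dirichlet resampling), so that downstream leave-one-out
re-estimation is a deterministic functional of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InputError(ValueError):
    """Invalid user-supplied data (counts, metadata, configuration)."""


class EstimationError(RuntimeError):
    """A numerically degenerate or infeasible estimation step."""


@dataclass
class CountTable:
    """Samples-by-taxa table of non-negative integer abundances."""

    counts: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D samples x taxa array")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        n, p = self.counts.shape
        if p < 3:
            raise InputError(
                f"need at least 3 taxa for basis-variance estimation, got {p}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.taxon_ids:
            self.taxon_ids = [f"taxon{j}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise InputError("id lengths do not match count dimensions")
        if len(set(self.sample_ids)) != n or len(set(self.taxon_ids)) != p:
            raise InputError("duplicate sample or taxon ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "CountTable":
        idx = np.asarray(idx)
        return CountTable(
            counts=self.counts[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            taxon_ids=list(self.taxon_ids),
        )


@dataclass
class SparccConfig:
    """Tuning knobs for the iterative basis-variance estimator.

    pseudocount
        Added to every cell before converting to fractions; zeros are
        ubiquitous in OTU tables.
    exclusion_threshold
        Minimum |rho| for a pair to be flagged as a strong correlation and
        excluded from the basis system.
    max_exclusion_iters
        Upper bound on exclusion rounds (one pair removed per round).
    clip_correlations
        Clip the returned correlations into [-1, 1].
    """

    pseudocount: float = 1.0
    exclusion_threshold: float = 0.1
    max_exclusion_iters: int = 10
    clip_correlations: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise InputError("pseudocount must be non-negative")
        if not (0 < self.exclusion_threshold < 1):
            raise InputError("exclusion_threshold must be in (0, 1)")
        if self.max_exclusion_iters < 0:
            raise InputError("max_exclusion_iters must be >= 0")


@dataclass
class LogRatioVariances:
    """Pairwise log-ratio variance matrix T and its row totals."""

    T: np.ndarray
    t_row: np.ndarray


@dataclass
class BasisVariances:
    """Solved variances of the log basis abundances."""

    sigma2: np.ndarray


@dataclass
class AssociationMatrix:
    """Symmetric p x p correlation estimate with unit diagonal."""

    rho: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        p = self.rho.shape[0]
        if self.rho.shape != (p, p):
            raise InputError("association matrix must be square")
        if not self.taxon_ids:
            self.taxon_ids = [f"taxon{j}" for j in range(p)]


_VARIANCE_FLOOR = 1e-12


def to_fractions(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Convert counts to strictly positive row-stochastic fractions."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InputError("counts must be non-negative")
    if pseudocount <= 0 and np.any(counts.sum(axis=1) <= 0) :
        raise InputError("zero-total sample with no pseudocount")
    smoothed = counts + pseudocount
    totals = smoothed.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise InputError("sample with non-positive total after pseudocount")
    return smoothed / totals


def logratio_variance(fractions: np.ndarray) -> LogRatioVariances:
    """Unbiased sample variances of log(u_j/u_k) for every taxon pair.

    Uses Var(log u_j) + Var(log u_k) - 2 Cov(log u_j, log u_k), which equals
    the direct pairwise computation but costs one covariance matrix.
    """
    fractions = np.asarray(fractions, dtype=float)
    n = fractions.shape[0]
    if n < 3:
        raise InputError(f"need at least 3 samples, got {n}")
    if np.any(fractions <= 0):
        raise InputError("fractions must be strictly positive")
    L = np.log(fractions)
    C = np.cov(L, rowvar=False)  # unbiased (ddof=1)
    v = np.diag(C)
    T = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    T = np.maximum(0.5 * (T + T.T), 0.0)  # symmetrize, clamp FP negatives
    np.fill_diagonal(T, 0.0)
    return LogRatioVariances(T=T, t_row=T.sum(axis=1))


def solve_basis_variances(
    lrv: LogRatioVariances,
    excluded_pairs: set[tuple[int, int]] | None = None,
) -> BasisVariances:
    """Solve the basis-variance linear system on the retained pairs.

    With P_j the retained partners of taxon j, the sparsity approximation
    gives  sum_{k in P_j} t_jk  ~=  |P_j| sigma_j^2 + sum_{k in P_j} sigma_k^2,
    a p x p linear system.  Negative solutions are clipped to a small floor.
    """
    T = lrv.T
    p = T.shape[0]
    retained = np.ones((p, p), dtype=bool)
    np.fill_diagonal(retained, False)
    for j, k in excluded_pairs or ():
        retained[j, k] = retained[k, j] = False
    degree = retained.sum(axis=1)
    if np.any(degree < 1):
        bad = np.where(degree < 1)[0].tolist()
        raise EstimationError(
            f"taxa {bad} have no retained partner; basis system is singular"
        )
    M = retained.astype(float)
    M[np.diag_indices(p)] = degree
    t = np.where(retained, T, 0.0).sum(axis=1)
    try:
        sigma2 = np.linalg.solve(M, t)
    except np.linalg.LinAlgError as exc:
        bad = np.where(degree <= 1)[0].tolist()
        raise EstimationError(
            f"basis-variance system singular (over-excluded taxa {bad})"
        ) from exc
    return BasisVariances(sigma2=np.maximum(sigma2, _VARIANCE_FLOOR))


def estimate_correlations(
    lrv: LogRatioVariances,
    basis: BasisVariances,
    clip: bool = True,
    taxon_ids: list[str] | None = None,
) -> AssociationMatrix:
    """Back-solve pairwise correlations from basis and log-ratio variances."""
    sigma2 = np.asarray(basis.sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise EstimationError("non-positive basis variance")
    sigma = np.sqrt(sigma2)
    num = sigma2[:, None] + sigma2[None, :] - lrv.T
    rho = num / (2.0 * np.outer(sigma, sigma))
    if clip:
        rho = np.clip(rho, -1.0, 1.0)
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 1.0)
    return AssociationMatrix(rho=rho, taxon_ids=taxon_ids or [])


def sparcc(counts: CountTable, config: SparccConfig | None = None) -> AssociationMatrix:
    """Full iterative estimate: fractions, log-ratio variances, exclusion loop.

    Each round solves the basis system, re-estimates correlations, and
    excludes the single not-yet-excluded pair with the largest |rho| above
    the threshold; stops when no pair qualifies or the iteration cap is hit.
    """
    config = config or SparccConfig()
    fractions = to_fractions(counts.counts, config.pseudocount)
    lrv = logratio_variance(fractions)
    return _sparcc_from_lrv(lrv, config, counts.taxon_ids)


def _sparcc_from_lrv(
    lrv: LogRatioVariances,
    config: SparccConfig,
    taxon_ids: list[str] | None = None,
) -> AssociationMatrix:
    excluded: set[tuple[int, int]] = set()
    basis = solve_basis_variances(lrv, excluded)
    assoc = estimate_correlations(lrv, basis, config.clip_correlations, taxon_ids)
    for _ in range(config.max_exclusion_iters):
        pair = _strongest_retained_pair(assoc.rho, excluded, config.exclusion_threshold)
        if pair is None:
            break
        excluded.add(pair)
        try:
            basis = solve_basis_variances(lrv, excluded)
        except EstimationError:
            # this exclusion makes the basis system singular: keep the last
            # solvable estimate instead of failing the whole fit
            excluded.discard(pair)
            break
        assoc = estimate_correlations(lrv, basis, config.clip_correlations, taxon_ids)
    return assoc


def _strongest_retained_pair(
    rho: np.ndarray,
    excluded: set[tuple[int, int]],
    threshold: float,
) -> tuple[int, int] | None:
    """Largest not-yet-excluded |rho| above threshold, never isolating a taxon."""
    p = rho.shape[0]
    a = np.abs(rho).copy()
    np.fill_diagonal(a, 0.0)
    degree = np.full(p, p - 1)
    for j, k in excluded:
        a[j, k] = a[k, j] = 0.0
        degree[j] -= 1
        degree[k] -= 1
    iu = np.triu_indices(p, 1)
    order = np.argsort(a[iu])[::-1]
    for idx in order:
        j, k = iu[0][idx], iu[1][idx]
        if a[j, k] <= threshold:
            return None
        if degree[j] > 1 and degree[k] > 1:  # exclusion must not isolate
            return (int(j), int(k))
    return None
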