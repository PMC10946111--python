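"""Synthetic microbiome studies with a known differential-connectivity truth.

The generator emulates the structure of a two-group 16S study:

* a scale-free (Barabasi-Albert) co-abundance network over p taxa;
* per group, a perturbed copy of that network in which all edges incident to
  a small set of covariate-associated ("spiked") taxa are removed — the taxa
  whose neighbourhoods differ between the two copies are the truly
  differentially connected (DC) taxa;
* a binary group label Z ~ Bernoulli(0.5) and a continuous covariate
  X ~ N(55, 10) (an age-like variable, shifted in group 2 in the
  multivariable setting);
* zero-inflated, truncated log-normal abundances coupled through a latent
  Gaussian copula whose correlation carries the group-specific network, with
  the spiked taxa additionally shifted in the latent log scale (by the
  standardized covariate in the multivariable setting, or by a group-2 offset
  in the univariable setting);
* integer counts drawn multinomially at a log-normal per-sample library size.

The effect sizes delta1, delta2 are the fractions of taxa spiked per group;
they control how much of the network is perturbed and hence how many taxa are
truly DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .jackknife import GroupedStudy
from .sparcc import CountTable, EstimationError, InputError


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    p, n
        Number of taxa and total sample size.
    delta1, delta2
        Fraction of taxa spiked (covariate-associated) in groups 1 and 2.
    multivariable
        If True, spiked taxa respond to the continuous covariate X within
        their group and X is shifted in group 2; if False, only a group-2
        abundance offset is applied (group-only design).
    shared_spike_set
        Force S1 = S2 (requires delta1 == delta2); the null configuration in
        which both groups receive the identical perturbation.
    """

    p: int = 20
    n: int = 200
    delta1: float = 0.05
    delta2: float = 0.20
    multivariable: bool = True
    shared_spike_set: bool = False
    ba_edges_per_node: int = 1
    edge_correlation: float = 0.6
    covariate_mean: float = 55.0
    covariate_sd: float = 10.0
    covariate_shift: float = 5.0
    zero_inflation: float = 0.3
    library_size_logmean: float = float(np.log(10000.0))
    library_size_logsd: float = 0.3
    effect_coefficient: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise InputError("need at least 2 taxa")
        if not (0 <= self.delta1 <= 1 and 0 <= self.delta2 <= 1):
            raise InputError("effect sizes must lie in [0, 1]")
        if int(np.ceil(self.delta1 * self.p)) >= self.p or int(
            np.ceil(self.delta2 * self.p)
        ) >= self.p:
            raise InputError("spiked set must leave at least one taxon untouched")
        if not (0 <= self.zero_inflation < 1):
            raise InputError("zero_inflation must lie in [0, 1)")
        if not (0 < self.edge_correlation < 1):
            raise InputError("edge_correlation must lie in (0, 1)")
        if self.shared_spike_set and self.delta1 != self.delta2:
            raise InputError("shared_spike_set requires delta1 == delta2")


@dataclass
class TruthNetwork:
    base_adjacency: np.ndarray
    omega: tuple[np.ndarray, np.ndarray]
    spiked: tuple[np.ndarray, np.ndarray]
    eta: np.ndarray


@dataclass
class SimulatedStudy:
    study: GroupedStudy
    truth: TruthNetwork
    config: SimConfig

    def config_dict(self) -> dict:
        return asdict(self.config)


def generate_ba_network(p: int, m: int = 1, seed: int = 0) -> np.ndarray:
    """0/1 adjacency of a preferential-attachment (scale-free) graph."""
    if p < 2:
        raise InputError("need at least 2 nodes")
    if p < m + 1:
        raise InputError("need p >= m + 1 for preferential attachment")
    g = nx.barabasi_albert_graph(p, m, seed=seed)
    adj = nx.to_numpy_array(g, dtype=int)
    np.fill_diagonal(adj, 0)
    return adj


def _remove_incident_edges(base: np.ndarray, spiked: np.ndarray) -> np.ndarray:
    omega = base.copy()
    omega[spiked, :] = 0
    omega[:, spiked] = 0
    return omega


def true_dc_labels(omega1: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """eta_k = 1 if taxon k has at least one differing neighbour entry."""
    omega1 = np.asarray(omega1)
    omega2 = np.asarray(omega2)
    if omega1.shape != omega2.shape:
        raise InputError("adjacency shapes differ")
    return (np.abs(omega1 - omega2).sum(axis=0) > 0).astype(int)


def perturb_truth(
    base: np.ndarray,
    delta1: float,
    delta2: float,
    seed: int = 0,
    shared_spike_set: bool = False,
) -> TruthNetwork:
    """Group-specific perturbed adjacencies around randomly spiked taxa.

    Spiked sets of size ceil(delta_z * p) are drawn uniformly among
    non-isolated nodes (removing edges around an isolated node changes
    nothing); all edges incident to a group's spiked taxa are removed from
    that group's copy of the network.
    """
    base = np.asarray(base)
    p = base.shape[0]
    rng = np.random.default_rng(seed)
    eligible = np.where(base.sum(axis=0) > 0)[0]
    if eligible.size == 0:
        eligible = np.arange(p)

    def draw(delta: float) -> np.ndarray:
        size = int(np.ceil(delta * p))
        size = min(size, eligible.size)
        return np.sort(rng.choice(eligible, size=size, replace=False))

    s1 = draw(delta1)
    s2 = s1.copy() if shared_spike_set else draw(delta2)
    omega1 = _remove_incident_edges(base, s1)
    omega2 = _remove_incident_edges(base, s2)
    return TruthNetwork(
        base_adjacency=base,
        omega=(omega1, omega2),
        spiked=(s1, s2),
        eta=true_dc_labels(omega1, omega2),
    )


def nearest_pd_correlation(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues are clipped at ``floor``, then the result is rescaled to unit
    diagonal.
    """
    mat = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    if np.any(d <= 0):
        raise EstimationError("positive-definite projection failed")
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def _latent_correlation(omega: np.ndarray, rho: float) -> np.ndarray:
    sigma = np.where(omega > 0, rho, 0.0)
    np.fill_diagonal(sigma, 1.0)
    return nearest_pd_correlation(sigma)


_LATENT_TRUNC = 3.0  # upper truncation (in sd units) of the log-normal marginals


def simulate_dataset(cfg: SimConfig) -> SimulatedStudy:
    """Draw one complete two-group study with its connectivity truth.

    The latent Gaussian copula carries the group-specific network: latent
    correlation is ``edge_correlation`` on the edges of the group's perturbed
    adjacency (projected to positive definite), so differential edges are
    genuinely present in the data, not only in the truth labels.
    """
    rng = np.random.default_rng(cfg.seed)
    base = generate_ba_network(cfg.p, cfg.ba_edges_per_node, seed=int(rng.integers(2**31)))
    truth = perturb_truth(
        base,
        cfg.delta1,
        cfg.delta2,
        seed=int(rng.integers(2**31)),
        shared_spike_set=cfg.shared_spike_set,
    )

    # group labels and covariate
    z = rng.binomial(1, 0.5, size=cfg.n) + 1
    # guard against an all-one-group draw at tiny n
    while len(np.unique(z)) < 2 or min(np.sum(z == 1), np.sum(z == 2)) < 4:
        z = rng.binomial(1, 0.5, size=cfg.n) + 1
    x = rng.normal(cfg.covariate_mean, cfg.covariate_sd, size=cfg.n)
    if cfg.multivariable:
        x[z == 2] += cfg.covariate_shift
    x_std = (x - x.mean()) / x.std()

    # taxon-level marginal parameters (one draw per dataset)
    mu = rng.normal(0.0, 1.0, size=cfg.p)
    sd = rng.uniform(0.5, 1.5, size=cfg.p)

    chol = {
        1: np.linalg.cholesky(_latent_correlation(truth.omega[0], cfg.edge_correlation)),
        2: np.linalg.cholesky(_latent_correlation(truth.omega[1], cfg.edge_correlation)),
    }

    log_abund = np.empty((cfg.n, cfg.p))
    for grp in (1, 2):
        idx = np.where(z == grp)[0]
        latent = rng.standard_normal((len(idx), cfg.p)) @ chol[grp].T
        latent = np.minimum(latent, _LATENT_TRUNC)  # truncated log-normal
        shifted = mu[None, :] + sd[None, :] * latent
        spiked = truth.spiked[grp - 1]
        if spiked.size:
            if cfg.multivariable:
                shifted[:, spiked] += cfg.effect_coefficient * x_std[idx, None]
            elif grp == 2:
                shifted[:, spiked] += cfg.effect_coefficient
        log_abund[idx] = shifted

    abund = np.exp(log_abund)
    keep = rng.random((cfg.n, cfg.p)) >= cfg.zero_inflation
    abund = abund * keep

    # multinomial counts at a log-normal library size
    lib = np.maximum(
        np.round(
            rng.lognormal(cfg.library_size_logmean, cfg.library_size_logsd, size=cfg.n)
        ).astype(int),
        1,
    )
    counts = np.empty((cfg.n, cfg.p), dtype=int)
    for i in range(cfg.n):
        total = abund[i].sum()
        if total <= 0:
            counts[i] = 0
            continue
        counts[i] = rng.multinomial(lib[i], abund[i] / total)

    table = CountTable(
        counts=counts,
        sample_ids=[f"S{i:04d}" for i in range(cfg.n)],
        taxon_ids=[f"taxon{j:03d}" for j in range(cfg.p)],
    )
    study = GroupedStudy(
        counts=table,
        group=z,
        covariates=x[:, None] if cfg.multivariable else np.empty((cfg.n, 0)),
        covariate_names=["age"] if cfg.multivariable else [],
    )
    return SimulatedStudy(study=study, truth=truth, config=cfg)
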