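"""Per-taxon pseudo-value regression, robust testing and FDR control.

Each taxon's pseudo-values are regressed on an intercept, the binary group
indicator Z and the clinical covariates:

    E[theta~_ik | Z_i, X_i] = alpha_k + beta_k Z_i + sum_m gamma_km X_im

Pseudo-values are heavy-tailed by construction (a leave-one-out estimate that
moves a lot produces an extreme pseudo-value), so the fit uses least trimmed
squares (LTS): minimize the sum of the h smallest squared residuals.  The
FAST-LTS algorithm draws random elemental subsets and improves each by
concentration steps (refit on the h best-fitting points) until the trimmed
objective stabilises.  A reweighting step then refits ordinary least squares
on the points whose standardized residuals fall below a cutoff, giving the
reported coefficients and standard errors.

beta_k is tested against zero with a t statistic; the per-taxon p-values are
converted to q-values (Storey's estimate of the null proportion, or plain
Benjamini-Hochberg) and a taxon is called differentially connected when its
q-value falls below the chosen error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .jackknife import GroupedStudy, PseudoValueMatrix, jackknife_pseudovalues
from .sparcc import InputError, EstimationError, SparccConfig


@dataclass
class LtsConfig:
    """FAST-LTS tuning parameters.

    coverage_fraction
        Fraction of points the trimmed objective covers.  ``None`` selects the
        maximal-breakdown coverage h = floor((n + d + 1)/2) for a design with
        d columns.
    n_initial_subsets
        Number of random elemental starts.
    n_csteps
        Cap on concentration steps per retained candidate.
    reweight_cutoff
        |standardized residual| bound for the reweighting step.
    """

    coverage_fraction: float | None = None
    n_initial_subsets: int = 500
    n_csteps: int = 50
    reweight_cutoff: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_fraction is not None and not (
            0.5 < self.coverage_fraction <= 1.0
        ):
            raise InputError("coverage_fraction must lie in (0.5, 1]")
        if self.n_initial_subsets < 1 or self.n_csteps < 1:
            raise InputError("subset and c-step counts must be positive")
        if self.reweight_cutoff <= 0:
            raise InputError("reweight_cutoff must be positive")

    def coverage(self, n: int, d: int) -> int:
        if self.coverage_fraction is None:
            h = (n + d + 1) // 2
        else:
            h = int(np.floor(n * self.coverage_fraction))
        h = max(h, d)
        if h > n:
            raise InputError(f"coverage h={h} exceeds n={n}")
        return h


@dataclass
class LtsFit:
    coefficients: np.ndarray        # reweighted (reported) estimates
    standard_errors: np.ndarray
    weights: np.ndarray             # 0/1 reweighting indicators
    scale: float                    # residual scale of the reweighted fit
    df: int
    objective: float                # raw trimmed sum of squares
    raw_coefficients: np.ndarray | None = None


def _trimmed_consistency_factor(h: int, n: int) -> float:
    """Variance inflation of the h/n central part of a normal sample."""
    alpha = h / n
    q = stats.norm.ppf((1.0 + alpha) / 2.0)
    factor = 1.0 - 2.0 * q * stats.norm.pdf(q) / alpha if alpha < 1.0 else 1.0
    return max(factor, 1e-12)


def _raw_scale_correction(n: int, d: int) -> float:
    """Finite-sample correction for the raw LTS scale at maximal breakdown.

    The concentration search overfits the selected h-subset, so the
    consistency-corrected raw scale still underestimates sigma at finite n.
    The downward bias was measured by Monte Carlo on normal-error designs
    over n in [20, 400], d in [2, 5] and summarised by the smooth curve
    E[sigma_hat/sigma] ~= 1 - exp(0.376) d^0.895 n^-0.746 (same spirit as the
    published small-sample LTS corrections).
    """
    bias = 1.0 - np.exp(0.376) * d**0.895 * n**-0.746
    return 1.0 / max(bias, 0.4)


def _truncation_consistency(cutoff: float) -> float:
    """Variance of a standard normal truncated to |x| <= cutoff."""
    mass = 2.0 * stats.norm.cdf(cutoff) - 1.0
    return 1.0 - 2.0 * cutoff * stats.norm.pdf(cutoff) / mass


def _batched_ols(X: np.ndarray, y: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """OLS coefficients for many row subsets at once; (B, h) row indices."""
    Xs = X[rows]                      # (B, h, d)
    ys = y[rows]                      # (B, h)
    G = np.einsum("bhi,bhj->bij", Xs, Xs)
    r = np.einsum("bhi,bh->bi", Xs, ys)
    # pinv tolerates collinear subsets; c-steps repair them afterwards
    return np.einsum("bij,bj->bi", np.linalg.pinv(G), r)


def fit_lts(response: np.ndarray, design: np.ndarray, config: LtsConfig | None = None) -> LtsFit:
    """Least trimmed squares via FAST-LTS with a reweighting step.

    Random elemental subsets of size d are fit exactly, improved with two
    concentration steps each, and the best candidates iterated to
    convergence.  Coefficients and standard errors come from the reweighted
    OLS fit on points with |standardized residual| <= cutoff; df is the
    number of retained points minus d.
    """
    config = config or LtsConfig()
    y = np.asarray(response, dtype=float)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    n, d = X.shape
    if y.shape != (n,):
        raise InputError("response length must match design rows")
    if n <= d:
        raise InputError(f"need n > d, got n={n}, d={d}")
    h = config.coverage(n, d)
    rng = np.random.default_rng(config.seed)

    if h == n:
        coef, obj = _ols_full(X, y)
        return _reweight(X, y, coef, h, n, d, config, obj)

    B = config.n_initial_subsets
    starts = np.stack(
        [rng.choice(n, size=d, replace=False) for _ in range(B)]
    )
    coefs = _batched_ols(X, y, starts)
    # two cheap c-steps for every start
    for _ in range(2):
        coefs, rows, objs = _cstep(X, y, coefs, h)
    # iterate the 10 best candidates to convergence
    keep = np.argsort(objs)[: min(10, B)]
    coefs = coefs[keep]
    prev = objs[keep]
    for _ in range(config.n_csteps):
        coefs, rows, objs = _cstep(X, y, coefs, h)
        if np.all(prev - objs <= 1e-12 * (1.0 + prev)):
            break
        prev = objs
    best = int(np.argmin(objs))
    if not np.isfinite(objs[best]):
        raise EstimationError("all LTS subsets were rank deficient")
    return _reweight(X, y, coefs[best], h, n, d, config, float(objs[best]))


def _ols_full(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _cstep(
    X: np.ndarray, y: np.ndarray, coefs: np.ndarray, h: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    resid2 = (y[None, :] - coefs @ X.T) ** 2          # (B, n)
    rows = np.argpartition(resid2, h - 1, axis=1)[:, :h]
    coefs = _batched_ols(X, y, rows)
    resid2 = (y[None, :] - coefs @ X.T) ** 2
    objs = np.sort(resid2, axis=1)[:, :h].sum(axis=1)
    return coefs, rows, objs


def _reweight(
    X: np.ndarray,
    y: np.ndarray,
    coef: np.ndarray,
    h: int,
    n: int,
    d: int,
    config: LtsConfig,
    objective: float,
) -> LtsFit:
    resid = y - X @ coef
    raw_scale = np.sqrt(
        np.sort(resid**2)[:h].sum() / h / _trimmed_consistency_factor(h, n)
    )
    if h < n:
        raw_scale *= _raw_scale_correction(n, d)
    if raw_scale < 1e-12:
        # exact (or near-exact) fit: keep everything consistent with it
        weights = (np.abs(resid) <= 1e-8 * (1.0 + np.abs(y).max())).astype(int)
        if weights.sum() < d + 1:
            weights = np.ones(n, dtype=int)
    else:
        weights = (np.abs(resid / raw_scale) <= config.reweight_cutoff).astype(int)
    idx = np.where(weights == 1)[0]
    if len(idx) <= d:
        idx = np.arange(n)
        weights = np.ones(n, dtype=int)
    Xw, yw = X[idx], y[idx]
    G = Xw.T @ Xw
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("reweighted design is rank deficient") from exc
    coef_w = Ginv @ (Xw.T @ yw)
    resid_w = yw - Xw @ coef_w
    df = len(idx) - d
    if df <= 0:
        raise EstimationError("no residual degrees of freedom after trimming")
    s2 = float(resid_w @ resid_w) / df
    if weights.sum() < n:  # retained set is |resid| <= cutoff truncated
        s2 /= _truncation_consistency(config.reweight_cutoff)
    se = np.sqrt(np.maximum(np.diag(Ginv) * s2, 0.0))
    return LtsFit(
        coefficients=coef_w,
        standard_errors=se,
        weights=weights,
        scale=float(np.sqrt(s2)),
        df=df,
        objective=objective,
        raw_coefficients=coef,
    )


def qvalues(p_values: np.ndarray, method: str = "storey", pi0: float | None = None) -> np.ndarray:
    """FDR q-values from a vector of p-values.

    ``storey`` estimates the null proportion pi0 by the lambda-grid smoothing
    recipe (cubic fit over lambda = 0, 0.05, ..., 0.95, evaluated at the
    right end); ``bh`` is the Benjamini-Hochberg step-up, i.e. pi0 = 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = 1.0 if method == "bh" else _storey_pi0(p)
    elif not (0 < pi0 <= 1):
        raise InputError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _storey_pi0(p: np.ndarray) -> float:
    m = p.size
    lams = np.arange(0.0, 0.951, 0.05)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lams])
    if np.all(pi0_lam == 0):
        return 1.0 / m
    coeffs = np.polyfit(lams, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lams[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def _design_matrix(study: GroupedStudy) -> tuple[np.ndarray, np.ndarray]:
    labels = study.group_labels
    if len(labels) < 2:
        raise InputError("group indicator is constant; need two groups")
    z = (study.group == labels[1]).astype(float)
    if z.std() == 0:
        raise InputError("group indicator is constant; need two groups")
    X = np.column_stack([np.ones(study.n_samples), z, study.covariates])
    return X, z


def taxon_tests(
    pseudo: PseudoValueMatrix,
    study: GroupedStudy,
    lts: LtsConfig | None = None,
    alpha: float = 0.05,
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Fit the pseudo-value regression for every taxon and test beta_k = 0.

    Returns a DataFrame indexed by taxon with the group coefficient, its
    standard error, t statistic, p-value, q-value, the DC call at level
    ``alpha``, and one column per covariate coefficient.  A taxon whose LTS
    fit fails is reported as an all-NaN row rather than aborting the run.
    """
    lts = lts or LtsConfig()
    X, _ = _design_matrix(study)
    values = pseudo.values
    if values.shape[0] != study.n_samples:
        raise InputError("pseudo-value rows must align with study samples")
    p_taxa = values.shape[1]
    rows = []
    for k in range(p_taxa):
        cfg_k = LtsConfig(
            coverage_fraction=lts.coverage_fraction,
            n_initial_subsets=lts.n_initial_subsets,
            n_csteps=lts.n_csteps,
            reweight_cutoff=lts.reweight_cutoff,
            seed=lts.seed + k,
        )
        try:
            fit = fit_lts(values[:, k], X, cfg_k)
            beta, se = fit.coefficients[1], fit.standard_errors[1]
            if se > 0:
                t_stat = beta / se
                p_val = 2.0 * stats.t.sf(np.abs(t_stat), fit.df)
            else:
                t_stat = np.inf * np.sign(beta) if beta != 0 else 0.0
                p_val = 0.0 if beta != 0 else 1.0
            rows.append(
                [beta, se, t_stat, p_val]
                + list(fit.coefficients[2:])
                + [fit.coefficients[0]]
            )
        except EstimationError:
            rows.append([np.nan] * (4 + study.covariates.shape[1] + 1))
    cov_cols = [f"gamma_{name}" for name in study.covariate_names]
    out = pd.DataFrame(
        rows,
        index=pd.Index(pseudo.taxon_ids, name="taxon"),
        columns=["beta", "se", "t_stat", "p_value"] + cov_cols + ["intercept"],
    )
    pv = out["p_value"].to_numpy()
    ok = ~np.isnan(pv)
    q = np.full(p_taxa, np.nan)
    if ok.any():
        q[ok] = qvalues(pv[ok], method=qvalue_method)
    out["q_value"] = q
    out["is_dc"] = out["q_value"] < alpha
    return out


def differential_connectivity_test(
    study: GroupedStudy,
    sparcc_cfg: SparccConfig | None = None,
    lts_cfg: LtsConfig | None = None,
    alpha: float = 0.05,
    qvalue_method: str = "storey",
    n_jobs: int = 1,
) -> pd.DataFrame:
    """End-to-end pipeline: pseudo-values, per-taxon robust tests, q-values.

    The returned DataFrame carries the run configuration in ``.attrs`` for
    provenance (SparCC settings, LTS settings, alpha, q-value method, and
    the centrality convention).
    """
    sparcc_cfg = sparcc_cfg or SparccConfig()
    lts_cfg = lts_cfg or LtsConfig()
    pseudo = jackknife_pseudovalues(study, sparcc_cfg, n_jobs=n_jobs)
    result = taxon_tests(pseudo, study, lts_cfg, alpha, qvalue_method)
    result.attrs["config"] = {
        "sparcc": vars(sparcc_cfg).copy(),
        "lts": vars(lts_cfg).copy(),
        "alpha": alpha,
        "qvalue_method": qvalue_method,
        "centrality": "signed column sum, diagonal included",
    }
    return result


# Short alias used throughout the CLI and docs.
dc_test = differential_connectivity_test
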