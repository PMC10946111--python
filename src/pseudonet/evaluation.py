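"""Scoring DC calls against a known truth and the replicate benchmark loop.

A taxon is truly differentially connected (DC) when its neighbourhood differs
between the two group-specific truth adjacencies.  Calls are q-value
thresholded at an error rate alpha.  Four metrics summarise a replicate:

    precision = TP / (TP + FP)      recall   = TP / (TP + FN)
    F1 = harmonic mean of the two   accuracy = (TP + TN) / p

Ratios with a zero denominator are undefined for that replicate; by default
they are dropped from replicate means (zero-filling is available as a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .regression import LtsConfig, differential_connectivity_test
from .simulate import SimConfig, simulate_dataset, true_dc_labels  # noqa: F401
from .sparcc import InputError, SparccConfig

METRICS = ("precision", "recall", "f1", "accuracy")


@dataclass
class MetricsResult:
    precision: float
    recall: float
    f1: float
    accuracy: float
    n_true_dc: int
    n_called_dc: int
    alpha: float
    replicate: int = 0


def compute_metrics(
    q_values: np.ndarray,
    eta: np.ndarray,
    alpha: float = 0.05,
    replicate: int = 0,
) -> MetricsResult:
    """Contingency metrics of q < alpha calls against truth labels.

    Undefined ratios (no calls for precision, no true DC taxa for recall,
    either for F1) are returned as NaN.
    """
    q = np.asarray(q_values, dtype=float)
    eta = np.asarray(eta)
    if q.shape != eta.shape:
        raise InputError("q-value and truth vectors must align")
    called = q < alpha
    truth = eta == 1
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    tn = int(np.sum(~called & ~truth))
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / q.size
    return MetricsResult(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        n_true_dc=int(truth.sum()),
        n_called_dc=int(called.sum()),
        alpha=alpha,
        replicate=replicate,
    )


def run_benchmark(
    cfg: SimConfig,
    replicates: int = 50,
    alpha: float = 0.05,
    sparcc_cfg: SparccConfig | None = None,
    lts_cfg: LtsConfig | None = None,
    qvalue_method: str = "storey",
    n_jobs: int = 1,
    undefined: str = "drop",
) -> pd.DataFrame:
    """Monte-Carlo benchmark: simulate, run the full pipeline, score, average.

    A fresh truth network is drawn for every replicate (the replicate index is
    folded into the seed).  Returns a one-row DataFrame with per-metric means
    and Monte-Carlo standard errors; the per-replicate table is attached as
    ``.attrs["replicates"]``.
    """
    if replicates < 1:
        raise InputError("need at least one replicate")
    if undefined not in ("drop", "zero"):
        raise InputError("undefined must be 'drop' or 'zero'")
    sparcc_cfg = sparcc_cfg or SparccConfig()
    lts_cfg = lts_cfg or LtsConfig()
    records = []
    failures = 0
    for s in range(replicates):
        rep_cfg = replace(cfg, seed=cfg.seed + s)
        try:
            sim = simulate_dataset(rep_cfg)
            result = differential_connectivity_test(
                sim.study,
                sparcc_cfg=sparcc_cfg,
                lts_cfg=lts_cfg,
                alpha=alpha,
                qvalue_method=qvalue_method,
                n_jobs=n_jobs,
            )
            m = compute_metrics(
                result["q_value"].to_numpy(), sim.truth.eta, alpha, replicate=s
            )
            records.append(vars(m))
        except Exception:
            failures += 1
    if not records:
        raise RuntimeError("every benchmark replicate failed")
    reps = pd.DataFrame.from_records(records)
    if undefined == "zero":
        reps[list(METRICS)] = reps[list(METRICS)].fillna(0.0)
    summary = {}
    for metric in METRICS:
        vals = reps[metric].dropna()
        summary[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
        summary[f"{metric}_se"] = (
            vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        )
        summary[f"{metric}_n"] = len(vals)
    summary.update(
        p=cfg.p,
        n=cfg.n,
        delta1=cfg.delta1,
        delta2=cfg.delta2,
        replicates=replicates,
        failures=failures,
        alpha=alpha,
    )
    out = pd.DataFrame([summary])
    out.attrs["replicates"] = reps
    return out
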