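"""Degree centrality and group-specific jackknife pseudo-values.

The connectivity summary for taxon k is its degree centrality: the marginal
(column) sum of the association matrix, diagonal included.  Comparing the
centrality between two biological groups directly would leave no room for
covariate adjustment, so each subject is instead assigned a leave-one-out
jackknife pseudo-value

    theta~_ik = n_z * theta^_k(group z) - (n_z - 1) * theta^_k(group z minus i)

computed within the subject's own group.  Pseudo-values behave approximately
like i.i.d. subject-level responses and can be regressed on the group
indicator plus clinical covariates.

A paired two-timepoint variant replaces the association matrix by the
difference of the matrices estimated at the two timepoints, capturing the
temporal change of connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .sparcc import (
    AssociationMatrix,
    CountTable,
    InputError,
    SparccConfig,
    sparcc,
)


@dataclass
class GroupedStudy:
    """A count table with a binary group label and clinical covariates."""

    counts: CountTable
    group: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        n = self.counts.n_samples
        if self.group.shape != (n,):
            raise InputError("group vector length must match sample count")
        labels = np.unique(self.group)
        if len(labels) != 2:
            raise InputError(
                f"group must take exactly two values, got {labels.tolist()}"
            )
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != n:
            raise InputError("covariate rows must match sample count")
        if not self.covariate_names:
            self.covariate_names = [
                f"X{m + 1}" for m in range(self.covariates.shape[1])
            ]
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise InputError("covariate names do not match covariate columns")
        for lab in labels:
            n_z = int(np.sum(self.group == lab))
            if n_z < 4:
                raise InputError(
                    f"group {lab!r} has {n_z} samples; need at least 4 "
                    "(leave-one-out estimation requires 3 remaining)"
                )

    @property
    def group_labels(self) -> np.ndarray:
        return np.unique(self.group)

    @property
    def n_samples(self) -> int:
        return self.counts.n_samples

    @property
    def n_taxa(self) -> int:
        return self.counts.n_taxa


@dataclass
class CentralityVector:
    theta: np.ndarray
    group_label: object = None


@dataclass
class PseudoValueMatrix:
    """n x p matrix of pseudo-values, rows in original sample order."""

    values: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.taxon_ids:
            self.taxon_ids = [f"taxon{j}" for j in range(self.values.shape[1])]


def degree_centrality(assoc: AssociationMatrix) -> CentralityVector:
    """Signed column sums of the association matrix, diagonal included."""
    return CentralityVector(theta=assoc.rho.sum(axis=0))


def _group_centralities(
    table: CountTable, config: SparccConfig, n_jobs: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Full-sample and all leave-one-out centralities for one group."""
    n_z = table.n_samples
    theta_full = degree_centrality(sparcc(table, config)).theta

    def loo(i: int) -> np.ndarray:
        keep = np.delete(np.arange(n_z), i)
        return degree_centrality(sparcc(table.subset_samples(keep), config)).theta

    if n_jobs == 1:
        theta_loo = [loo(i) for i in range(n_z)]
    else:
        theta_loo = Parallel(n_jobs=n_jobs)(delayed(loo)(i) for i in range(n_z))
    return theta_full, np.vstack(theta_loo)


def _pseudovalues(theta_full: np.ndarray, theta_loo: np.ndarray) -> np.ndarray:
    n_z = theta_loo.shape[0]
    return n_z * theta_full[None, :] - (n_z - 1) * theta_loo


def jackknife_pseudovalues(
    study: GroupedStudy,
    config: SparccConfig | None = None,
    n_jobs: int = 1,
) -> PseudoValueMatrix:
    """Group-specific leave-one-out pseudo-values of degree centrality.

    Per group: estimate the association matrix on the whole group, re-estimate
    leaving out each subject in turn, and combine into pseudo-values.  Rows
    are returned in the original sample order.  Parallel execution over
    leave-one-out refits is order-independent.
    """
    config = config or SparccConfig()
    n, p = study.n_samples, study.n_taxa
    values = np.empty((n, p))
    for lab in study.group_labels:
        idx = np.where(study.group == lab)[0]
        table = study.counts.subset_samples(idx)
        theta_full, theta_loo = _group_centralities(table, config, n_jobs)
        values[idx] = _pseudovalues(theta_full, theta_loo)
    return PseudoValueMatrix(values=values, taxon_ids=list(study.counts.taxon_ids))


def _check_paired(study_t1: GroupedStudy, study_t2: GroupedStudy) -> None:
    if study_t1.counts.sample_ids != study_t2.counts.sample_ids:
        raise InputError("paired timepoints must share the same subjects")
    if study_t1.counts.taxon_ids != study_t2.counts.taxon_ids:
        raise InputError("paired timepoints must share the same taxa")
    if not np.array_equal(study_t1.group, study_t2.group):
        raise InputError("paired timepoints must share group labels")


def paired_difference_pseudovalues(
    study_t1: GroupedStudy,
    study_t2: GroupedStudy,
    config: SparccConfig | None = None,
    n_jobs: int = 1,
) -> PseudoValueMatrix:
    """Pseudo-values of the change in centrality between two timepoints.

    Per group, the association matrices are estimated at both timepoints and
    differenced (t2 minus t1); centralities are marginal sums of the
    difference.  Leave-one-out removes the subject from both timepoints.
    """
    config = config or SparccConfig()
    _check_paired(study_t1, study_t2)
    n, p = study_t1.n_samples, study_t1.n_taxa
    values = np.empty((n, p))
    for lab in study_t1.group_labels:
        idx = np.where(study_t1.group == lab)[0]
        t1 = study_t1.counts.subset_samples(idx)
        t2 = study_t2.counts.subset_samples(idx)
        n_z = len(idx)

        def diff_theta(keep: np.ndarray) -> np.ndarray:
            d = (
                sparcc(t2.subset_samples(keep), config).rho
                - sparcc(t1.subset_samples(keep), config).rho
            )
            return d.sum(axis=0)

        all_idx = np.arange(n_z)
        theta_full = diff_theta(all_idx)

        def loo(i: int) -> np.ndarray:
            return diff_theta(np.delete(all_idx, i))

        if n_jobs == 1:
            theta_loo = [loo(i) for i in range(n_z)]
        else:
            theta_loo = Parallel(n_jobs=n_jobs)(delayed(loo)(i) for i in range(n_z))
        values[idx] = _pseudovalues(theta_full, np.vstack(theta_loo))
    return PseudoValueMatrix(
        values=values, taxon_ids=list(study_t1.counts.taxon_ids)
    )
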