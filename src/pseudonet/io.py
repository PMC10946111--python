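"""Reading and writing study tables.

Counts are tab-separated text with samples as rows (first column the sample
id, header row of taxon ids); the transposed dialect (taxa as rows) is
accepted via a flag.  Metadata is comma-separated with one row per sample.
Results are written as tab-separated text with the run configuration echoed
in a ``#``-prefixed header block.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .jackknife import GroupedStudy
from .sparcc import CountTable, InputError

logger = logging.getLogger("pseudonet")


def read_counts(path: str | Path, taxa_are_rows: bool = False) -> CountTable:
    """Read a TSV count table into a samples-by-taxa CountTable."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"could not parse count table {path}: {exc}") from exc
    if taxa_are_rows:
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InputError(f"non-numeric entries in count table {path}")
    if np.any(values < 0) or np.any(values != np.floor(values)):
        raise InputError(f"counts in {path} must be non-negative integers")
    return CountTable(
        counts=values.astype(int),
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
    )


def write_counts(table: CountTable, path: str | Path, taxa_are_rows: bool = False) -> None:
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.taxon_ids)
    df.index.name = "sample_id"
    if taxa_are_rows:
        df = df.T
        df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_study(
    counts_path: str | Path,
    metadata_path: str | Path,
    group_col: str,
    covariate_cols: list[str] | None = None,
    taxa_are_rows: bool = False,
) -> GroupedStudy:
    """Join a count table with sample metadata into a GroupedStudy.

    Samples are inner-joined on sample id; samples with a missing group label
    or covariate value are dropped with a logged warning.
    """
    covariate_cols = covariate_cols or []
    table = read_counts(counts_path, taxa_are_rows)
    try:
        meta = pd.read_csv(metadata_path, index_col=0)
    except Exception as exc:  # pragma: no cover
        raise InputError(f"could not parse metadata {metadata_path}: {exc}") from exc
    meta.index = meta.index.astype(str)
    missing_cols = [c for c in [group_col, *covariate_cols] if c not in meta.columns]
    if missing_cols:
        raise InputError(f"metadata lacks columns {missing_cols}")
    shared = [s for s in table.sample_ids if s in meta.index]
    if not shared:
        raise InputError("no sample ids shared between counts and metadata")
    dropped_join = set(table.sample_ids) ^ set(meta.index)
    if dropped_join:
        logger.warning(
            "dropping %d samples absent from one of the two tables", len(dropped_join)
        )
    meta = meta.loc[shared, [group_col, *covariate_cols]]
    complete = meta.notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d samples with missing group/covariate values: %s",
            (~complete).sum(),
            list(meta.index[~complete]),
        )
    meta = meta[complete]
    keep_ids = list(meta.index)
    idx = [table.sample_ids.index(s) for s in keep_ids]
    table = table.subset_samples(np.array(idx))
    group = meta[group_col].to_numpy()
    covariates = _encode_covariates(meta[covariate_cols]) if covariate_cols else None
    return GroupedStudy(
        counts=table,
        group=group,
        covariates=covariates,
        covariate_names=covariate_cols,
    )


def _encode_covariates(df: pd.DataFrame) -> np.ndarray:
    """Numeric covariates pass through; two-level strings become 0/1."""
    cols = []
    for c in df.columns:
        col = df[c]
        if np.issubdtype(col.dtype, np.number):
            cols.append(col.to_numpy(dtype=float))
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise InputError(
                    f"covariate {c!r} has {len(levels)} levels; encode it numerically"
                )
            cols.append((col.astype(str) == levels[-1]).to_numpy(dtype=float))
    return np.column_stack(cols)


def prevalence_filter(study: GroupedStudy, min_prevalence: float) -> GroupedStudy:
    """Drop taxa observed (nonzero) in fewer than ``min_prevalence`` of samples."""
    if not (0 <= min_prevalence <= 1):
        raise InputError("min_prevalence must lie in [0, 1]")
    counts = study.counts.counts
    prevalence = (counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if min_prevalence == 0:
        keep = np.ones(counts.shape[1], dtype=bool)
    if not keep.any():
        raise InputError("prevalence filter removed every taxon")
    removed = [t for t, k in zip(study.counts.taxon_ids, keep) if not k]
    if removed:
        logger.warning("prevalence filter removed %d taxa: %s", len(removed), removed)
    table = CountTable(
        counts=counts[:, keep],
        sample_ids=list(study.counts.sample_ids),
        taxon_ids=[t for t, k in zip(study.counts.taxon_ids, keep) if k],
    )
    return GroupedStudy(
        counts=table,
        group=study.group,
        covariates=study.covariates,
        covariate_names=list(study.covariate_names),
    )


def write_results(result: pd.DataFrame, path: str | Path) -> None:
    """Write a DC result table as TSV with its config echoed as comments."""
    path = Path(path)
    with path.open("w") as fh:
        config = result.attrs.get("config")
        if config:
            for line in json.dumps(config, indent=None, default=str).splitlines():
                fh.write(f"# {line}\n")
        result.to_csv(fh, sep="\t")


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "base_adjacency": truth.base_adjacency.tolist(),
        "omega1": truth.omega[0].tolist(),
        "omega2": truth.omega[1].tolist(),
        "spiked1": truth.spiked[0].tolist(),
        "spiked2": truth.spiked[1].tolist(),
        "eta": truth.eta.tolist(),
    }
    Path(path).write_text(json.dumps(payload))
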