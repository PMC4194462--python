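"""Expression-matrix handling: probe collapsing, missing-data filters, merging.

An expression matrix is a :class:`pandas.DataFrame` of log2-scale expression
values with genes as the index and samples as the columns.  Missing values
are ``NaN`` (written as empty cells in TSV).  All coverage fractions are
computed over non-missing counts.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_probe_map",
    "collapse_probes",
    "filter_expression",
    "merge_experiments",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column ``gene_id``, empty cell = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    _check_unique(df.index, "gene ids")
    _check_unique(df.columns, "sample ids")
    return df


def write_expression_tsv(E: pd.DataFrame, path) -> None:
    """Write an expression matrix; round-trips finite values bit-stably."""
    E.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


def read_probe_map(path) -> pd.DataFrame:
    """Read a probe-to-gene conversion table with columns ``probe_id``, ``gene_id``."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"probe_id", "gene_id"} - set(pm.columns)
    if missing:
        raise ValueError(f"probe map lacks columns: {sorted(missing)}")
    return pm.drop_duplicates()


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what}")


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.DataFrame,
                    mode: str = "elementwise-max") -> pd.DataFrame:
    """Convert a probes x samples matrix into a genes x samples matrix.

    Probes mapping to more than one gene are dropped.  When several probes
    map to one gene, the gene's value is, per sample, the maximum over its
    probes (missing values ignored; a sample missing on every probe stays
    missing).  ``mode="max-mean"`` instead keeps, per gene, the single probe
    with the highest mean expression.

    Parameters
    ----------
    probe_matrix : DataFrame indexed by probe id.
    probe_map : DataFrame with columns ``probe_id`` and ``gene_id``.
    """
    if probe_matrix.empty:
        raise ValueError("empty probe matrix")
    pm = probe_map[["probe_id", "gene_id"]].drop_duplicates()
    if pm.empty:
        raise ValueError("no mapping")
    # single probes matching more than one gene are removed
    per_probe = pm.groupby("probe_id")["gene_id"].nunique()
    ambiguous = set(per_probe.index[per_probe > 1])
    pm = pm[~pm["probe_id"].isin(ambiguous)]
    pm = pm[pm["probe_id"].isin(probe_matrix.index)]
    if pm.empty:
        return probe_matrix.iloc[:0].copy().rename_axis("gene_id")

    sub = probe_matrix.loc[pm["probe_id"]]
    sub.index = pd.Index(pm["gene_id"].to_numpy(), name="gene_id")
    if mode == "elementwise-max":
        out = sub.groupby(level=0).max()  # skips NaN; all-NaN stays NaN
    elif mode == "max-mean":
        means = sub.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        ranked = sub.iloc[order]
        out = ranked[~ranked.index.duplicated(keep="first")]
        out = out.sort_index()
    else:
        raise ValueError(f"unknown collapse mode: {mode!r}")
    return out


def filter_expression(E: pd.DataFrame, common_genes: Iterable[str] | None = None,
                      sample_min: float = 0.5, gene_min: float = 0.75) -> pd.DataFrame:
    """Two-stage missing-data filter.

    Stage 1 removes samples with observed values for less than ``sample_min``
    of the common gene list; stage 2 then removes genes observed in less than
    ``gene_min`` of the remaining samples.  The stage order is fixed.
    """
    if not (0 <= sample_min <= 1 and 0 <= gene_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    common = pd.Index(sorted(set(common_genes))) if common_genes is not None else E.index
    common = common.intersection(E.index)
    if len(common) == 0:
        raise ValueError("no common genes present in matrix")

    cover = E.loc[common].notna().sum(axis=0) / len(common)
    kept_samples = cover.index[(cover >= sample_min) | (sample_min == 0)]
    if len(kept_samples) == 0:
        raise ValueError("empty after sample filter")
    E1 = E[kept_samples]

    gene_cover = E1.notna().sum(axis=1) / E1.shape[1]
    kept_genes = gene_cover.index[(gene_cover >= gene_min) | (gene_min == 0)]
    return E1.loc[kept_genes]


def merge_experiments(matrices: Sequence[pd.DataFrame],
                      labels: Sequence[str] | None = None,
                      gene_mode: str = "intersection") -> pd.DataFrame:
    """Merge per-experiment matrices into one multi-experiment matrix.

    Sample columns are concatenated under experiment-tagged ids
    (``label:sample``); values are not re-normalised.  The common gene list
    is the intersection of the input gene sets by default
    (``gene_mode="union"`` keeps genes present in any input, with missing
    cells where an experiment lacks the gene).
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to merge")
    if labels is None:
        labels = [f"exp{i + 1}" for i in range(len(matrices))]
    if len(labels) != len(matrices):
        raise ValueError("labels/matrices length mismatch")

    if gene_mode == "intersection":
        genes = matrices[0].index
        for M in matrices[1:]:
            genes = genes.intersection(M.index)
        if len(genes) == 0:
            raise ValueError("empty common gene list")
    elif gene_mode == "union":
        genes = matrices[0].index
        for M in matrices[1:]:
            genes = genes.union(M.index)
    else:
        raise ValueError(f"unknown gene_mode: {gene_mode!r}")
    genes = genes.sort_values()

    parts = []
    for lab, M in zip(labels, matrices):
        part = M.reindex(genes)
        part.columns = [f"{lab}:{c}" for c in M.columns]
        parts.append(part)
    merged = pd.concat(parts, axis=1)
    if merged.columns.duplicated().any():
        raise ValueError("duplicate sample ids after tagging")
    merged.index.name = "gene_id"
    return merged
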