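"""Per-layer normalization chains.

Three chains are implemented:

* ATAC peak counts: log2-CPM with a library-scaled pseudo-count, quantile
  normalization across the cohort, then log-scale averaging of technical
  replicates.
* RNA counts: the same log2-CPM transform (a documented stand-in for a
  variance-stabilizing transform; the linkage statistics only require an
  approximately linear log-scale value).
* TMT-style peptide intensities: missing-value fill with the run minimum,
  per-channel rescaling to the reference-channel total, peptide-to-gene
  rollup as sample/reference ratios, log2, and replicate averaging.

Gene-body accessibility is an RPKM (reads over the gene body excluding
promoter peaks, per kb and per million library reads) quantile-normalized
across the cohort.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "log_cpm",
    "quantile_normalize",
    "average_replicates",
    "transform_rna",
    "rollup_protein",
    "gene_body_rpkm",
    "normalize_atac",
]

DEFAULT_PRIOR_COUNT = 5.0


def log_cpm(counts: pd.DataFrame, prior: float = DEFAULT_PRIOR_COUNT) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled pseudo-count.

    For column ``j`` with library size ``L_j`` and scaled prior
    ``p_j = prior * L_j / mean(L)``::

        value = log2((c + p_j) / (L_j + 2 * p_j) * 1e6)

    Strictly monotone in counts within a column; raises on a zero library.
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("raw counts must be non-negative")
    lib = values.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    pj = prior * lib / lib.mean()
    out = np.log2((values + pj) / (lib + 2.0 * pj) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the shared reference distribution.

    The reference is the row-wise mean of the column-sorted values; each
    column is mapped to it by rank.  Ties within a column receive the mean
    of the tied reference quantiles, making the result deterministic and
    order-independent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average assigned reference values across tied input values
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_replicates(
    matrix: pd.DataFrame, replicate_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Average technical-replicate columns (on the log scale).

    ``replicate_groups`` maps each output sample id to its replicate column
    ids.  A group with zero columns is an error.
    """
    cols = {}
    for sample, members in replicate_groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"replicate group {sample!r} has no columns")
        missing = [m for m in members if m not in matrix.columns]
        if missing:
            raise KeyError(f"replicate columns not in matrix: {missing}")
        cols[sample] = matrix[members].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.index)


def transform_rna(counts: pd.DataFrame, prior: float = DEFAULT_PRIOR_COUNT) -> pd.DataFrame:
    """Log-scale RNA transform (delegates to :func:`log_cpm`)."""
    return log_cpm(counts, prior=prior)


def normalize_atac(
    counts: pd.DataFrame,
    replicate_groups: Mapping[str, Sequence[str]],
    prior: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """Full ATAC chain: log2-CPM, quantile normalization, replicate average."""
    return average_replicates(quantile_normalize(log_cpm(counts, prior)), replicate_groups)


def rollup_protein(peptides: pd.DataFrame) -> pd.DataFrame:
    """Roll a long-format peptide table up to gene-level log2 ratios.

    ``peptides`` columns: ``peptide_id, gene_id, run_id, channel_id,
    sample_id, is_reference, intensity`` (missing intensities as NaN; the
    ``sample_id`` of reference channels is ignored).  Per run:

    1. missing peptide intensities are set to the run minimum (the smallest
       observed intensity over all peptides and channels in that run);
    2. each channel is rescaled so its total equals the total abundance of
       the run's reference channels;
    3. per gene, ratio = sum of sample-channel peptides over sum of
       reference-channel peptides (intensity-weighted rollup);
    4. ratios are log2 transformed;
    5. technical replicates (the same sample measured in several runs) are
       averaged.

    A gene with no detected peptides in a run is absent (NaN) from that
    run's samples, not zero.
    """
    required = {"peptide_id", "gene_id", "run_id", "channel_id", "is_reference", "intensity"}
    missing_cols = required - set(peptides.columns)
    if missing_cols:
        raise ValueError(f"peptide table missing columns: {sorted(missing_cols)}")

    frames = []
    for run_id, run in peptides.groupby("run_id", sort=True):
        refs = run[run["is_reference"]]
        if refs.empty:
            raise ValueError(f"run {run_id!r} has no reference channel")
        intensities = run["intensity"].to_numpy(dtype=float)
        observed = intensities[np.isfinite(intensities)]
        if observed.size == 0:
            raise ValueError(f"run {run_id!r} has no observed intensities")
        run = run.assign(intensity=np.where(np.isfinite(intensities), intensities, observed.min()))

        ref_total = run.loc[run["is_reference"], "intensity"].sum()
        channel_totals = run.groupby("channel_id")["intensity"].transform("sum")
        run = run.assign(intensity=run["intensity"] * ref_total / channel_totals)

        ref_sums = (
            run[run["is_reference"]].groupby("gene_id")["intensity"].sum()
        )
        sample_rows = run[~run["is_reference"]]
        sums = sample_rows.groupby(["gene_id", "sample_id"])["intensity"].sum().unstack()
        ratios = np.log2(sums.div(ref_sums.reindex(sums.index), axis=0))
        frames.append(ratios)

    # replicate average: mean of log2 ratios across runs sharing a sample id
    combined = pd.concat(frames, axis=1)
    out = combined.T.groupby(level=0).mean().T
    return out.sort_index()


def gene_body_rpkm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
    quantile: bool = True,
) -> pd.DataFrame:
    """Gene-body accessibility RPKM, quantile-normalized across the cohort.

    ``counts`` holds per-sample ATAC insertions over each gene body
    (promoter-peak bp already excluded upstream).  RPKM divides by the gene
    length in kb and the library size in millions; ``library_sizes``
    defaults to the column sums of ``counts``.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("gene length missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("zero-length gene")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (lib <= 0).any():
        raise ValueError("non-positive library size")
    rpkm = counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)
    if quantile and rpkm.shape[1] >= 2:
        rpkm = quantile_normalize(rpkm)
    return rpkm
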