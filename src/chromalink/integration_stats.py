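"""Cross-omic correlation statistics and enrichment tests.

Sample-wise correlations pair, for each linked element-gene, the Pearson
correlation of element accessibility with RNA and the Spearman correlation
of protein with RNA across samples; a pair is "high paired" when both
exceed 0.5.  Gene-wise correlation relates per-comparison log fold changes
of RNA and protein across genes.  The differential non-promoter activity
score sums log fold changes of a gene's differential non-promoter peaks,
and the exon/intron enrichment test compares the exonic fraction of active
non-promoter elements against the exonic length fraction of the gene
bodies by an exact binomial tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HIGH_PAIRED_THRESHOLD",
    "ActivityScore",
    "sample_wise_correlations",
    "classify_paired",
    "gene_wise_correlation",
    "np_activity_score",
    "exonic_enrichment_test",
    "rna_abundance_by_correlation_bin",
]

#: both correlations must exceed this for a pair to count as high paired
HIGH_PAIRED_THRESHOLD = 0.5

MIN_SHARED_SAMPLES = 6


@dataclass(frozen=True)
class ActivityScore:
    """Summed log2 fold change of a gene's differential non-promoter peaks."""

    gene_id: str
    comparison: str
    score: float
    n_peaks: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def sample_wise_correlations(
    element_matrix: pd.DataFrame,
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    pairs: pd.DataFrame,
    element_method: str = "pearson",
    protein_method: str = "spearman",
) -> pd.DataFrame:
    """Per linked pair: element-RNA and protein-RNA correlations.

    ``pairs`` needs columns ``element_id`` and ``gene_id`` (a gene's own
    accessibility can serve as a pseudo-element by using the gene id as
    element id).  Correlations run over the samples shared by all three
    matrices; protein NaNs are dropped pairwise.  Pairs with constant
    vectors or fewer than 6 usable samples are skipped with a warning.
    """
    shared = [
        c for c in rna.columns if c in set(element_matrix.columns) & set(protein.columns)
    ]
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError(f"fewer than {MIN_SHARED_SAMPLES} shared samples")
    corr = {"pearson": _pearson, "spearman": lambda x, y: float(stats.spearmanr(x, y)[0])}
    f_elem = corr[element_method]
    f_prot = corr[protein_method]

    rows, skipped = [], 0
    e_mat = element_matrix[shared]
    r_mat = rna[shared]
    p_mat = protein[shared]
    for element_id, gene_id in pairs[["element_id", "gene_id"]].itertuples(index=False):
        if element_id not in e_mat.index or gene_id not in r_mat.index or gene_id not in p_mat.index:
            skipped += 1
            continue
        e = e_mat.loc[element_id].to_numpy(dtype=float)
        r = r_mat.loc[gene_id].to_numpy(dtype=float)
        p = p_mat.loc[gene_id].to_numpy(dtype=float)
        ok = np.isfinite(p) & np.isfinite(r) & np.isfinite(e)
        if ok.sum() < MIN_SHARED_SAMPLES:
            skipped += 1
            continue
        e, r, p = e[ok], r[ok], p[ok]
        if e.std() == 0 or r.std() == 0 or p.std() == 0:
            skipped += 1
            continue
        r_elem_rna = f_elem(e, r)
        r_prot_rna = f_prot(p, r)
        rows.append(
            {
                "element_id": element_id,
                "gene_id": gene_id,
                "r_elem_rna": r_elem_rna,
                "r_prot_rna": r_prot_rna,
                "high_paired": min(r_elem_rna, r_prot_rna) > HIGH_PAIRED_THRESHOLD,
            }
        )
    if skipped:
        warnings.warn(f"{skipped} pair(s) skipped (missing, constant or too few samples)")
    return pd.DataFrame(
        rows, columns=["element_id", "gene_id", "r_elem_rna", "r_prot_rna", "high_paired"]
    )


def classify_paired(
    pairs: pd.DataFrame,
    differential: pd.Series | dict,
    element_class: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Fraction of high-paired pairs per differential category.

    ``differential`` maps gene_id -> bool; ``element_class`` optionally maps
    element_id -> {promoter, non_promoter} to stratify.  Empty categories
    are reported with NaN fraction and flagged ``undefined``.
    """
    diff = pd.Series(differential)
    df = pairs.copy()
    df["category"] = np.where(
        df["gene_id"].map(diff).fillna(False), "differential", "not_differential"
    )
    if element_class is not None:
        df["element_class"] = df["element_id"].map(pd.Series(element_class))
        group_cols = ["element_class", "category"]
    else:
        df["element_class"] = "all"
        group_cols = ["element_class", "category"]
    rows = []
    for eclass in df["element_class"].dropna().unique():
        for cat in ("not_differential", "differential"):
            sub = df[(df["element_class"] == eclass) & (df["category"] == cat)]
            n = len(sub)
            n_high = int(sub["high_paired"].sum())
            rows.append(
                {
                    "element_class": eclass,
                    "category": cat,
                    "n_pairs": n,
                    "n_high_paired": n_high,
                    "frac_high_paired": n_high / n if n else np.nan,
                    "undefined": n == 0,
                }
            )
    return pd.DataFrame(rows)


def gene_wise_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation and sign concordance of RNA vs protein logFC.

    ``records`` needs columns ``rna_logFC`` and ``protein_logFC``.  A zero
    fold change on either side counts as non-concordant.  Requires at
    least 3 records.
    """
    if len(records) < 3:
        raise ValueError("gene-wise correlation needs at least 3 records")
    x = records["rna_logFC"].to_numpy(dtype=float)
    y = records["protein_logFC"].to_numpy(dtype=float)
    rho = float(stats.spearmanr(x, y)[0])
    concordance = float(np.mean(x * y > 0))
    return rho, concordance


def np_activity_score(
    gene_id: str, comparison: str, differential_np: pd.DataFrame
) -> ActivityScore:
    """Sum of log2 fold changes of a gene's differential non-promoter peaks.

    ``differential_np`` needs columns ``gene_id``, ``comparison`` and
    ``logFC``, already restricted to differential non-promoter links.  An
    empty contribution set yields score 0 with ``n_peaks = 0``.
    """
    sub = differential_np[
        (differential_np["gene_id"] == gene_id)
        & (differential_np["comparison"] == comparison)
    ]
    return ActivityScore(
        gene_id, comparison, float(sub["logFC"].sum()), int(len(sub))
    )


def exonic_enrichment_test(
    n_exonic: int, n_intronic: int, expected_exonic_fraction: float
) -> float:
    """Exact upper-tail binomial p for exonic enrichment.

    ``P(X >= n_exonic)`` with ``n = n_exonic + n_intronic`` trials at the
    expected exonic rate (typically the mean exonic length fraction of the
    analyzed gene bodies).
    """
    if n_exonic < 0 or n_intronic < 0:
        raise ValueError("counts must be non-negative")
    n = n_exonic + n_intronic
    if n == 0:
        raise ValueError("no elements to test")
    if not 0.0 < expected_exonic_fraction < 1.0:
        raise ValueError("expected fraction must lie in (0, 1)")
    return float(
        stats.binomtest(n_exonic, n, expected_exonic_fraction, alternative="greater").pvalue
    )


def rna_abundance_by_correlation_bin(
    correlations: pd.Series, rna_means: pd.Series, bins: int = 5
) -> pd.DataFrame:
    """Descriptive helper: mean RNA abundance per protein-RNA correlation bin."""
    df = pd.DataFrame({"r": correlations, "rna": rna_means}).dropna()
    df["bin"] = pd.cut(df["r"], bins=bins)
    out = df.groupby("bin", observed=True)["rna"].agg(["count", "mean"]).reset_index()
    return out.rename(columns={"count": "n_genes", "mean": "mean_rna_abundance"})
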