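"""Two-group differential statistics and per-layer differential flags.

Differential features are called with a Welch two-sample t-test on
normalized log-scale values, one test per feature and pairwise state
comparison, with Benjamini-Hochberg correction applied within each
layer x comparison.  Layer-specific FDR thresholds follow the analysis
conventions: 0.01 for peak accessibility, 0.1 for RNA, protein and
gene-accessibility layers.  A gene counts as differentially expressed if it
is significant at RNA or protein level in any pairwise comparison.
"""

from __future__ import annotations

import itertools
import warnings
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_FDR",
    "two_group_test",
    "welch_many",
    "bh_adjust",
    "call_differential",
    "gene_differential_flags",
]

DEFAULT_FDR = {
    "atac_peak": 0.01,
    "rna": 0.1,
    "protein": 0.1,
    "gene_accessibility": 0.1,
}


def welch_many(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t-test of ``b`` against ``a`` (features x samples).

    Returns ``(logFC, t, p)`` with ``logFC = mean(b) - mean(a)`` on the
    log-scale input.  Rows where both groups are constant with equal means
    get ``p = 1``; constant rows with unequal means get ``p = 0``.
    NaN sample values are ignored per row (groups must keep >= 2 values).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.sum(np.isfinite(a), axis=1)
    nb = np.sum(np.isfinite(b), axis=1)
    if np.any(na < 2) or np.any(nb < 2):
        raise ValueError("each group needs at least 2 finite values per feature")
    ma = np.nanmean(a, axis=1)
    mb = np.nanmean(b, axis=1)
    va = np.nanvar(a, axis=1, ddof=1)
    vb = np.nanvar(b, axis=1, ddof=1)
    logfc = mb - ma
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.where(
        se2 > 0,
        2.0 * stats.t.sf(np.abs(t), np.where(se2 > 0, df, 1.0)),
        np.where(logfc == 0, 1.0, 0.0),
    )
    with np.errstate(invalid="ignore"):
        degenerate_t = np.sign(logfc) * np.where(logfc == 0, 0.0, np.inf)
    t = np.where(se2 > 0, t, degenerate_t)
    return logfc, t, p


def two_group_test(values, groups, order=None) -> tuple[float, float, float]:
    """Welch t-test of group2 vs group1 for a single feature.

    ``groups`` holds two labels aligned with ``values``; ``order`` fixes
    (group1, group2) — by default the order of first appearance — and
    ``logFC = mean(group2) - mean(group1)``.  Reversing ``order`` flips the
    sign of logFC and leaves p unchanged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(order) if order is not None else list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2 or not set(labels) == set(groups.tolist()):
        raise ValueError("exactly two groups required")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    logfc, t, p = welch_many(a[None, :], b[None, :])
    return float(logfc[0]), float(t[0]), float(p[0])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN inputs are excluded from the number of tests and propagated as NaN.
    Invariant to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def call_differential(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    layer: str,
    thresholds: dict[str, float] = DEFAULT_FDR,
    states: list[str] | None = None,
) -> pd.DataFrame:
    """All pairwise two-group tests for one omic layer.

    ``matrix`` is features x samples on a log scale; ``sample_sheet`` maps
    ``sample_id`` to ``state``.  For states in cohort order, each later
    state is compared against each earlier one (``logFC = later - earlier``),
    BH is applied within each comparison, and ``significant`` marks
    ``q < thresholds[layer]``.  Comparisons with fewer than two samples in
    a state are skipped with a warning.
    """
    if layer not in thresholds:
        raise KeyError(f"no FDR threshold for layer {layer!r}")
    fdr = thresholds[layer]
    sheet = sample_sheet.drop_duplicates("sample_id").set_index("sample_id")
    if states is None:
        states = list(dict.fromkeys(sheet["state"]))
    if len(states) < 2:
        raise ValueError("need at least two states")
    cols_by_state = {
        s: [c for c in matrix.columns if c in sheet.index and sheet.loc[c, "state"] == s]
        for s in states
    }
    records = []
    for s1, s2 in itertools.combinations(states, 2):
        c1, c2 = cols_by_state[s1], cols_by_state[s2]
        if len(c1) < 2 or len(c2) < 2:
            warnings.warn(f"skipping {s2}_vs_{s1}: fewer than 2 samples in a state")
            continue
        a = matrix[c1].to_numpy(dtype=float)
        b = matrix[c2].to_numpy(dtype=float)
        logfc, t, p = welch_many(a, b)
        q = bh_adjust(p)
        records.append(
            pd.DataFrame(
                {
                    "feature_id": matrix.index,
                    "comparison": f"{s2}_vs_{s1}",
                    "logFC": logfc,
                    "t": t,
                    "p": p,
                    "q": q,
                    "significant": q < fdr,
                }
            )
        )
    if not records:
        raise ValueError("no testable comparison")
    out = pd.concat(records, ignore_index=True)
    out.insert(1, "layer", layer)
    return out


def gene_differential_flags(
    rna_records: pd.DataFrame, protein_records: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-gene differential flags.

    A gene is flagged (``any_pairwise_rna_or_protein``) if significant in
    any pairwise comparison at the RNA or protein layer; per-layer
    per-comparison flags are retained in wide columns.
    """
    both = pd.concat([rna_records, protein_records], ignore_index=True)
    wide = (
        both.pivot_table(
            index="feature_id",
            columns=["layer", "comparison"],
            values="significant",
            aggfunc="any",
        )
        .fillna(False)
        .astype(bool)
    )
    wide.columns = [f"{layer}:{comp}" for layer, comp in wide.columns]
    wide.insert(0, "any_pairwise_rna_or_protein", wide.any(axis=1))
    wide.index.name = "gene_id"
    return wide.reset_index()
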