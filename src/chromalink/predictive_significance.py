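"""Protein predictive significance: interaction F-tests and Fisher comparison.

The core statistic asks whether regulatory-element accessibility adds
predictive value for protein abundance beyond RNA.  Gene-element pairs are
first categorized by differential status (a: neither differential, b: gene
expression only, c: element only, d: both).  Each pair is then fitted with

    protein ~ rna + rna * accessibility

and the added interaction term is assessed with a partial F-test against
the RNA-only reduced model (for a single added term, F equals the squared
t of the interaction coefficient).  After BH correction at FDR 0.05 within
the tested set, the counts of significant pairs are compared between two
categories with Fisher's exact test; that Fisher p is the protein
predictive significance.

Two protocols are implemented: the split protocol (patients are randomly
halved; one half supplies the differential categorization, the other the
F-tests, controlling selection bias) and the modified no-split protocol
for small cohorts, which uses a two-class "differentially active"
partition on the full cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "PREDICTIVE_FDR",
    "InteractionFit",
    "CategoryEnrichment",
    "split_samples",
    "categorize_pairs",
    "interaction_f_test",
    "fit_pairs",
    "protein_predictive_significance",
    "modified_predictive_significance",
]

PREDICTIVE_FDR = 0.05


@dataclass(frozen=True)
class InteractionFit:
    """Partial F-test of the RNA x accessibility interaction term."""

    F: float
    p: float
    n: int
    df_resid: int
    status: str = "ok"  # ok | collinear | perfect_fit


@dataclass(frozen=True)
class CategoryEnrichment:
    """Fisher comparison of significant-fit counts between two categories."""

    compare: tuple[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    fisher_p: float
    undefined: bool = False


def split_samples(
    sample_sheet: pd.DataFrame, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Randomly halve the cohort at the patient level.

    All of a patient's samples stay on the same side; the two sides differ
    by at most one patient.  Deterministic under ``seed``.
    """
    patients = list(dict.fromkeys(sample_sheet["patient_id"]))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    half = (len(order) + 1) // 2
    set_a = set(order[:half])
    a = [
        s
        for s, p in zip(sample_sheet["sample_id"], sample_sheet["patient_id"])
        if p in set_a
    ]
    b = [
        s
        for s, p in zip(sample_sheet["sample_id"], sample_sheet["patient_id"])
        if p not in set_a
    ]
    return a, b


def categorize_pairs(
    pairs: pd.DataFrame,
    gene_flags: pd.Series | dict,
    element_flags: pd.Series | dict,
) -> pd.DataFrame:
    """Four-way categorization of gene-element pairs from differential flags.

    a: neither differential; b: gene expression only; c: element only;
    d: both.  Pairs whose gene or element lacks a flag are excluded with a
    warning.
    """
    gf = pd.Series(gene_flags)
    ef = pd.Series(element_flags)
    df = pairs.copy()
    g = df["gene_id"].map(gf)
    e = df["element_id"].map(ef)
    missing = g.isna() | e.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} pair(s) missing differential flags; excluded")
        df, g, e = df[~missing], g[~missing], e[~missing]
    g = g.astype(bool)
    e = e.astype(bool)
    df = df.assign(
        category=np.select(
            [(~g) & (~e), g & (~e), (~g) & e, g & e],
            ["a", "b", "c", "d"],
            default="a",
        )
    )
    return df


def interaction_f_test(
    protein: np.ndarray, rna: np.ndarray, accessibility: np.ndarray
) -> InteractionFit:
    """Partial F-test for the added ``rna * accessibility`` term.

    Full model: ``protein = b0 + b1 * rna + b2 * (rna * accessibility)``;
    reduced model drops ``b2``.  ``F = (RSS_red - RSS_full) / (RSS_full /
    (n - 3))`` with an F(1, n-3) tail p.  A constant accessibility vector
    makes the interaction collinear with RNA and is flagged; a perfect fit
    is reported at the smallest positive p with a flag.
    """
    y = np.asarray(protein, dtype=float)
    x1 = np.asarray(rna, dtype=float)
    x2 = np.asarray(accessibility, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    n = y.size
    if n < 5:
        raise ValueError("interaction test needs at least 5 samples")
    inter = x1 * x2
    X_full = np.column_stack([np.ones(n), x1, inter])
    X_red = X_full[:, :2]
    if np.linalg.matrix_rank(X_full) < 3:
        return InteractionFit(np.nan, np.nan, n, n - 3, status="collinear")
    beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_f = float(np.sum((y - X_full @ beta_f) ** 2))
    rss_r = float(np.sum((y - X_red @ beta_r) ** 2))
    df_resid = n - 3
    if rss_f <= 1e-12 * (float(y @ y) + 1.0):  # numerically perfect fit
        return InteractionFit(np.inf, np.nextafter(0.0, 1.0), n, df_resid, "perfect_fit")
    F = max(rss_r - rss_f, 0.0) / (rss_f / df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    return InteractionFit(float(F), p, n, df_resid)


def fit_pairs(
    pairs: pd.DataFrame,
    protein: pd.DataFrame,
    rna: pd.DataFrame,
    accessibility: pd.DataFrame,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Run the interaction F-test for every gene-element pair.

    ``samples`` restricts the fit to a sample subset (set B in the split
    protocol).  Pairs that cannot be fitted (missing features, collinear
    accessibility) carry NaN p and a status column.
    """
    cols = samples if samples is not None else [
        c for c in rna.columns if c in set(protein.columns) & set(accessibility.columns)
    ]
    rows = []
    for rec in pairs.to_dict("records"):
        gid, eid = rec["gene_id"], rec["element_id"]
        if (
            gid not in protein.index
            or gid not in rna.index
            or eid not in accessibility.index
        ):
            rows.append({**rec, "F": np.nan, "p": np.nan, "status": "missing"})
            continue
        try:
            fit = interaction_f_test(
                protein.loc[gid, cols].to_numpy(dtype=float),
                rna.loc[gid, cols].to_numpy(dtype=float),
                accessibility.loc[eid, cols].to_numpy(dtype=float),
            )
        except ValueError:
            rows.append({**rec, "F": np.nan, "p": np.nan, "status": "too_few_samples"})
            continue
        rows.append({**rec, "F": fit.F, "p": fit.p, "status": fit.status})
    cols = list(pairs.columns) + ["F", "p", "status"]
    return pd.DataFrame(rows, columns=cols if not rows else None)


def _fisher_from_flags(
    sig: np.ndarray, in_first: np.ndarray, labels: tuple[str, str]
) -> CategoryEnrichment:
    n1, n2 = int(in_first.sum()), int((~in_first).sum())
    if n1 == 0 or n2 == 0:
        return CategoryEnrichment(
            labels, ((0, 0), (0, 0)), np.nan, np.nan, undefined=True
        )
    k1 = int(sig[in_first].sum())
    k2 = int(sig[~in_first].sum())
    table = ((k1, n1 - k1), (k2, n2 - k2))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return CategoryEnrichment(labels, table, float(odds), float(p))


def protein_predictive_significance(
    fits: pd.DataFrame,
    compare: tuple[str, str] = ("d", "a"),
    fdr: float = PREDICTIVE_FDR,
) -> CategoryEnrichment:
    """Fisher comparison of FDR-significant interaction fits between categories.

    ``fits`` needs ``category`` and ``p`` columns.  BH runs within the
    union of the two compared categories; the 2x2 table is
    (significant / not) x (category); the two-sided Fisher p is the
    protein predictive significance.
    """
    if fits.empty or "category" not in fits.columns:
        return CategoryEnrichment(compare, ((0, 0), (0, 0)), np.nan, np.nan, True)
    sub = fits[fits["category"].isin(compare)].dropna(subset=["p"]).copy()
    if sub.empty:
        return CategoryEnrichment(compare, ((0, 0), (0, 0)), np.nan, np.nan, True)
    sub["q"] = bh_adjust(sub["p"].to_numpy())
    sig = (sub["q"] < fdr).to_numpy()
    in_first = (sub["category"] == compare[0]).to_numpy()
    return _fisher_from_flags(sig, in_first, compare)


def modified_predictive_significance(
    fits: pd.DataFrame,
    active: pd.Series | dict,
    fdr: float = PREDICTIVE_FDR,
) -> CategoryEnrichment:
    """No-split two-class variant for small cohorts.

    ``active`` maps gene_id -> bool, where "differentially active" means
    differential at both RNA and protein and linked to differential
    gene-body footprints.  Compares significant-fit counts between the
    active and inactive classes.
    """
    act = pd.Series(active)
    sub = fits.dropna(subset=["p"]).copy()
    flags = sub["gene_id"].map(act)
    sub = sub[flags.notna()]
    if sub.empty:
        return CategoryEnrichment(
            ("active", "not_active"), ((0, 0), (0, 0)), np.nan, np.nan, True
        )
    sub["q"] = bh_adjust(sub["p"].to_numpy())
    sig = (sub["q"] < fdr).to_numpy()
    in_first = sub["gene_id"].map(act).astype(bool).to_numpy()
    return _fisher_from_flags(sig, in_first, ("active", "not_active"))
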