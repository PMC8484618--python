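"""Seeded calibration and power studies on synthetic cohorts.

These functions quantify the statistical behaviour of the pipeline under
known ground truth: false-discovery calibration of the peak-gene linkage
on null cohorts, sensitivity for strongly coupled planted links, type-I
calibration of the interaction F-test, power of the protein predictive
significance when category-d pairs carry true interaction effects, and the
cohort-wide protein-RNA correlation summary.  Every study is deterministic
given its base seed (per-replicate seeds are spawned from it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .linkage import link_peaks_to_genes
from .normalization import normalize_atac, rollup_protein, transform_rna
from .predictive_significance import (
    interaction_f_test,
    protein_predictive_significance,
)
from .synthetic_cohort import (
    SimulationConfig,
    simulate_annotation,
    simulate_multiomics,
)

__all__ = [
    "simulate_and_link",
    "null_linkage_fdr",
    "planted_link_sensitivity",
    "interaction_test_calibration",
    "predictive_significance_power",
    "protein_rna_correlation_summary",
]


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_and_link(
    config: SimulationConfig, n_null: int = 2000, fdr: float = 0.05
) -> tuple[pd.DataFrame, set]:
    """Simulate a cohort, normalize, and run peak-gene linkage.

    Returns the full tested-pair table and the planted link triples.
    ``n_null`` defaults below the production 10,000 because toy genomes
    hold far fewer trans peaks; the null moments are unchanged.
    """
    annotation = simulate_annotation(config)
    cohort, truth = simulate_multiomics(config, annotation)
    peak_acc = normalize_atac(cohort.atac_counts, cohort.replicate_groups)
    rna = transform_rna(cohort.rna_counts)
    sample_states = cohort.sample_sheet.set_index("sample_id")["state"]
    links = link_peaks_to_genes(
        rna,
        peak_acc,
        sample_states,
        annotation.genes,
        cohort.peaks,
        states=list(config.states),
        fdr=fdr,
        n_null=n_null,
        seed=config.seed,
        chrom_sizes=annotation.chrom_sizes,
    )
    return links, truth.linked_pairs


def null_linkage_fdr(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_genes: int = 500,
    n_patients: int = 18,
    **config_kwargs,
) -> float:
    """Mean fraction of peak-gene pairs linked at q < 0.05 on null cohorts.

    Cohorts carry no planted links and no differential effects; the
    returned fraction estimates the realized false-linkage rate and should
    not exceed the nominal FDR.
    """
    fracs = []
    for seed in _seeds(base_seed, n_seeds):
        config = SimulationConfig(
            seed=seed,
            n_genes=n_genes,
            n_patients=n_patients,
            frac_linked_genes=0.0,
            frac_differential_genes=0.0,
            **config_kwargs,
        )
        links, _ = simulate_and_link(config)
        fracs.append(links["significant"].mean() if len(links) else 0.0)
    return float(np.mean(fracs))


def planted_link_sensitivity(
    n_seeds: int = 20,
    base_seed: int = 0,
    rho_acc_rna: float = 0.9,
    n_genes: int = 500,
    n_patients: int = 18,
    **config_kwargs,
) -> float:
    """Pooled recovery rate of planted links at q < 0.05.

    Links are planted with strong accessibility-RNA coupling; recovery is
    the fraction of planted (peak, gene, state) triples that the linkage
    procedure reports significant, pooled over seeds.
    """
    hit = total = 0
    for seed in _seeds(base_seed, n_seeds):
        config = SimulationConfig(
            seed=seed,
            n_genes=n_genes,
            n_patients=n_patients,
            rho_acc_rna=rho_acc_rna,
            frac_differential_genes=0.0,
            **config_kwargs,
        )
        links, planted = simulate_and_link(config)
        sig = set(
            map(
                tuple,
                links.loc[links["significant"], ["peak_id", "gene_id", "state"]].to_numpy(),
            )
        )
        tested = set(map(tuple, links[["peak_id", "gene_id", "state"]].to_numpy()))
        planted = planted & tested  # a planted peak can merge away on toy genomes
        hit += len(planted & sig)
        total += len(planted)
    return hit / total if total else float("nan")


def interaction_test_calibration(
    n_repeats: int = 1000, n_samples: int = 27, base_seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of interaction-test p-values below ``alpha`` under the null.

    Protein is independent of RNA and accessibility; a calibrated test
    rejects at close to the nominal rate.
    """
    rng = np.random.default_rng(base_seed)
    rejections = 0
    for _ in range(n_repeats):
        protein = rng.normal(size=n_samples)
        rna = rng.normal(size=n_samples)
        acc = rng.normal(size=n_samples)
        fit = interaction_f_test(protein, rna, acc)
        if fit.p < alpha:
            rejections += 1
    return rejections / n_repeats


def _simulate_category_pairs(
    rng: np.random.Generator,
    n_pairs_per_category: int,
    n_samples: int,
    beta_interaction: float,
    noise_sd: float,
) -> pd.DataFrame:
    """Pairs for the power study: category d carries a true interaction."""
    rows = []
    for cat, beta in (("a", 0.0), ("d", beta_interaction)):
        for i in range(n_pairs_per_category):
            rna = rng.normal(size=n_samples)
            acc = rng.normal(size=n_samples)
            protein = rna + beta * rna * acc + rng.normal(0, noise_sd, n_samples)
            fit = interaction_f_test(protein, rna, acc)
            rows.append(
                {
                    "gene_id": f"{cat}_{i}",
                    "element_id": f"e_{cat}_{i}",
                    "category": cat,
                    "F": fit.F,
                    "p": fit.p,
                }
            )
    return pd.DataFrame(rows)


def predictive_significance_power(
    n_runs: int = 20,
    base_seed: int = 0,
    n_pairs_per_category: int = 60,
    n_samples: int = 27,
    beta_interaction: float = 0.6,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs with Fisher p < alpha when category d carries effects.

    Each run simulates gene-element pairs where category d has a true
    RNA x accessibility interaction in the protein model and category a
    has none, fits the interaction tests, and computes the protein
    predictive significance (d vs a).  ``n_samples`` reflects the fitting
    half of a split cohort.
    """
    wins = 0
    for seed in _seeds(base_seed, n_runs):
        rng = np.random.default_rng(seed)
        fits = _simulate_category_pairs(
            rng, n_pairs_per_category, n_samples, beta_interaction, noise_sd
        )
        enr = protein_predictive_significance(fits, compare=("d", "a"))
        if not enr.undefined and enr.fisher_p < alpha:
            wins += 1
    return wins / n_runs


def protein_rna_correlation_summary(
    config: SimulationConfig | None = None, seed: int = 0
) -> dict:
    """Median per-gene protein-RNA Spearman correlation, all vs differential.

    Simulates a default cohort, rolls peptides up to protein, and
    correlates protein with log RNA per gene across shared samples.
    Returns medians for all genes and for the planted differential subset,
    plus the fraction of positive correlations.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    annotation = simulate_annotation(config)
    cohort, truth = simulate_multiomics(config, annotation)
    rna = transform_rna(cohort.rna_counts)
    protein = rollup_protein(cohort.peptides)
    shared = [c for c in rna.columns if c in protein.columns]
    rho = {}
    for gid in protein.index:
        if gid not in rna.index:
            continue
        p = protein.loc[gid, shared].to_numpy(dtype=float)
        r = rna.loc[gid, shared].to_numpy(dtype=float)
        ok = np.isfinite(p) & np.isfinite(r)
        if ok.sum() < 6 or p[ok].std() == 0 or r[ok].std() == 0:
            continue
        rho[gid] = float(stats.spearmanr(p[ok], r[ok])[0])
    values = pd.Series(rho)
    diff = values.reindex(truth.differential_genes.keys()).dropna()
    return {
        "median_all": float(values.median()),
        "median_differential": float(diff.median()) if len(diff) else float("nan"),
        "frac_positive_all": float((values > 0).mean()),
        "n_genes": int(len(values)),
    }
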