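"""End-to-end orchestration of the integrative analysis.

``normalize_cohort`` applies the three normalization chains to a raw
cohort; ``run_pipeline`` executes the full analysis on a simulated bundle
(simulation, normalization, differential calling, peak-gene linkage,
sample-wise correlations, predictive significance, footprint and network
statistics) and writes deterministic TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as cio
from .differential import call_differential, gene_differential_flags
from .footprints_networks import (
    annotate_links_with_footprints,
    differential_footprint_sites,
    footprint_location_test,
    permuted_network_pvalue,
)
from .integration_stats import classify_paired, sample_wise_correlations
from .linkage import LINK_FDR, link_peaks_to_genes
from .normalization import (
    gene_body_rpkm,
    normalize_atac,
    rollup_protein,
    transform_rna,
)
from .predictive_significance import (
    categorize_pairs,
    fit_pairs,
    protein_predictive_significance,
    split_samples,
)
from .synthetic_cohort import OmicsCohort, SimulationConfig, simulate_bundle

__all__ = ["NormalizedCohort", "normalize_cohort", "run_pipeline"]


@dataclass
class NormalizedCohort:
    """Normalized matrices over the shared sample universe."""

    peak_acc: pd.DataFrame
    gene_acc: pd.DataFrame
    rna: pd.DataFrame
    protein: pd.DataFrame
    sample_sheet: pd.DataFrame


def normalize_cohort(cohort: OmicsCohort) -> NormalizedCohort:
    """Apply the per-layer normalization chains to a raw cohort."""
    peak_acc = normalize_atac(cohort.atac_counts, cohort.replicate_groups)
    order = [s for s in cohort.sample_sheet["sample_id"] if s in peak_acc.columns]
    peak_acc = peak_acc[order]
    rna = transform_rna(cohort.rna_counts)
    protein = rollup_protein(cohort.peptides)
    protein = protein.reindex(columns=cohort.sample_sheet["sample_id"])
    return NormalizedCohort(
        peak_acc=peak_acc,
        gene_acc=pd.DataFrame(),  # filled by run_pipeline (needs gene lengths)
        rna=rna,
        protein=protein,
        sample_sheet=cohort.sample_sheet,
    )


def run_pipeline(
    config: SimulationConfig,
    outdir,
    link_fdr: float = LINK_FDR,
    n_null: int | None = None,
    n_perm: int = 1000,
    split_seed: int = 0,
) -> dict:
    """Simulate a cohort and run the full integrative analysis.

    Writes the bundle plus ``links.tsv``, ``differential_*.tsv``,
    ``paired_correlations.tsv``, ``predictive_significance.tsv`` and
    ``network.tsv`` under ``outdir``.  All randomness derives from
    ``config.seed`` and ``split_seed``; outputs are byte-stable.
    Returns a summary dict of the headline results.
    """
    from .linkage import N_NULL

    if n_null is None:
        n_null = N_NULL
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    annotation, cohort, truth, footprints, edges = simulate_bundle(config)
    cio.write_bundle(out / "bundle", annotation, cohort, truth, footprints, edges)
    genes = annotation.genes
    gene_lengths = {g.gene_id: g.body.length for g in genes}

    norm = normalize_cohort(cohort)
    norm.gene_acc = gene_body_rpkm(cohort.genebody_counts, gene_lengths)

    # differential per layer
    diffs = {}
    sheet = cohort.sample_sheet
    diffs["atac_peak"] = call_differential(norm.peak_acc, sheet, "atac_peak")
    diffs["rna"] = call_differential(norm.rna, sheet, "rna")
    diffs["gene_accessibility"] = call_differential(
        norm.gene_acc, sheet, "gene_accessibility"
    )
    prot = norm.protein.dropna(axis=0, how="any")
    diffs["protein"] = call_differential(prot, sheet, "protein")
    gene_flags = gene_differential_flags(diffs["rna"], diffs["protein"])
    flag_map = gene_flags.set_index("gene_id")["any_pairwise_rna_or_protein"]

    # peak-gene linkage
    states = list(config.states)
    sample_states = sheet.set_index("sample_id")["state"]
    links = link_peaks_to_genes(
        norm.rna,
        norm.peak_acc,
        sample_states,
        genes,
        cohort.peaks,
        states=states,
        fdr=link_fdr,
        n_null=n_null,
        seed=config.seed,
        chrom_sizes=annotation.chrom_sizes,
    )
    sig_links = links[links["significant"]].drop_duplicates(["peak_id", "gene_id"])

    # sample-wise correlations on linked pairs
    pairs = sig_links.rename(columns={"peak_id": "element_id"})[
        ["element_id", "gene_id"]
    ].drop_duplicates()
    paired = sample_wise_correlations(norm.peak_acc, norm.rna, norm.protein, pairs)
    elem_class = sig_links.drop_duplicates("peak_id").set_index("peak_id")["peak_class"]
    paired_summary = classify_paired(paired, flag_map, elem_class)

    # predictive significance (split protocol)
    set_a, set_b = split_samples(sheet, seed=split_seed)
    rna_a = call_differential(norm.rna[set_a], sheet[sheet.sample_id.isin(set_a)], "rna")
    prot_a_mat = norm.protein[set_a].dropna(axis=0, how="any")
    prot_a = call_differential(prot_a_mat, sheet[sheet.sample_id.isin(set_a)], "protein")
    acc_a = call_differential(
        norm.peak_acc[set_a], sheet[sheet.sample_id.isin(set_a)], "atac_peak"
    )
    gflags_a = (
        gene_differential_flags(rna_a, prot_a)
        .set_index("gene_id")["any_pairwise_rna_or_protein"]
    )
    eflags_a = acc_a.groupby("feature_id")["significant"].any()
    categorized = categorize_pairs(pairs, gflags_a, eflags_a)
    fits = fit_pairs(categorized, norm.protein, norm.rna, norm.peak_acc, samples=set_b)
    predsig = protein_predictive_significance(fits)

    # footprints: tumor-vs-normal differential sites, location test
    state_on = states[1] if len(states) > 1 else states[0]
    diff_sites = differential_footprint_sites(footprints, state_on, states[0])
    np_links = sig_links[sig_links["peak_class"] == "non_promoter"]
    has_fp = annotate_links_with_footprints(np_links, cohort.peaks, diff_sites)
    location_result = None
    if has_fp.any() and (~has_fp).any():
        location_result = footprint_location_test(np_links[has_fp], np_links[~has_fp])

    # network enrichment of the coordinated differential gene set
    gene_set = [g for g in truth.coordinated_genes if flag_map.get(g, False)]
    if len(gene_set) < 3:
        gene_set = truth.coordinated_genes or list(flag_map.index[flag_map])[:20]
    background = [g.gene_id for g in genes]
    network = permuted_network_pvalue(
        gene_set, edges, background, n_perm=n_perm, seed=config.seed
    )

    # deterministic outputs
    links.to_csv(out / "links.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
    for layer, df in diffs.items():
        df.to_csv(
            out / f"differential_{layer}.tsv",
            sep="\t",
            index=False,
            float_format=cio.FLOAT_FORMAT,
        )
    paired.to_csv(
        out / "paired_correlations.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT
    )
    paired_summary.to_csv(
        out / "paired_summary.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT
    )
    fits.to_csv(
        out / "interaction_fits.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT
    )
    pd.DataFrame(
        [
            {
                "compare": "d_vs_a",
                "sig_first": predsig.table[0][0],
                "not_first": predsig.table[0][1],
                "sig_second": predsig.table[1][0],
                "not_second": predsig.table[1][1],
                "odds_ratio": predsig.odds_ratio,
                "fisher_p": predsig.fisher_p,
            }
        ]
    ).to_csv(out / "predictive_significance.tsv", sep="\t", index=False,
             float_format=cio.FLOAT_FORMAT)
    pd.DataFrame(
        [
            {
                "n_genes": len(gene_set),
                "e_obs": network.e_obs,
                "mu_null": network.mu_null,
                "sigma_null": network.sigma_null,
                "z": network.z,
                "p": network.p,
                "p_empirical": network.p_empirical,
                "n_perm": network.n_perm,
            }
        ]
    ).to_csv(out / "network.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)

    return {
        "n_links": int(sig_links.shape[0]),
        "n_tested_pairs": int(links.shape[0]),
        "predictive_significance": predsig,
        "network": network,
        "location_test": location_result,
        "paired_summary": paired_summary,
        "links": links,
        "truth": truth,
    }
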