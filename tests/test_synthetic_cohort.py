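"""Synthetic cohort generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromalink.evaluation import protein_rna_correlation_summary
from chromalink.synthetic_cohort import (
    GenomeCapacityError,
    SimulationConfig,
    simulate_annotation,
    simulate_bundle,
    simulate_footprints,
    simulate_interaction_network,
    simulate_multiomics,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frac_differential_genes=1.5),
            dict(frac_coordinated=-0.1),
            dict(n_genes=0),
            dict(states=("Tumor", "Tumor")),
            dict(rho_acc_rna=1.0),
            dict(rho_rna_prot=-1.2),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestAnnotation:
    def test_genes_contained_and_non_overlapping(self, small_bundle):
        annotation = small_bundle[0]
        by_chrom = {}
        for g in annotation.genes:
            assert 0 <= g.body.start < g.body.end <= annotation.chrom_sizes[g.chrom]
            assert g.exons, "every gene has at least one exon"
            for e in g.exons:
                assert g.body.contains(e)
            assert g.tss == (g.body.start if g.strand == "+" else g.body.end - 1)
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.body.start)
            for a, b in zip(genes, genes[1:]):
                assert a.body.end <= b.body.start
        strands = {g.strand for g in annotation.genes}
        assert strands == {"+", "-"}

    def test_gene_count_matches_config(self, small_config, small_bundle):
        assert len(small_bundle[0].genes) == small_config.n_genes

    def test_determinism(self, small_config):
        a = simulate_annotation(small_config)
        b = simulate_annotation(small_config)
        assert a.genes == b.genes
        assert a.chrom_sizes == b.chrom_sizes

    def test_single_exon_genes_have_no_introns(self, small_bundle):
        single = [g for g in small_bundle[0].genes if len(g.exons) == 1]
        assert single, "cohort should contain single-exon genes"
        for g in single:
            assert g.introns == ()
            assert g.exons[0].length == g.body.length

    def test_capacity_error(self):
        with pytest.raises(GenomeCapacityError):
            simulate_annotation(
                SimulationConfig(n_genes=200, n_chromosomes=1, chromosome_length=500_000)
            )


class TestMultiomics:
    def test_full_bundle_determinism(self, small_config):
        a_ann, a_cohort, a_truth, a_fp, a_edges = simulate_bundle(small_config)
        b_ann, b_cohort, b_truth, b_fp, b_edges = simulate_bundle(small_config)
        pd.testing.assert_frame_equal(a_cohort.atac_counts, b_cohort.atac_counts)
        pd.testing.assert_frame_equal(a_cohort.rna_counts, b_cohort.rna_counts)
        pd.testing.assert_frame_equal(a_cohort.peptides, b_cohort.peptides)
        pd.testing.assert_frame_equal(a_fp, b_fp)
        pd.testing.assert_frame_equal(a_edges, b_edges)
        assert a_truth.linked_pairs == b_truth.linked_pairs

    def test_truth_invariants(self, small_bundle):
        annotation, cohort, truth, _, _ = small_bundle
        assert set(truth.coordinated_genes) <= set(truth.differential_genes)
        peak_ids = {p.peak_id for p in cohort.peaks}
        for pid, gid, state in truth.linked_pairs:
            assert pid in peak_ids
        assert set(truth.planted_module) <= {g.gene_id for g in annotation.genes}

    def test_sample_layout(self, small_config, small_bundle):
        _, cohort, *_ = small_bundle
        n = small_config.n_patients * len(small_config.states)
        assert len(cohort.sample_sheet) == n
        assert cohort.rna_counts.shape[1] == n
        assert (
            cohort.atac_counts.shape[1]
            == n * small_config.replicate_count
        )
        # every TMT run carries a reference channel
        for _, run in cohort.peptides.groupby("run_id"):
            assert run["is_reference"].any()

    def test_planted_links_correlate_above_background(self, small_bundle):
        """Direct correlation of the emitted matrices, no linkage machinery."""
        annotation, cohort, truth, _, _ = small_bundle
        log_rna = np.log2(cohort.rna_counts + 1)
        # average ATAC replicates on the raw log scale
        acc = np.log2(cohort.atac_counts + 1)
        acc = acc.T.groupby(cohort.atac_sample_sheet.set_index("column_id")["sample_id"]).mean().T
        state_of = cohort.sample_sheet.set_index("sample_id")["state"]
        linked_r, background_r = [], []
        rng = np.random.default_rng(0)
        linked = {(p, g) for p, g, _ in truth.linked_pairs}
        peak_ids = list(acc.index)
        for state in ("Normal", "Tumor", "Met"):
            cols = [s for s in acc.columns if state_of[s] == state]
            for pid, gid in list(linked)[:60]:
                r = np.corrcoef(acc.loc[pid, cols], log_rna.loc[gid, cols])[0, 1]
                linked_r.append(r)
            for _ in range(60):
                pid = peak_ids[rng.integers(len(peak_ids))]
                gid = log_rna.index[rng.integers(len(log_rna.index))]
                if (pid, gid) in linked:
                    continue
                r = np.corrcoef(acc.loc[pid, cols], log_rna.loc[gid, cols])[0, 1]
                background_r.append(r)
        assert np.mean(linked_r) > np.mean(background_r) + 0.3

    def test_configured_coupling_recovered(self):
        """Emitted matrices reproduce the rho targets within +-0.1."""
        config = SimulationConfig(seed=41, n_genes=150, rho_acc_rna=0.9)
        annotation = simulate_annotation(config)
        cohort, truth = simulate_multiomics(config, annotation)
        log_rna = np.log2(cohort.rna_counts + 1)
        acc = np.log2(cohort.atac_counts + 1)
        acc = acc.T.groupby(
            cohort.atac_sample_sheet.set_index("column_id")["sample_id"]
        ).mean().T
        state_of = cohort.sample_sheet.set_index("sample_id")["state"]
        cols = [s for s in acc.columns if state_of[s] == "Tumor"]
        rs = [
            np.corrcoef(acc.loc[pid, cols], log_rna.loc[gid, cols])[0, 1]
            for pid, gid, state in truth.linked_pairs
            if state == "Tumor"
        ]
        assert abs(np.mean(rs) - 0.9) < 0.1

    def test_uncoupled_protein_has_near_zero_correlation(self):
        """rho targets of zero leave the protein layer independent of RNA."""
        config = SimulationConfig(
            seed=42,
            rho_rna_prot=0.0,
            rho_rna_prot_differential=0.0,
            frac_differential_genes=0.0,
        )
        summary = protein_rna_correlation_summary(config)
        assert abs(summary["median_all"]) < 0.1
        assert summary["n_genes"] >= 450


class TestFootprints:
    def test_forced_placement_for_coordinated_genes(self, small_config):
        config = SimulationConfig(
            **{**small_config.__dict__, "footprint_prob_coordinated": 1.0}
        )
        annotation = simulate_annotation(config)
        cohort, truth = simulate_multiomics(config, annotation)
        fp = simulate_footprints(config, annotation, truth, peaks=cohort.peaks)
        diff = fp[(fp["state"] == "Tumor") & fp["bound"]]
        gene_bodies = {g.gene_id: g.body for g in annotation.genes}
        for gid in truth.coordinated_genes:
            sub = fp[(fp["gene_id"] == gid) & (fp["state"] == "Tumor") & fp["bound"]]
            inside = [
                gene_bodies[gid].start <= s and e <= gene_bodies[gid].end
                for s, e in zip(sub["start"], sub["end"])
            ]
            assert any(inside)

    def test_zero_probability_gives_no_differential_sites(self, small_config):
        from chromalink.footprints_networks import differential_footprint_sites

        config = SimulationConfig(
            **{
                **small_config.__dict__,
                "footprint_prob_coordinated": 0.0,
                "footprint_background_bound_prob": 0.0,
            }
        )
        annotation = simulate_annotation(config)
        _, truth = simulate_multiomics(config, annotation)
        fp = simulate_footprints(config, annotation, truth)
        sites = differential_footprint_sites(fp, "Tumor", "Normal")
        assert sites.empty

    def test_seeded_determinism(self, small_config, small_bundle):
        annotation, cohort, truth, fp, _ = small_bundle
        again = simulate_footprints(small_config, annotation, truth, peaks=cohort.peaks)
        pd.testing.assert_frame_equal(fp, again)


class TestNetwork:
    def test_complete_module_edge_count(self):
        config = SimulationConfig(
            module_size=5, module_density=1.0, background_edge_prob=0.0
        )
        truth_genes = [f"gene_{i:04d}" for i in range(30)]
        from chromalink.synthetic_cohort import PlantedTruth

        truth = PlantedTruth(planted_module=truth_genes[:5])
        edges = simulate_interaction_network(config, truth, truth_genes)
        assert len(edges) == 10  # complete graph on 5 nodes
        within = set(truth.planted_module)
        assert all(a in within and b in within for a, b in edges.to_numpy())

    def test_no_self_loops_and_deduplicated(self, small_bundle):
        *_, edges = small_bundle
        assert (edges["gene_a"] != edges["gene_b"]).all()
        canon = {tuple(sorted(e)) for e in edges.to_numpy()}
        assert len(canon) == len(edges)


def test_null_effects_give_uniform_downstream_pvalues():
    """The marginal-calibration invariant on the RNA layer (KS at alpha 0.01)."""
    from chromalink.differential import call_differential
    from chromalink.normalization import transform_rna

    config = SimulationConfig(seed=43, frac_differential_genes=0.0)
    annotation = simulate_annotation(config)
    cohort, _ = simulate_multiomics(config, annotation)
    rec = call_differential(
        transform_rna(cohort.rna_counts), cohort.sample_sheet, "rna"
    )
    p = rec.loc[rec["comparison"] == "Met_vs_Tumor", "p"]
    assert len(p) >= 500
    assert stats.kstest(p, "uniform").pvalue > 0.01
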