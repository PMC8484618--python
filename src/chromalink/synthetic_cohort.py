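"""In-silico multi-omics cohort with known planted structure.

The generator emulates a patient-matched three-state cancer cohort (normal
tissue, primary tumor, metastasis) profiled for chromatin accessibility
(peak-level and gene-body ATAC counts with technical replicates), RNA
(gene-level counts), and protein (peptide-level TMT-style intensities with
a reference channel per run), together with transcription-factor footprint
calls and a protein-protein interaction edge list.

Statistical structure
---------------------
* Counts (peaks, gene bodies, RNA) are negative-binomial around log-normal
  per-feature baselines: the standard minimal model for over-dispersed
  sequencing counts.
* Every gene carries a per-sample latent activity combining a patient
  random effect (samples are patient-matched across states) and sample
  noise; the RNA log-mean loads on it.
* Planted peak-gene links couple the linked peak's accessibility to the
  gene's realized (observed) log RNA with target correlation
  ``rho_acc_rna``; protein couples to observed log RNA with target
  ``rho_rna_prot`` (boosted for differential genes), making the configured
  correlations directly recoverable from the emitted matrices.
* Differential genes shift their state means by ``logfc_scale`` (log2) at
  RNA and protein; the coordinated subset also shifts the linked peak and
  gene-body accessibility, and receives a bound-in-tumor/met footprint
  inside the gene body.
* A planted module of coordinated genes receives dense interaction edges
  on an Erdos-Renyi background.

Identical config + seed reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_model import GeneModel, GenomicInterval, Peak, peak_set_from_summits

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "Annotation",
    "OmicsCohort",
    "simulate_annotation",
    "simulate_multiomics",
    "simulate_footprints",
    "simulate_interaction_network",
    "simulate_bundle",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable study conditions for the synthetic cohort.

    Defaults reflect the emulated cohort: 18 patients with one sample per
    state (54 triple-omic samples), three disease states, moderate
    background protein-RNA coupling (~0.25, so the cohort-wide median
    protein-RNA correlation lands near the low positive values typical of
    tumor proteogenomics) with a boosted coupling for differential genes.
    """

    seed: int = 0
    n_patients: int = 18
    states: tuple[str, ...] = ("Normal", "Tumor", "Met")
    n_genes: int = 500
    n_chromosomes: int = 4
    chromosome_length: int = 12_000_000
    peaks_per_gene: float = 4.0
    frac_linked_genes: float = 1.0
    frac_differential_genes: float = 0.2
    frac_coordinated: float = 0.5
    logfc_scale: float = 2.0
    rho_acc_rna: float = 0.75
    rho_rna_prot: float = 0.25
    rho_rna_prot_differential: float = 0.45
    nb_dispersion: float = 0.05
    replicate_count: int = 2
    frac_missing_peptides: float = 0.1
    peptides_per_gene: float = 3.0
    # secondary knobs (documented in the methods note)
    patient_effect_sd: float = 0.3
    latent_sd_log2: float = 1.0
    base_log2_mean: float = 8.0
    base_log2_sd: float = 1.0
    peptide_noise_sd_log2: float = 0.3
    intergenic_peaks_per_chrom: int = 50
    footprint_prob_coordinated: float = 0.9
    background_footprints_per_gene: float = 1.0
    footprint_background_bound_prob: float = 0.3
    module_size: int = 15
    module_density: float = 0.9
    background_edge_prob: float = 0.005

    def __post_init__(self) -> None:
        for name in (
            "frac_linked_genes",
            "frac_differential_genes",
            "frac_coordinated",
            "frac_missing_peptides",
            "module_density",
            "background_edge_prob",
            "footprint_prob_coordinated",
            "footprint_background_bound_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_patients",
            "n_genes",
            "n_chromosomes",
            "chromosome_length",
            "replicate_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(set(self.states)) < 2:
            raise ValueError("need at least 2 distinct states")
        for name in ("rho_acc_rna", "rho_rna_prot", "rho_rna_prot_differential"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    linked_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    differential_genes: dict[str, dict] = field(default_factory=dict)
    coordinated_genes: list[str] = field(default_factory=list)
    planted_module: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "linked_pairs": sorted(list(t) for t in self.linked_pairs),
            "differential_genes": self.differential_genes,
            "coordinated_genes": sorted(self.coordinated_genes),
            "planted_module": sorted(self.planted_module),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            linked_pairs={tuple(t) for t in d["linked_pairs"]},
            differential_genes=d["differential_genes"],
            coordinated_genes=list(d["coordinated_genes"]),
            planted_module=list(d["planted_module"]),
        )


@dataclass
class Annotation:
    """Toy genome: gene models plus chromosome sizes."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]


@dataclass
class OmicsCohort:
    """Raw simulated layers plus sample metadata.

    ``atac_counts`` columns are technical-replicate columns described by
    ``atac_sample_sheet`` (column_id, sample_id, patient_id, state,
    replicate); the remaining matrices are per biological sample.
    """

    sample_sheet: pd.DataFrame
    atac_sample_sheet: pd.DataFrame
    peaks: list[Peak]
    atac_counts: pd.DataFrame
    genebody_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    peptides: pd.DataFrame

    @property
    def replicate_groups(self) -> dict[str, list[str]]:
        return {
            s: list(g["column_id"])
            for s, g in self.atac_sample_sheet.groupby("sample_id", sort=True)
        }


class GenomeCapacityError(ValueError):
    """Requested genes do not fit in the requested genome."""


# fixed registry so every layer draws from its own independent stream
_STREAMS = (
    "annotation",
    "truth",
    "rna",
    "peaks",
    "genebody",
    "protein",
    "footprints",
    "network",
)


def _rng(config: SimulationConfig, label: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(label)])


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Place non-overlapping genes with exon structure on a toy genome.

    Genes are spread as evenly as possible over the chromosomes, with
    log-normal body lengths, random strands (both strands always
    represented), and alternating exon/intron segments starting and ending
    with an exon.  Raises :class:`GenomeCapacityError` when the genes
    cannot fit.
    """
    rng = _rng(config, "annotation")
    chrom_sizes = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1

    genes: list[GeneModel] = []
    gi = 0
    strands = rng.choice(["+", "-"], size=config.n_genes)
    if config.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "+" if strands[-1] == "-" else "-"
    for ci, (chrom, n_here) in enumerate(zip(chrom_sizes, per_chrom)):
        if n_here == 0:
            continue
        lengths = np.clip(
            rng.lognormal(np.log(15_000), 0.5, size=n_here), 2_000, 200_000
        ).astype(int)
        free = config.chromosome_length - int(lengths.sum())
        if free < n_here + 1:
            raise GenomeCapacityError(
                f"{n_here} genes (total {lengths.sum()} bp) exceed {chrom} "
                f"capacity {config.chromosome_length} bp"
            )
        gaps = np.floor(rng.dirichlet(np.ones(n_here + 1)) * free).astype(int)
        cursor = 0
        for k in range(n_here):
            start = cursor + int(gaps[k])
            end = start + int(lengths[k])
            cursor = end
            body = GenomicInterval(chrom, start, end)
            exons = _draw_exons(rng, body)
            genes.append(
                GeneModel(f"gene_{gi:04d}", body, strand=str(strands[gi]), exons=exons)
            )
            gi += 1
    return Annotation(genes=genes, chrom_sizes=chrom_sizes)


def _draw_exons(rng: np.random.Generator, body: GenomicInterval) -> tuple[GenomicInterval, ...]:
    """Alternating exon/intron segments; first and last segments are exons."""
    max_ex = max(1, body.length // 400)
    n_ex = int(min(1 + rng.poisson(3), max_ex))
    n_seg = 2 * n_ex - 1
    w = rng.dirichlet(np.ones(n_seg))
    seg = np.maximum((w * body.length).astype(int), 50)
    # renormalize the last segment so the sum matches the body exactly
    seg[-1] = body.length - int(seg[:-1].sum())
    if seg[-1] < 50:  # fall back to a single-exon gene on tiny bodies
        return (GenomicInterval(body.chrom, body.start, body.end),)
    bounds = body.start + np.concatenate([[0], np.cumsum(seg)])
    return tuple(
        GenomicInterval(body.chrom, int(bounds[i]), int(bounds[i + 1]))
        for i in range(0, n_seg, 2)
    )


def _nb_counts(rng: np.random.Generator, log2_mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws around ``2 ** log2_mean``."""
    mu = np.exp2(log2_mean)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=1, keepdims=True)) / sd


def simulate_multiomics(
    config: SimulationConfig, annotation: Annotation
) -> tuple[OmicsCohort, PlantedTruth]:
    """Generate all omic layers plus the planted ground truth."""
    genes = annotation.genes
    n_genes = len(genes)
    states = list(config.states)
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    sample_ids, sample_patient, sample_state = [], [], []
    for p in patients:
        for s in states:
            sample_ids.append(f"{p}_{s}")
            sample_patient.append(p)
            sample_state.append(s)
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "patient_id": sample_patient, "state": sample_state}
    )
    n_samples = len(sample_ids)
    state_of = sheet["state"].to_numpy()
    patient_idx = np.array([patients.index(p) for p in sheet["patient_id"]])

    # --- planted truth -----------------------------------------------------
    t_rng = _rng(config, "truth")
    perm = t_rng.permutation(n_genes)
    n_diff = int(round(config.frac_differential_genes * n_genes))
    diff_idx = perm[:n_diff]
    n_coord = int(round(config.frac_coordinated * n_diff))
    coord_idx = diff_idx[:n_coord]
    n_linked = int(round(config.frac_linked_genes * n_genes))
    linked_idx = set(t_rng.permutation(n_genes)[:n_linked].tolist())

    truth = PlantedTruth()
    target_states = t_rng.choice(states[1:], size=n_diff)
    signs = t_rng.choice([-1.0, 1.0], size=n_diff)
    delta_rna = np.zeros((n_genes, n_samples))
    delta_acc = np.zeros((n_genes, n_samples))
    coord_set = set(coord_idx.tolist())
    for j, gi in enumerate(diff_idx):
        g = genes[gi].gene_id
        tgt, s = target_states[j], signs[j]
        mask = state_of == tgt
        delta_rna[gi, mask] = s * config.logfc_scale
        is_coord = gi in coord_set
        if is_coord:
            delta_acc[gi, mask] = s * config.logfc_scale
        truth.differential_genes[g] = {
            "comparison": f"{tgt}_vs_{states[0]}",
            "rna_logfc": s * config.logfc_scale,
            "protein_logfc": s * config.logfc_scale,
            "accessibility_logfc": s * config.logfc_scale if is_coord else 0.0,
        }
    truth.coordinated_genes = sorted(genes[gi].gene_id for gi in coord_idx)
    truth.planted_module = truth.coordinated_genes[: config.module_size] or [
        genes[gi].gene_id for gi in perm[: config.module_size]
    ]

    # --- RNA ---------------------------------------------------------------
    r_rng = _rng(config, "rna")
    base = r_rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_genes)
    u = r_rng.normal(0.0, config.patient_effect_sd, size=(n_genes, config.n_patients))
    e = r_rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    latent = (u[:, patient_idx] + e) / np.sqrt(1.0 + config.patient_effect_sd**2)
    rna_log2 = base[:, None] + config.latent_sd_log2 * latent + delta_rna
    rna_counts = _nb_counts(r_rng, rna_log2, config.nb_dispersion)
    rna = pd.DataFrame(rna_counts, index=[g.gene_id for g in genes], columns=sample_ids)

    log_rna = np.log2(rna_counts + 1.0)
    z_rna_global = _zscore_rows(log_rna)
    z_rna_state = np.empty_like(log_rna)
    for s in states:
        mask = state_of == s
        z_rna_state[:, mask] = _zscore_rows(log_rna[:, mask])

    # --- peaks -------------------------------------------------------------
    p_rng = _rng(config, "peaks")
    summits: list[tuple[str, int]] = []
    planted_summit_of_gene: dict[int, tuple[str, int]] = {}
    for gi, g in enumerate(genes):
        n_pk = 1 + p_rng.poisson(max(config.peaks_per_gene - 1.0, 0.0))
        size = annotation.chrom_sizes[g.chrom]
        for k in range(n_pk):
            if k == 0:
                if p_rng.random() < 0.5:
                    pos = int(p_rng.integers(g.body.start, g.body.end))
                else:
                    pos = int(g.tss + p_rng.integers(-50_000, 50_001))
            else:
                pos = int(g.tss + p_rng.integers(-200_000, 200_001))
            pos = int(np.clip(pos, 0, size - 1))
            if k == 0 and gi in linked_idx:
                planted_summit_of_gene[gi] = (g.chrom, pos)
            summits.append((g.chrom, pos))
    for chrom, size in annotation.chrom_sizes.items():
        for pos in p_rng.integers(0, size, size=config.intergenic_peaks_per_chrom):
            summits.append((chrom, int(pos)))
    peaks = peak_set_from_summits(summits, annotation.chrom_sizes)

    # map planted summits onto merged peak ids
    peak_of_summit: dict[tuple[str, int], str] = {}
    for pk in peaks:
        for s in pk.member_summits:
            peak_of_summit[(pk.interval.chrom, s)] = pk.peak_id
    linked_peak_of_gene = {
        gi: peak_of_summit[key] for gi, key in planted_summit_of_gene.items()
    }
    for gi, pid in linked_peak_of_gene.items():
        for s in states:
            truth.linked_pairs.add((pid, genes[gi].gene_id, s))

    n_peaks = len(peaks)
    peak_ids = [pk.peak_id for pk in peaks]
    peak_index = {pid: i for i, pid in enumerate(peak_ids)}
    pbase = p_rng.normal(config.base_log2_mean - 1.0, config.base_log2_sd, size=n_peaks)
    noise = p_rng.normal(0.0, 1.0, size=(n_peaks, n_samples))
    peak_latent = noise.copy()
    rho = config.rho_acc_rna
    for gi, pid in linked_peak_of_gene.items():
        pi = peak_index[pid]
        peak_latent[pi] = rho * z_rna_state[gi] + np.sqrt(1 - rho**2) * noise[pi]
    delta_peak = np.zeros((n_peaks, n_samples))
    for gi in coord_idx:
        pid = linked_peak_of_gene.get(int(gi))
        if pid is not None:
            delta_peak[peak_index[pid]] += delta_acc[gi]
    peak_log2 = pbase[:, None] + config.latent_sd_log2 * peak_latent + delta_peak

    rep_cols, rep_rows = [], []
    for sid, st, pat in zip(sheet["sample_id"], sheet["state"], sheet["patient_id"]):
        for r in range(1, config.replicate_count + 1):
            rep_cols.append(f"{sid}_r{r}")
            rep_rows.append((f"{sid}_r{r}", sid, pat, st, r))
    atac_sheet = pd.DataFrame(
        rep_rows, columns=["column_id", "sample_id", "patient_id", "state", "replicate"]
    )
    atac = np.empty((n_peaks, len(rep_cols)), dtype=np.int64)
    for j in range(config.replicate_count):
        atac[:, j :: config.replicate_count] = _nb_counts(
            p_rng, peak_log2, config.nb_dispersion
        )
    atac_counts = pd.DataFrame(atac, index=peak_ids, columns=rep_cols)

    # --- gene-body accessibility ------------------------------------------
    g_rng = _rng(config, "genebody")
    gb_noise = g_rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    gb_latent = gb_noise.copy()
    for gi in coord_idx:
        gb_latent[gi] = rho * z_rna_global[gi] + np.sqrt(1 - rho**2) * gb_noise[gi]
    gb_log2 = (
        base[:, None]
        - 1.0
        + config.latent_sd_log2 * gb_latent
        + delta_acc
    )
    genebody = pd.DataFrame(
        _nb_counts(g_rng, gb_log2, config.nb_dispersion),
        index=[g.gene_id for g in genes],
        columns=sample_ids,
    )

    # --- protein (peptide level) ------------------------------------------
    pr_rng = _rng(config, "protein")
    rho_prot = np.full(n_genes, config.rho_rna_prot)
    rho_prot[diff_idx] = config.rho_rna_prot_differential
    p_noise = pr_rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    prot_latent = rho_prot[:, None] * z_rna_global + np.sqrt(
        1 - rho_prot[:, None] ** 2
    ) * p_noise
    prot_log2 = config.latent_sd_log2 * prot_latent + delta_rna  # sample/ref log-ratio

    peptides = _simulate_peptides(config, pr_rng, genes, sheet, prot_log2)

    cohort = OmicsCohort(
        sample_sheet=sheet,
        atac_sample_sheet=atac_sheet,
        peaks=peaks,
        atac_counts=atac_counts,
        genebody_counts=genebody,
        rna_counts=rna,
        peptides=peptides,
    )
    return cohort, truth


def _simulate_peptides(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    sheet: pd.DataFrame,
    prot_log2: np.ndarray,
) -> pd.DataFrame:
    """Peptide-level TMT-style intensities, one run per patient block.

    Patients are grouped three per run (all of a patient's states stay in
    one run, mirroring patient-randomized multiplexing); each run carries
    its sample channels plus one reference channel.  Peptide intensities
    are log-normal around a peptide baseline times the gene's sample/ref
    ratio; a fraction of sample-channel intensities is missing at random.
    """
    n_genes = len(genes)
    patients = list(dict.fromkeys(sheet["patient_id"]))
    runs = [patients[i : i + 3] for i in range(0, len(patients), 3)]
    n_pep = 1 + rng.poisson(max(config.peptides_per_gene - 1.0, 0.0), size=n_genes)
    total_pep = int(n_pep.sum())
    gene_of_pep = np.repeat(np.arange(n_genes), n_pep)
    pep_rank = np.concatenate([np.arange(k) for k in n_pep])
    pep_ids = np.array(
        [f"{genes[g].gene_id}_pep{j + 1}" for g, j in zip(gene_of_pep, pep_rank)]
    )
    gene_ids = np.array([genes[g].gene_id for g in gene_of_pep])
    pep_base = rng.normal(10.0, 1.0, size=total_pep)
    sigma = config.peptide_noise_sd_log2
    sample_pos = {sid: i for i, sid in enumerate(sheet["sample_id"])}
    patient_of_sample = dict(zip(sheet["sample_id"], sheet["patient_id"]))

    frames = []
    for run_i, run_patients in enumerate(runs):
        run_id = f"run_{run_i + 1:02d}"
        run_samples = [
            sid
            for sid in sheet["sample_id"]
            if patient_of_sample[sid] in set(run_patients)
        ]
        cols = [sample_pos[sid] for sid in run_samples]
        ref = np.exp2(pep_base + rng.normal(0.0, sigma, size=total_pep))
        vals = np.exp2(
            pep_base[:, None]
            + prot_log2[gene_of_pep][:, cols]
            + rng.normal(0.0, sigma, size=(total_pep, len(cols)))
        )
        vals[rng.random(vals.shape) < config.frac_missing_peptides] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "peptide_id": pep_ids,
                    "gene_id": gene_ids,
                    "run_id": run_id,
                    "channel_id": "ref",
                    "sample_id": "",
                    "is_reference": True,
                    "intensity": ref,
                }
            )
        )
        for k, sid in enumerate(run_samples):
            frames.append(
                pd.DataFrame(
                    {
                        "peptide_id": pep_ids,
                        "gene_id": gene_ids,
                        "run_id": run_id,
                        "channel_id": f"ch_{sid}",
                        "sample_id": sid,
                        "is_reference": False,
                        "intensity": vals[:, k],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_footprints(
    config: SimulationConfig,
    annotation: Annotation,
    truth: PlantedTruth,
    peaks: Sequence[Peak] | None = None,
) -> pd.DataFrame:
    """Per-site, per-state TF-footprint bound/unbound calls.

    Coordinated genes receive, with probability
    ``footprint_prob_coordinated``, a site inside their gene body that is
    bound in every non-reference state and unbound in the reference state;
    when ``peaks`` are supplied and the gene's planted linked peak lies in
    the gene body, the site is placed inside that peak (footprints live in
    accessible chromatin).  Background sites are bound uniformly at random
    in each state.  Returns a long table: motif_id, chrom, start, end,
    gene_id, state, bound.
    """
    rng = _rng(config, "footprints")
    states = list(config.states)
    gene_by_id = {g.gene_id: g for g in annotation.genes}
    peak_by_id = {p.peak_id: p for p in peaks} if peaks else {}
    linked_peak = {gid: pid for pid, gid, _ in truth.linked_pairs}
    rows = []
    site_i = 0
    for gid in sorted(truth.coordinated_genes):
        if rng.random() >= config.footprint_prob_coordinated:
            continue
        g = gene_by_id[gid]
        lo, hi = g.body.start, max(g.body.end - 20, g.body.start + 1)
        pk = peak_by_id.get(linked_peak.get(gid, ""))
        if pk is not None and pk.interval.overlaps(g.body):
            lo = max(lo, pk.interval.start)
            hi = min(hi, max(pk.interval.end - 20, pk.interval.start + 1))
            if hi <= lo:
                hi = lo + 1
        pos = int(rng.integers(lo, hi))
        motif = f"motif_{site_i % 12:02d}"
        for s in states:
            rows.append(
                (motif, g.chrom, pos, pos + 20, gid, s, s != states[0])
            )
        site_i += 1
    for g in annotation.genes:
        n_bg = rng.poisson(config.background_footprints_per_gene)
        for _ in range(n_bg):
            pos = int(rng.integers(g.body.start, max(g.body.end - 20, g.body.start + 1)))
            motif = f"motif_{int(rng.integers(12)):02d}"
            for s in states:
                bound = bool(rng.random() < config.footprint_background_bound_prob)
                rows.append((motif, g.chrom, pos, pos + 20, g.gene_id, s, bound))
    return pd.DataFrame(
        rows, columns=["motif_id", "chrom", "start", "end", "gene_id", "state", "bound"]
    )


def simulate_interaction_network(
    config: SimulationConfig, truth: PlantedTruth, gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Undirected, deduplicated interaction edges with a planted module.

    Genes of ``truth.planted_module`` are wired with density
    ``module_density``; all remaining pairs follow an Erdos-Renyi
    background with probability ``background_edge_prob``.  No self-loops.
    """
    rng = _rng(config, "network")
    gene_ids = sorted(gene_ids)
    module = sorted(set(truth.planted_module) & set(gene_ids))
    pos = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    edges: set[tuple[str, str]] = set()
    mod_pos = [pos[g] for g in module]
    for i in range(len(mod_pos)):
        for j in range(i + 1, len(mod_pos)):
            if rng.random() < config.module_density:
                a, b = sorted((gene_ids[mod_pos[i]], gene_ids[mod_pos[j]]))
                edges.add((a, b))
    if config.background_edge_prob > 0 and n >= 2:
        n_draw = rng.binomial(n * (n - 1) // 2, config.background_edge_prob)
        attempts = 0
        while n_draw > 0 and attempts < 100 * (n_draw + 1):
            attempts += 1
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = sorted((gene_ids[i], gene_ids[j]))
            if (a, b) in edges:
                continue
            edges.add((a, b))
            n_draw -= 1
    return pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])


def simulate_bundle(config: SimulationConfig):
    """Convenience wrapper: annotation, cohort, truth, footprints, edges."""
    annotation = simulate_annotation(config)
    cohort, truth = simulate_multiomics(config, annotation)
    footprints = simulate_footprints(config, annotation, truth, peaks=cohort.peaks)
    edges = simulate_interaction_network(
        config, truth, [g.gene_id for g in annotation.genes]
    )
    return annotation, cohort, truth, footprints, edges
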