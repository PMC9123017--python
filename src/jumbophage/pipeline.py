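"""End-to-end synthetic study: world -> QC -> populations -> clusters ->
profiles -> ecology -> hosts, with planted-truth recovery metrics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import annotation, bin_qc, ecology, hosts, network, populations, synthetic


@dataclass
class PipelineConfig:
    world: synthetic.WorldConfig = field(default_factory=synthetic.WorldConfig)
    n_reference_genomes: int = 30
    calibration_quantile: float = 0.95
    spinglass_runs: int = 20
    anosim_permutations: int = 999


@dataclass
class PipelineResult:
    world: synthetic.SyntheticWorld
    evenness_threshold: float
    qc_reports: list[bin_qc.QcReport]
    population_assignment: populations.PopulationAssignment
    population_ari: float
    partition: network.Partition
    cluster_labels: dict[str, str]
    cluster_ari: float
    profile: annotation.ClusterFunctionProfile
    discriminating_families: list[str]
    abundance: ecology.AbundanceMatrix
    stats: dict[str, ecology.StatResult]
    exclusivity: pd.DataFrame
    host_evidence: list[hosts.HostEvidence]
    host_accuracy: float

    @property
    def qc_pass_rate(self) -> float:
        return sum(r.overall_pass for r in self.qc_reports) / len(self.qc_reports)


def run_pipeline(
    config: PipelineConfig | None = None, seed: int = 0, outdir: str | Path | None = None
) -> PipelineResult:
    cfg = config or PipelineConfig()
    world = synthetic.make_world(cfg.world, seed=seed)

    # --- bin QC with evenness threshold calibrated on fragmented references
    refs = synthetic.reference_fragment_bins(cfg.n_reference_genomes, seed=seed + 101)
    ref_cov = synthetic.simulate_coverage(
        refs, cfg.world.n_coverage_samples, noise_cv=cfg.world.coverage_noise_cv,
        seed=seed + 102,
    )
    threshold = bin_qc.calibrate_evenness_threshold(
        refs, ref_cov, quantile=cfg.calibration_quantile
    )
    thresholds = bin_qc.QcThresholds(evenness_threshold=threshold)
    reports = bin_qc.run_qc(
        world.bins,
        thresholds,
        coverage=world.coverage,
        annotations=world.marker_tables,
        classifier_scores=world.classifier_scores,
    )
    passing_bins = [
        b for b, r in zip(world.bins, reports) if r.overall_pass
    ]

    # --- populations over the genomes of passing bins
    gene_sets = {}
    lengths = {}
    source_of_bin = {}
    for b in passing_bins:
        source = b.contigs[0].source_genome
        source_of_bin[b.bin_id] = source
        gene_sets[b.bin_id] = b.gene_sequences()
        lengths[b.bin_id] = b.total_length
    assignment, _pairs = populations.cluster_genomes(gene_sets, lengths)
    truth = [world.population_truth[source_of_bin[b]] for b in assignment.population_of]
    recovered = [assignment.population_of[b] for b in assignment.population_of]
    population_ari = float(adjusted_rand_score(truth, recovered)) if truth else 0.0

    # --- gene-sharing network and PGC-like clusters (on the genome set)
    net = network.build_network(
        world.annotation_hits, genomes=[g.genome_id for g in world.genomes]
    )
    params = network.SpinglassParams(n_runs=cfg.spinglass_runs, seed=seed + 201)
    partition, _runs = network.detect_communities(net, params)
    cluster_labels = network.extract_genome_clusters(partition, net)
    assigned = [g for g in cluster_labels if cluster_labels[g] != "unassigned"]
    cluster_ari = float(
        adjusted_rand_score(
            [world.community_truth[g] for g in assigned],
            [cluster_labels[g] for g in assigned],
        )
    )

    # --- functional profiles per recovered cluster
    consensus = annotation.consensus_table(world.annotation_hits, world.category_map)
    gene_table = world.annotation_hits[["genome_id", "gene_id"]].merge(
        consensus[["gene_id", "family_id", "category"]], on="gene_id"
    )
    profile = annotation.profile_clusters(gene_table, cluster_labels)
    known = set(world.category_map.loc[world.category_map["known"], "family_id"])
    try:
        discriminating = annotation.select_discriminating_genes(
            profile.presence_fractions, known_families=known
        )
    except ValueError:
        discriminating = []

    # --- ecology on the planted mapping table
    pop_meta = (
        pd.DataFrame(
            {
                "population_id": [world.population_truth[g.genome_id] for g in world.genomes],
                "genome_length": [g.length for g in world.genomes],
                "cluster": [world.community_truth[g.genome_id] for g in world.genomes],
            }
        )
        .groupby("population_id", as_index=False)
        .agg({"genome_length": "max", "cluster": "first"})
    )
    abundance = ecology.build_abundance_matrix(
        world.mapping,
        genome_length=dict(zip(pop_meta["population_id"], pop_meta["genome_length"])),
        total_reads=synthetic.SUBSAMPLE_DEPTH,
    )
    stats: dict[str, ecology.StatResult] = {}
    for matrix_type in ("presence", "rpkm"):
        for by in ("fraction_class", "depth"):
            stats[f"anosim_{by}_{matrix_type}"] = ecology.compare_groups(
                abundance, world.metadata, by=by, matrix_type=matrix_type,
                n_permutations=cfg.anosim_permutations, seed=seed + 301,
            )
    # planted depth enrichment: richness of the enriched cluster, SRF vs MES
    enriched = sorted(cfg.world.depth_effects) or ["cluster_0"]
    pops_enriched = pop_meta.loc[pop_meta["cluster"] == enriched[0], "population_id"]
    sub = abundance.presence.loc[abundance.presence.index.isin(pops_enriched)]
    rich = ecology.richness(sub)
    meta_ix = world.metadata.set_index("sample_id")
    srf = rich[meta_ix.loc[rich.index, "depth"] == "SRF"]
    mes = rich[meta_ix.loc[rich.index, "depth"] == "MES"]
    stats["ranksum_enriched_cluster_srf_vs_mes"] = ecology.rank_sum_test(srf, mes)
    exclusivity = ecology.fraction_exclusivity(abundance.presence, world.metadata)

    # --- host prediction against the planted references
    evidence = hosts.predict_hosts(
        {g.genome_id: g.sequence for g in world.genomes},
        world.hosts.spacers,
        world.hosts.phage_trnas,
        world.hosts.host_trnas,
        world.hosts.gene_hit_counts,
    )
    correct = sum(
        1 for e in evidence if e.consensus == world.hosts.host_truth[e.phage_id]
    )
    host_accuracy = correct / len(evidence) if evidence else 0.0

    result = PipelineResult(
        world=world,
        evenness_threshold=threshold,
        qc_reports=reports,
        population_assignment=assignment,
        population_ari=population_ari,
        partition=partition,
        cluster_labels=cluster_labels,
        cluster_ari=cluster_ari,
        profile=profile,
        discriminating_families=discriminating,
        abundance=abundance,
        stats=stats,
        exclusivity=exclusivity,
        host_evidence=evidence,
        host_accuracy=host_accuracy,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bin_qc.reports_to_frame(result.qc_reports).to_csv(
        outdir / "qc_report.tsv", sep="\t", index=False
    )
    result.population_assignment.to_frame().to_csv(
        outdir / "populations.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(result.cluster_labels.items()), columns=["genome_id", "cluster"]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    result.profile.category_means.to_csv(outdir / "cluster_category_profile.tsv", sep="\t")
    result.abundance.rpkm.to_csv(outdir / "rpkm_matrix.tsv", sep="\t")
    result.abundance.presence.astype(int).to_csv(outdir / "presence_matrix.tsv", sep="\t")
    result.exclusivity.to_csv(outdir / "fraction_exclusivity.tsv", sep="\t", index=False)
    hosts.evidence_to_frame(result.host_evidence).to_csv(
        outdir / "host_predictions.tsv", sep="\t", index=False
    )
    summary = {
        "seed": result.world.rng_seed,
        "evenness_threshold": result.evenness_threshold,
        "qc_pass_rate": result.qc_pass_rate,
        "population_ari": result.population_ari,
        "cluster_ari": result.cluster_ari,
        "modularity": result.partition.modularity_q,
        "host_accuracy": result.host_accuracy,
        "n_discriminating_families": len(result.discriminating_families),
        "stats": {
            k: {"statistic": v.statistic, "p_value": v.p_value}
            for k, v in result.stats.items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
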