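"""Synthetic metagenome worlds with planted ground truth.

The generator emulates every input the pipeline consumes: jumbo phage
genomes organised into planted gene-content clusters and ANI populations,
bins fragmented from those genomes (some deliberately contaminated with a
foreign contig), per-contig coverage tables across samples, read-mapping
summaries with planted depth/size-fraction structure, gene-family annotation
hit tables, and host signals (CRISPR spacers, tRNAs, taxon-labelled gene-hit
counts). Every table regenerates bit-identically from (parameters, seed).

Genomes are strings over {A,C,G,T}. Within a cluster, population ancestors
diverge from a cluster ancestor by per-base substitution; genome copies
diverge from their population ancestor the same way, so pairwise divergence
within a population is ~`within_divergence` and between populations
~`between_divergence`. No indels, read errors or assembly artefacts are
simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Contig, CoverageMatrix, Gene, Genome, GenomeBin

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEPTHS = ("SRF", "DCM", "MES")
BIOMES = ("Coastal", "Westerlies", "Trades")
PHYLA = ("Proteobacteria", "Cyanobacteria", "Firmicutes", "Bacteroidetes")
CATEGORIES = ("information processing", "virion structure", "metabolism", "cell biology", "other")

SUBSAMPLE_DEPTH = 20_000_000  # reads per sample after even-depth subsampling
READ_LENGTH = 100  # bp, for the covered-fraction saturation curve


def _random_seq_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution at the given rate (always to a different base)."""
    out = codes.copy()
    sites = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(sites):
        out[sites] = (out[sites] + rng.integers(1, 4, size=len(sites), dtype=np.uint8)) % 4
    return out


def _gene_coordinates(
    length: int, n_genes: int, rng: np.random.Generator, coding_fraction: float = 0.9
) -> list[tuple[int, int, str]]:
    """Non-overlapping gene intervals covering ~coding_fraction of the genome.

    Lengths are drawn uniform [300, 3000] bp then rescaled to hit the coding
    target (floor 60 bp), so the >= 80% coverage contract holds for any
    (length, n_genes) combination.
    """
    raw = rng.uniform(300, 3000, size=n_genes)
    target = coding_fraction * length
    lengths = np.maximum(60, np.round(raw * target / raw.sum()).astype(int))
    total_gap = length - lengths.sum()
    if total_gap < 0:  # rounding overshoot: trim the largest genes
        while lengths.sum() > length:
            lengths[np.argmax(lengths)] -= min(lengths.max() - 60, lengths.sum() - length)
        total_gap = length - lengths.sum()
    gaps = rng.multinomial(total_gap, np.ones(n_genes + 1) / (n_genes + 1))
    coords = []
    pos = 0
    for i, glen in enumerate(lengths):
        pos += gaps[i]
        strand = "+" if rng.random() < 0.5 else "-"
        coords.append((int(pos), int(pos + glen), strand))
        pos += glen
    return coords


def generate_genomes(
    n_clusters: int,
    genomes_per_cluster: int,
    length_range: tuple[int, int],
    genes_per_genome: int = 250,
    seed: int = 0,
    population_size: int = 2,
    within_divergence: float = 0.02,
    between_divergence: float = 0.10,
    families_per_cluster: int | None = None,
    family_noise: float = 0.05,
) -> tuple[list[Genome], dict[str, str], dict[str, str], dict[str, str]]:
    """Planted phage genomes with population and community (cluster) truth.

    Returns (genomes, population_truth, community_truth, family_of_gene).
    Consecutive groups of ``population_size`` genomes within a cluster share
    a population ancestor. Gene families come from cluster-specific pools
    (the planted gene-sharing communities) with a ``family_noise`` fraction
    drawn from the global pool.
    """
    lo, hi = length_range
    if not (200_000 <= lo <= hi):
        raise ValueError("genome lengths must be >= 200,000 bp and lo <= hi")
    if n_clusters < 1 or genomes_per_cluster < 1 or genes_per_genome < 1:
        raise ValueError("counts must be positive")
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    rng = np.random.default_rng(seed)
    if families_per_cluster is None:
        families_per_cluster = max(20, int(1.5 * genes_per_genome))
    pools = [
        [f"FAM{c:02d}_{i:04d}" for i in range(families_per_cluster)]
        for c in range(n_clusters)
    ]
    all_families = [f for pool in pools for f in pool]

    genomes: list[Genome] = []
    population_truth: dict[str, str] = {}
    community_truth: dict[str, str] = {}
    family_of_gene: dict[str, str] = {}
    for c in range(n_clusters):
        cluster_id = f"cluster_{c}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq_codes(rng, length)
        coords = _gene_coordinates(length, genes_per_genome, rng)
        n_pops = math.ceil(genomes_per_cluster / population_size)
        g_idx = 0
        for p in range(n_pops):
            pop_id = f"cluster_{c}_pop_{p}"
            pop_ancestor = _mutate(ancestor, between_divergence / 2.0, rng)
            n_copies = min(population_size, genomes_per_cluster - g_idx)
            for _ in range(n_copies):
                gid = f"g_c{c}p{p}n{g_idx:03d}"
                codes = _mutate(pop_ancestor, within_divergence / 2.0, rng)
                genes = []
                for k, (start, end, strand) in enumerate(coords):
                    gene_id = f"{gid}_gene{k:04d}"
                    genes.append(Gene(gene_id, gid, start, end, strand))
                    if rng.random() < family_noise:
                        fam = all_families[rng.integers(len(all_families))]
                    else:
                        fam = pools[c][rng.integers(len(pools[c]))]
                    family_of_gene[gene_id] = fam
                genomes.append(Genome(gid, _codes_to_str(codes), genes))
                population_truth[gid] = pop_id
                community_truth[gid] = cluster_id
                g_idx += 1
    return genomes, population_truth, community_truth, family_of_gene


def fragment_into_bins(
    genomes: list[Genome],
    contigs_per_bin: int | tuple[int, int] = (1, 5),
    contamination_rate: float = 0.0,
    seed: int = 0,
    min_contig_bp: int = 5_000,
) -> tuple[list[GenomeBin], dict[str, bool], dict[str, str]]:
    """Fragment each genome into a bin of 1-5 contigs; plant contaminants.

    A clean bin's contigs are a contiguous partition of one genome; a
    contaminated bin additionally carries exactly one contig cut from a
    different genome. Returns (bins, contamination_truth, foreign_contig)
    where foreign_contig maps contaminated bin id -> its foreign contig id.
    """
    if isinstance(contigs_per_bin, int):
        k_lo = k_hi = contigs_per_bin
    else:
        k_lo, k_hi = contigs_per_bin
    if not (1 <= k_lo <= k_hi <= 5):
        raise ValueError("contigs_per_bin must lie within 1..5")
    if not 0.0 <= contamination_rate <= 1.0:
        raise ValueError("contamination_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bins: list[GenomeBin] = []
    contamination_truth: dict[str, bool] = {}
    foreign_contig: dict[str, str] = {}
    for gi, genome in enumerate(genomes):
        bin_id = f"bin_{genome.genome_id}"
        contaminated = bool(rng.random() < contamination_rate) and len(genomes) > 1
        k = int(rng.integers(k_lo, k_hi + 1))
        if contaminated:
            k = min(k, 4)  # leave room for the foreign contig within the <= 5 rule
        if k * min_contig_bp > genome.length:
            raise ValueError(
                f"cannot cut {genome.genome_id} ({genome.length} bp) into {k} "
                f"contigs of >= {min_contig_bp} bp"
            )
        extra = rng.multinomial(genome.length - k * min_contig_bp, np.ones(k) / k)
        part_lengths = (min_contig_bp + extra).tolist()
        contigs: list[Contig] = []
        genes: list[Gene] = []
        pos = 0
        for ci, plen in enumerate(part_lengths):
            contig_id = f"{bin_id}_c{ci}"
            contigs.append(
                Contig(contig_id, plen, genome.sequence[pos : pos + plen],
                       source_genome=genome.genome_id)
            )
            for g in genome.genes:
                if g.start >= pos and g.end <= pos + plen:
                    genes.append(Gene(g.gene_id, contig_id, g.start - pos, g.end - pos, g.strand))
            pos += plen
        if contaminated:
            donor_idx = int(rng.integers(len(genomes) - 1))
            if donor_idx >= gi:
                donor_idx += 1
            donor = genomes[donor_idx]
            flen = int(rng.integers(10_000, min(60_000, donor.length // 4)))
            fstart = int(rng.integers(0, donor.length - flen))
            contig_id = f"{bin_id}_foreign"
            contigs.append(
                Contig(contig_id, flen, donor.sequence[fstart : fstart + flen],
                       source_genome=donor.genome_id)
            )
            for g in donor.genes:
                if g.start >= fstart and g.end <= fstart + flen:
                    genes.append(
                        Gene(f"{bin_id}_{g.gene_id}", contig_id,
                             g.start - fstart, g.end - fstart, g.strand)
                    )
            foreign_contig[bin_id] = contig_id
        bins.append(GenomeBin(bin_id, contigs, genes))
        contamination_truth[bin_id] = contaminated
    return bins, contamination_truth, foreign_contig


def simulate_coverage(
    bins: list[GenomeBin],
    n_samples: int,
    lognormal_params: tuple[float, float] = (2.0, 1.0),
    noise_cv: float = 0.1,
    seed: int = 0,
    foreign_contig: dict[str, str] | None = None,
) -> CoverageMatrix:
    """Per-contig mean coverage across samples.

    Contigs of a clean bin share one latent lognormal per-sample abundance
    perturbed by multiplicative lognormal noise with coefficient of variation
    ``noise_cv``; a planted foreign contig follows its own independent latent
    profile (that is the signal the evenness filter must detect).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    mu, sigma = lognormal_params
    foreign_contig = foreign_contig or {}
    if noise_cv > 0:
        s2 = math.log(1.0 + noise_cv**2)
        noise_mu, noise_sigma = -s2 / 2.0, math.sqrt(s2)
    samples = [f"s{j:03d}" for j in range(n_samples)]
    rows = {}
    lengths: dict[str, int] = {}
    bin_of: dict[str, str] = {}
    for b in bins:
        latent = rng.lognormal(mu, sigma, size=n_samples)
        foreign = foreign_contig.get(b.bin_id)
        latent_foreign = rng.lognormal(mu, sigma, size=n_samples) if foreign else None
        for c in b.contigs:
            base = latent_foreign if c.contig_id == foreign else latent
            if noise_cv > 0:
                cov = base * rng.lognormal(noise_mu, noise_sigma, size=n_samples)
            else:
                cov = base.copy()
            rows[c.contig_id] = cov
            lengths[c.contig_id] = c.length
            bin_of[c.contig_id] = b.bin_id
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return CoverageMatrix(values, lengths, bin_of)


def covered_fraction_curve(read_count, genome_length, read_length: int = READ_LENGTH):
    """Lander-Waterman saturation: 1 - exp(-reads * read_length / genome_length)."""
    read_count = np.asarray(read_count, dtype=float)
    return 1.0 - np.exp(-read_count * read_length / np.asarray(genome_length, dtype=float))


def simulate_mapping_and_metadata(
    populations: pd.DataFrame,
    n_stations: int = 20,
    depths: tuple[str, ...] = DEPTHS,
    fractions: tuple[str, ...] = ("0.1-0.22", "0.22-3"),
    depth_effects: dict[str, dict[str, float]] | None = None,
    fraction_effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    reads_lognormal: tuple[float, float] = (math.log(1000.0), 1.2),
    total_reads: int = SUBSAMPLE_DEPTH,
    read_length: int = READ_LENGTH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read-mapping summaries plus sample metadata with planted structure.

    ``populations`` needs columns population_id, genome_length, cluster.
    ``depth_effects``/``fraction_effects`` are multiplicative factors on the
    expected read count, keyed by cluster then by depth layer or fraction
    class. Read counts are Poisson around a per-station lognormal baseline;
    the covered fraction follows the saturation curve deterministically.
    """
    from .ecology import fraction_class  # local import to avoid a cycle

    required = {"population_id", "genome_length", "cluster"}
    if not required <= set(populations.columns):
        raise ValueError(f"populations table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    depth_effects = depth_effects or {}
    fraction_effects = fraction_effects or {}

    meta_rows = []
    for st in range(n_stations):
        station = f"st{st:03d}"
        biome = BIOMES[st % len(BIOMES)]
        for depth in depths:
            for frac in fractions:
                sample_id = f"{station}_{depth}_{frac}"
                meta_rows.append(
                    {"sample_id": sample_id, "station": station, "depth": depth,
                     "size_fraction": frac, "fraction_class": fraction_class(frac),
                     "biome": biome, "total_reads": total_reads}
                )
    metadata = pd.DataFrame(meta_rows)

    mu, sigma = reads_lognormal
    map_rows = []
    for _, pop in populations.iterrows():
        base_by_station = rng.lognormal(mu, sigma, size=n_stations)
        cluster = pop["cluster"]
        for si, m in enumerate(meta_rows):
            lam = base_by_station[si // (len(depths) * len(fractions))]
            lam *= depth_effects.get(cluster, {}).get(m["depth"], 1.0)
            lam *= fraction_effects.get(cluster, {}).get(m["fraction_class"], 1.0)
            count = int(rng.poisson(lam))
            cf = float(covered_fraction_curve(count, pop["genome_length"], read_length))
            map_rows.append(
                {"population_id": pop["population_id"], "sample_id": m["sample_id"],
                 "covered_fraction": cf, "read_count": count}
            )
    mapping = pd.DataFrame(map_rows)
    return mapping, metadata


@dataclass
class HostSignals:
    spacers: list[tuple[str, str, str, str]]  # (spacer_id, host_id, phylum, seq)
    host_trnas: list[tuple[str, str, str]]  # (trna_id, phylum, seq)
    phage_trnas: dict[str, list[tuple[str, str]]]  # phage -> [(trna_id, seq)]
    gene_hit_counts: dict[str, dict[str, int]]  # phage -> phylum -> count
    host_truth: dict[str, str | None]  # phage -> planted phylum (or None)


def plant_host_signals(
    genomes: list[Genome],
    n_hosts: int = 8,
    phyla: tuple[str, ...] = PHYLA,
    seed: int = 0,
    assigned_fraction: float = 0.5,
    spacer_len: int = 32,
    trna_len: int = 72,
    decoys_per_host: int = 3,
    plant_promiscuous_pair: bool = True,
    groups: dict[str, str] | None = None,
) -> HostSignals:
    """Host reference tables with planted phage-host links.

    Phages are grouped (``groups``: genome id -> group label, e.g. the
    planted gene-sharing cluster; default every phage its own group) and a
    random ``assigned_fraction`` of groups gets a host of one phylum: every
    member phage donates a CRISPR spacer (copied with 0-1 mismatches into a
    host), shares a tRNA with that host (<= 1 mismatch), and gets a dominant
    (>= 3x) gene-hit count for the phylum. Grouping at the cluster level
    keeps the truth consistent when near-identical genomes cross-match each
    other's spacers. Decoy spacers and tRNAs are independent random
    sequences; one cross-phylum promiscuous tRNA pair is planted among decoy
    hosts to exercise the removal rule.
    """
    if spacer_len <= 24:
        raise ValueError("planted spacers must exceed 24 bp")
    rng = np.random.default_rng(seed)
    hosts = [(f"host_{h:03d}", phyla[h % len(phyla)]) for h in range(n_hosts)]
    spacers: list[tuple[str, str, str, str]] = []
    host_trnas: list[tuple[str, str, str]] = []
    phage_trnas: dict[str, list[tuple[str, str]]] = {}
    gene_hits: dict[str, dict[str, int]] = {}
    host_truth: dict[str, str | None] = {}

    for hid, phylum in hosts:
        for d in range(decoys_per_host):
            spacers.append(
                (f"{hid}_sp{d}", hid, phylum, _codes_to_str(_random_seq_codes(rng, spacer_len)))
            )
            host_trnas.append(
                (f"{hid}_trna{d}", phylum, _codes_to_str(_random_seq_codes(rng, trna_len)))
            )
    if plant_promiscuous_pair and n_hosts >= 2:
        shared = _codes_to_str(_random_seq_codes(rng, trna_len))
        host_trnas.append((f"{hosts[0][0]}_trna_prom", hosts[0][1], shared))
        host_trnas.append((f"{hosts[1][0]}_trna_prom", hosts[1][1], shared))

    if groups is None:
        groups = {g.genome_id: g.genome_id for g in genomes}
    group_host: dict[str, tuple[str, str] | None] = {}
    for grp in sorted({groups[g.genome_id] for g in genomes}):
        if rng.random() < assigned_fraction:
            group_host[grp] = hosts[int(rng.integers(n_hosts))]
        else:
            group_host[grp] = None

    lookup = np.zeros(256, dtype=np.uint8)
    lookup[_BASES] = np.arange(4)
    for i, genome in enumerate(genomes):
        phage_trnas[genome.genome_id] = []
        assigned = group_host[groups[genome.genome_id]]
        if assigned is not None:
            hid, phylum = assigned
            host_truth[genome.genome_id] = phylum
            # spacer copied from the phage with 0-1 mismatches
            pos = int(rng.integers(0, genome.length - spacer_len))
            codes = lookup[np.frombuffer(
                genome.sequence[pos : pos + spacer_len].encode(), dtype=np.uint8
            )]
            n_mm = int(rng.integers(0, 2))
            spacer_seq = _codes_to_str(codes if n_mm == 0 else _flip_one(codes, rng))
            spacers.append((f"{hid}_planted_{genome.genome_id}", hid, phylum, spacer_seq))
            # shared tRNA with <= 1 mismatch
            trna_codes = _random_seq_codes(rng, trna_len)
            host_trnas.append((f"{hid}_trna_{genome.genome_id}", phylum, _codes_to_str(trna_codes)))
            phage_copy = _flip_one(trna_codes, rng) if rng.random() < 0.5 else trna_codes
            phage_trnas[genome.genome_id].append(
                (f"{genome.genome_id}_trna0", _codes_to_str(phage_copy))
            )
            # gene-content: dominant phylum with >= 3x the runner-up
            top = int(rng.integers(9, 15))
            second = int(rng.integers(0, top // 3 + 1))
            other = [p for p in phyla if p != phylum]
            counts = {phylum: top}
            if other:
                counts[other[int(rng.integers(len(other)))]] = second
            gene_hits[genome.genome_id] = counts
        else:
            host_truth[genome.genome_id] = None
            # balanced counts: no phylum reaches the 3x factor
            a, b = phyla[i % len(phyla)], phyla[(i + 1) % len(phyla)]
            n = int(rng.integers(4, 8))
            gene_hits[genome.genome_id] = {a: n, b: max(1, n - 1)}
    return HostSignals(spacers, host_trnas, phage_trnas, gene_hits, host_truth)


def make_classifier_scores(bins: list[GenomeBin], seed: int = 0) -> dict[str, "object"]:
    """Viral-classifier score tables for bins that are genuine phages.

    Per-contig dsDNA-phage scores are high (0.92-1.0) and CheckV quality is
    medium or better, so a clean world passes the composite viral rule.
    """
    from .bin_qc import ClassifierScores

    rng = np.random.default_rng(seed)
    qualities = ("medium", "high", "complete")
    out = {}
    for b in bins:
        out[b.bin_id] = ClassifierScores(
            bin_id=b.bin_id,
            dsdna_scores_per_contig=[float(rng.uniform(0.92, 1.0)) for _ in b.contigs],
            checkv_quality=qualities[int(rng.integers(len(qualities)))],
            vibrant_consensus_viral=bool(rng.random() < 0.9),
        )
    return out


def make_marker_tables(bins: list[GenomeBin], seed: int = 0) -> dict[str, pd.DataFrame]:
    """Per-bin annotation flags for the marker-conflict check (all clean)."""
    rng = np.random.default_rng(seed)
    out = {}
    for b in bins:
        n = int(rng.integers(20, 40))
        out[b.bin_id] = pd.DataFrame(
            {
                "gene_id": [f"{b.bin_id}_m{i}" for i in range(n)],
                "is_ribosomal": [False] * n,
                "is_ncldv_marker": [False] * n,
                "best_hit_kingdom": ["phage"] * (n - 1) + ["NCLDV"],
            }
        )
    return out


def reference_fragment_bins(
    n_references: int,
    length_range: tuple[int, int] = (200_000, 500_000),
    contigs_per_bin: tuple[int, int] = (2, 5),
    seed: int = 0,
    min_contig_bp: int = 5_000,
) -> list[GenomeBin]:
    """Artificially fragmented reference genomes for evenness calibration.

    Only contig lengths matter for the coverage-evenness statistic, so these
    bins carry no sequence. At least two contigs per reference (single-contig
    references carry no evenness information).
    """
    k_lo, k_hi = contigs_per_bin
    if not (2 <= k_lo <= k_hi <= 5):
        raise ValueError("reference fragmentation needs 2..5 contigs")
    rng = np.random.default_rng(seed)
    bins = []
    for r in range(n_references):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        k = int(rng.integers(k_lo, k_hi + 1))
        extra = rng.multinomial(length - k * min_contig_bp, np.ones(k) / k)
        contigs = [
            Contig(f"ref_{r:03d}_c{i}", int(min_contig_bp + e), source_genome=f"ref_{r:03d}")
            for i, e in enumerate(extra)
        ]
        bins.append(GenomeBin(f"ref_{r:03d}", contigs))
    return bins


def _flip_one(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    site = int(rng.integers(len(codes)))
    out[site] = (out[site] + rng.integers(1, 4)) % 4
    return out


def make_annotation_hits(
    genomes: list[Genome],
    family_of_gene: dict[str, str],
    seed: int = 0,
    known_fraction: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene -> family hit table (HMM-search-like) plus a category map.

    Every gene hits its planted family in the VOG-like database with a small
    e-value; a ``known_fraction`` of families gets a known functional
    category, the rest are unknown (mirroring the large unannotated share of
    environmental phage genes).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genome in genomes:
        for g in genome.genes:
            fam = family_of_gene[g.gene_id]
            rows.append(
                {"genome_id": genome.genome_id, "gene_id": g.gene_id, "db": "vog",
                 "family_id": fam, "e_value": float(10.0 ** rng.uniform(-30, -5)),
                 "bit_score": float(rng.uniform(50, 400)), "description": fam}
            )
    hits = pd.DataFrame(rows)
    families = sorted(set(family_of_gene.values()))
    known = rng.random(len(families)) < known_fraction
    cats = [
        CATEGORIES[int(rng.integers(len(CATEGORIES)))] if k else "unknown"
        for k in known
    ]
    category_map = pd.DataFrame(
        {"family_id": families, "category": cats, "known": known,
         "description": [f"synthetic family {f}" for f in families]}
    )
    return hits, category_map


@dataclass
class WorldConfig:
    """Study conditions for a synthetic world (defaults are the test bed)."""

    n_clusters: int = 4
    genomes_per_cluster: int = 6
    population_size: int = 2
    length_range: tuple[int, int] = (200_000, 500_000)
    genes_per_genome: int = 250
    within_divergence: float = 0.02
    between_divergence: float = 0.10
    families_per_cluster: int = 60
    family_noise: float = 0.05
    contigs_per_bin: tuple[int, int] = (1, 5)
    contamination_rate: float = 0.0
    n_coverage_samples: int = 50
    coverage_noise_cv: float = 0.1
    n_stations: int = 20
    fractions: tuple[str, ...] = ("0.1-0.22", "0.22-3")
    depth_effects: dict = field(
        default_factory=lambda: {"cluster_0": {"SRF": 10.0, "MES": 0.2}}
    )
    n_hosts: int = 8


@dataclass
class SyntheticWorld:
    config: WorldConfig
    rng_seed: int
    genomes: list[Genome]
    population_truth: dict[str, str]
    community_truth: dict[str, str]
    family_of_gene: dict[str, str]
    bins: list[GenomeBin]
    contamination_truth: dict[str, bool]
    foreign_contigs: dict[str, str]
    coverage: CoverageMatrix
    mapping: pd.DataFrame
    metadata: pd.DataFrame
    annotation_hits: pd.DataFrame
    category_map: pd.DataFrame
    hosts: HostSignals
    classifier_scores: dict = field(default_factory=dict)
    marker_tables: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Internal consistency of the planted truth tables."""
        bin_ids = {b.bin_id for b in self.bins}
        assert set(self.contamination_truth) == bin_ids
        for g in self.genomes:
            assert g.genome_id in self.population_truth
            assert g.genome_id in self.community_truth
        for b in self.bins:
            sources = {c.source_genome for c in b.contigs}
            expected = 2 if self.contamination_truth[b.bin_id] else 1
            assert len(sources) == expected, (b.bin_id, sources)


def make_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete synthetic study from one seed."""
    cfg = config or WorldConfig()
    genomes, pop_truth, comm_truth, fam_of_gene = generate_genomes(
        cfg.n_clusters,
        cfg.genomes_per_cluster,
        cfg.length_range,
        cfg.genes_per_genome,
        seed=seed,
        population_size=cfg.population_size,
        within_divergence=cfg.within_divergence,
        between_divergence=cfg.between_divergence,
        families_per_cluster=cfg.families_per_cluster,
        family_noise=cfg.family_noise,
    )
    bins, contam_truth, foreign = fragment_into_bins(
        genomes, cfg.contigs_per_bin, cfg.contamination_rate, seed=seed + 1
    )
    coverage = simulate_coverage(
        bins, cfg.n_coverage_samples, noise_cv=cfg.coverage_noise_cv,
        seed=seed + 2, foreign_contig=foreign,
    )
    populations = (
        pd.DataFrame(
            {
                "population_id": [pop_truth[g.genome_id] for g in genomes],
                "genome_length": [g.length for g in genomes],
                "cluster": [comm_truth[g.genome_id] for g in genomes],
            }
        )
        .groupby("population_id", as_index=False)
        .agg({"genome_length": "max", "cluster": "first"})
    )
    mapping, metadata = simulate_mapping_and_metadata(
        populations,
        n_stations=cfg.n_stations,
        fractions=cfg.fractions,
        depth_effects=cfg.depth_effects,
        seed=seed + 3,
    )
    hits, category_map = make_annotation_hits(genomes, fam_of_gene, seed=seed + 4)
    host_signals = plant_host_signals(
        genomes, cfg.n_hosts, seed=seed + 5, groups=comm_truth
    )
    classifier_scores = make_classifier_scores(bins, seed=seed + 6)
    marker_tables = make_marker_tables(bins, seed=seed + 7)
    world = SyntheticWorld(
        config=cfg,
        rng_seed=seed,
        genomes=genomes,
        population_truth=pop_truth,
        community_truth=comm_truth,
        family_of_gene=fam_of_gene,
        bins=bins,
        contamination_truth=contam_truth,
        foreign_contigs=foreign,
        coverage=coverage,
        mapping=mapping,
        metadata=metadata,
        annotation_hits=hits,
        category_map=category_map,
        hosts=host_signals,
        classifier_scores=classifier_scores,
        marker_tables=marker_tables,
    )
    world.validate()
    return world


def planted_bipartite(
    n_blocks: int = 4,
    genomes_per_block: int = 10,
    families_per_block: int = 30,
    p_in: float = 0.9,
    p_out: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Planted-partition bipartite hit table for community-detection tests.

    Genomes link to families of their own block with probability p_in and to
    foreign families with p_out. Returns (hit table, genome -> block truth).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for b in range(n_blocks):
        for g in range(genomes_per_block):
            gid = f"b{b}_g{g}"
            truth[gid] = f"block_{b}"
            for fb in range(n_blocks):
                p = p_in if fb == b else p_out
                link = rng.random(families_per_block) < p
                for f in np.flatnonzero(link):
                    rows.append(
                        {"genome_id": gid, "family_id": f"b{fb}_f{f}", "e_value": 1e-10}
                    )
    return pd.DataFrame(rows), truth
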