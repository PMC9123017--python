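"""Viral population clustering by gene-level average nucleotide identity.

Two genomes belong to the same population when they share >80% of their genes
at >95% average nucleotide identity; populations are the connected components
(single linkage) of the resulting threshold graph. Gene matching is best-hit:
every gene of the genome with fewer genes is aligned against candidate genes
of the other genome (k-mer prefilter, then edlib edit-distance alignment) and
matched to its best-identity partner, subject to a per-gene identity floor
that keeps chance alignments out of the average.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import networkx as nx
import pandas as pd

ANI_MIN = 95.0  # percent, strict >
FRAC_MIN = 0.80  # strict >
MATCH_IDENTITY_FLOOR = 0.90  # per-gene floor before averaging
PREFILTER_K = 15
PREFILTER_STRIDE = 16
PREFILTER_MIN_SHARED = 3


@dataclass(frozen=True)
class GenePair:
    """ANI summary for one genome pair."""

    genome_a: str
    genome_b: str
    ani: float  # percent identity over matched genes, alignment-length weighted
    shared_fraction: float  # matched genes / gene count of the smaller genome

    def __post_init__(self) -> None:
        if not 0.0 <= self.ani <= 100.0:
            raise ValueError(f"ani out of range: {self.ani}")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError(f"shared_fraction out of range: {self.shared_fraction}")

    def swapped(self) -> "GenePair":
        return GenePair(self.genome_b, self.genome_a, self.ani, self.shared_fraction)


@dataclass
class PopulationAssignment:
    population_of: dict[str, str]  # genome id -> population id
    representative_of: dict[str, str]  # population id -> representative genome id

    def populations(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for g, p in self.population_of.items():
            out[p].append(g)
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": g, "population_id": p,
             "is_representative": self.representative_of[p] == g}
            for g, p in sorted(self.population_of.items())
        ]
        return pd.DataFrame(rows)


def _gene_kmers(seq: str, k: int = PREFILTER_K, stride: int = PREFILTER_STRIDE) -> set[str]:
    """k-mers sampled on a fixed coordinate grid.

    Homologous substitution-diverged genes keep their coordinates, so their
    sampled k-mer sets intersect wherever a grid window is mutation-free;
    unrelated genes share essentially nothing.
    """
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)}


def _identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def pairwise_gene_ani(
    genes_a: dict[str, str],
    genes_b: dict[str, str],
    genome_a: str = "a",
    genome_b: str = "b",
    identity_floor: float = MATCH_IDENTITY_FLOOR,
    kmers_a: dict[str, set[str]] | None = None,
    kmers_b: dict[str, set[str]] | None = None,
) -> GenePair:
    """Gene-content ANI between two genomes.

    ``genes_a``/``genes_b`` map gene id to nucleotide sequence. Each gene of
    the smaller gene set is matched to its best-identity alignment in the
    other set; matches below ``identity_floor`` are discarded. The ANI is the
    alignment-length-weighted mean identity of the matches (percent), and
    shared_fraction is the matched count over the smaller gene count.
    """
    if not genes_a or not genes_b:
        raise ValueError("both genomes must have at least one gene")
    if kmers_a is None:
        kmers_a = {g: _gene_kmers(s) for g, s in genes_a.items()}
    if kmers_b is None:
        kmers_b = {g: _gene_kmers(s) for g, s in genes_b.items()}
    if len(genes_a) <= len(genes_b):
        query, subject = genes_a, genes_b
        query_kmers, subject_kmers = kmers_a, kmers_b
        qid, sid = genome_a, genome_b
    else:
        query, subject = genes_b, genes_a
        query_kmers, subject_kmers = kmers_b, kmers_a
        qid, sid = genome_b, genome_a

    # k-mer prefilter: only align gene pairs sharing enough sampled k-mers
    kmer_index: dict[str, list[str]] = defaultdict(list)
    for gid in subject:
        for km in subject_kmers[gid]:
            kmer_index[km].append(gid)

    matched = 0
    weight_sum = 0.0
    identity_sum = 0.0
    for qgid, seq in query.items():
        counts: dict[str, int] = defaultdict(int)
        for km in query_kmers[qgid]:
            for gid in kmer_index.get(km, ()):
                counts[gid] += 1
        candidates = [g for g, c in counts.items() if c >= PREFILTER_MIN_SHARED]
        best = 0.0
        best_len = 0
        for gid in candidates:
            other = subject[gid]
            ident = _identity(seq, other)
            if ident > best:
                best = ident
                best_len = max(len(seq), len(other))
        if best >= identity_floor:
            matched += 1
            weight_sum += best_len
            identity_sum += best * best_len
    ani = 100.0 * identity_sum / weight_sum if weight_sum else 0.0
    shared = matched / len(query)
    pair = GenePair(qid, sid, ani=ani, shared_fraction=shared)
    # report in caller's (a, b) order
    return pair if (qid, sid) == (genome_a, genome_b) else pair.swapped()


def all_pairwise_ani(gene_sets: dict[str, dict[str, str]]) -> list[GenePair]:
    """ANI for every unordered genome pair (prefilter k-mers computed once)."""
    ids = sorted(gene_sets)
    kmers = {
        gid: {g: _gene_kmers(s) for g, s in genes.items()}
        for gid, genes in gene_sets.items()
    }
    return [
        pairwise_gene_ani(gene_sets[a], gene_sets[b], a, b,
                          kmers_a=kmers[a], kmers_b=kmers[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    ]


def build_population_graph(
    pairs: list[GenePair],
    genomes: list[str],
    ani_min: float = ANI_MIN,
    frac_min: float = FRAC_MIN,
) -> nx.Graph:
    """Threshold graph: edge iff ani > ani_min AND shared_fraction > frac_min."""
    if not 0 <= ani_min <= 100 or not 0 <= frac_min <= 1:
        raise ValueError("thresholds out of range")
    g = nx.Graph()
    g.add_nodes_from(genomes)
    for p in pairs:
        if p.ani > ani_min and p.shared_fraction > frac_min:
            g.add_edge(p.genome_a, p.genome_b, ani=p.ani, shared_fraction=p.shared_fraction)
    return g


def cluster_populations(
    graph: nx.Graph, genome_lengths: dict[str, int] | None = None
) -> PopulationAssignment:
    """Single-linkage populations = connected components of the threshold graph.

    The representative of each population is its longest genome (ties broken
    by lexicographically smallest id); without lengths, the smallest id.
    """
    population_of: dict[str, str] = {}
    representative_of: dict[str, str] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for idx, comp in enumerate(components):
        members = sorted(comp)
        pop_id = f"pop_{idx:04d}"
        if genome_lengths is not None:
            rep = min(members, key=lambda g: (-genome_lengths.get(g, 0), g))
        else:
            rep = members[0]
        for m in members:
            population_of[m] = pop_id
        representative_of[pop_id] = rep
    return PopulationAssignment(population_of, representative_of)


def cluster_genomes(
    gene_sets: dict[str, dict[str, str]],
    genome_lengths: dict[str, int] | None = None,
    ani_min: float = ANI_MIN,
    frac_min: float = FRAC_MIN,
) -> tuple[PopulationAssignment, list[GenePair]]:
    """Convenience: ANI for all pairs, threshold graph, connected components."""
    pairs = all_pairwise_ani(gene_sets)
    graph = build_population_graph(pairs, sorted(gene_sets), ani_min, frac_min)
    return cluster_populations(graph, genome_lengths), pairs
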