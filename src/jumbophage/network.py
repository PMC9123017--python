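"""Bipartite gene-sharing network and Phage Genome Cluster detection.

Genomes and gene families (VOG-like orthologous groups) are the two node
kinds; an edge records that a genome encodes at least one member of a family.
Communities are found with the Reichardt-Bornholdt spinglass Potts model
(simulated annealing, q spin states) run many times with independent seeds;
the partition of the run with the highest Newman-Girvan modularity is kept.
Genome-side communities, relabelled by decreasing size, are the Phage Genome
Clusters (PGCs).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd


@dataclass
class BipartiteNetwork:
    genome_nodes: list[str]
    family_nodes: list[str]
    edges: set[tuple[str, str]]  # (genome, family)

    def __post_init__(self) -> None:
        genomes = set(self.genome_nodes)
        families = set(self.family_nodes)
        if genomes & families:
            raise ValueError("genome and family node ids overlap")
        for g, f in self.edges:
            if g not in genomes or f not in families:
                raise ValueError(f"edge ({g}, {f}) references unknown node")

    @property
    def nodes(self) -> list[str]:
        return list(self.genome_nodes) + list(self.family_nodes)

    def degree_zero_genomes(self) -> list[str]:
        linked = {g for g, _ in self.edges}
        return [g for g in self.genome_nodes if g not in linked]

    def to_igraph(self) -> igraph.Graph:
        nodes = self.nodes
        idx = {n: i for i, n in enumerate(nodes)}
        g = igraph.Graph(len(nodes), [(idx[a], idx[b]) for a, b in sorted(self.edges)])
        g.vs["name"] = nodes
        g.vs["kind"] = ["genome"] * len(self.genome_nodes) + ["family"] * len(self.family_nodes)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["genome_id", "family_id"])


@dataclass
class SpinglassParams:
    n_spins: int = 50
    n_runs: int = 100
    gamma: float = 1.0
    start_temp: float = 1.0
    stop_temp: float = 0.01
    cooling_factor: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spins < 2:
            raise ValueError("need at least 2 spins")
        if not self.stop_temp < self.start_temp:
            raise ValueError("stop_temp must be < start_temp")
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class Partition:
    membership: dict[str, int]  # node id -> community id
    modularity_q: float
    run_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.modularity_q <= 1.0:
            raise ValueError(f"modularity out of range: {self.modularity_q}")

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return out


def build_network(
    hits: pd.DataFrame,
    genomes: list[str] | None = None,
    e_max: float = 0.001,
) -> BipartiteNetwork:
    """Bipartite network from a gene-family hit table.

    ``hits`` needs columns genome_id, family_id, e_value. An edge is drawn
    when a genome has at least one hit to the family with e_value <= e_max.
    Families with no qualifying hit are omitted; genomes given in ``genomes``
    are retained even with zero qualifying hits (degree-0, "unclassifiable").
    """
    required = {"genome_id", "family_id", "e_value"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    bad = hits["e_value"] < 0
    if bad.any():
        raise ValueError(f"negative e_value at table row {int(np.argmax(bad.to_numpy()))}")
    keep = hits[hits["e_value"] <= e_max]
    edges = {(str(g), str(f)) for g, f in zip(keep["genome_id"], keep["family_id"])}
    genome_nodes = sorted(set(hits["genome_id"].astype(str)) | set(genomes or []))
    family_nodes = sorted({f for _, f in edges})
    return BipartiteNetwork(genome_nodes, family_nodes, edges)


def modularity(network: BipartiteNetwork | igraph.Graph, membership: dict[str, int]) -> float:
    """Newman-Girvan modularity Q of a partition on the undirected graph.

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j), computed per
    community as (within-edges/m - (degree-sum/2m)^2).
    """
    g = network.to_igraph() if isinstance(network, BipartiteNetwork) else network
    m = g.ecount()
    if m == 0:
        raise ValueError("modularity undefined on an empty edge set")
    names = g.vs["name"] if "name" in g.vs.attributes() else list(range(g.vcount()))
    unassigned = [n for n in names if n not in membership]
    if unassigned:
        raise ValueError(f"partition misses nodes: {unassigned[:5]}")
    degrees = g.degree()
    within: dict[int, float] = {}
    dsum: dict[int, float] = {}
    comm = [membership[n] for n in names]
    for v, (c, k) in enumerate(zip(comm, degrees)):
        dsum[c] = dsum.get(c, 0.0) + k
    for e in g.es:
        if comm[e.source] == comm[e.target]:
            c = comm[e.source]
            within[c] = within.get(c, 0.0) + 1.0
    q = 0.0
    for c, d in dsum.items():
        q += within.get(c, 0.0) / m - (d / (2.0 * m)) ** 2
    return q


def spinglass_once(
    network: BipartiteNetwork | igraph.Graph,
    params: SpinglassParams,
    run_seed: int,
    run_index: int = 0,
) -> Partition:
    """One seeded spinglass annealing run on a connected graph.

    Minimises the Potts Hamiltonian H = -sum_{i<j} (A_ij - gamma k_i k_j/2m)
    delta(sigma_i, sigma_j) by simulated annealing over q spin states
    (igraph's Reichardt-Bornholdt implementation). Deterministic for a given
    run_seed.
    """
    g = network.to_igraph() if isinstance(network, BipartiteNetwork) else network
    if len(g.components()) != 1:
        raise ValueError("spinglass requires a connected graph; cluster per component")
    igraph.set_random_number_generator(random.Random(run_seed))
    cl = g.community_spinglass(
        spins=params.n_spins,
        gamma=params.gamma,
        start_temp=params.start_temp,
        stop_temp=params.stop_temp,
        cool_fact=params.cooling_factor,
    )
    igraph.set_random_number_generator(random)  # restore default
    names = g.vs["name"] if "name" in g.vs.attributes() else list(range(g.vcount()))
    membership = dict(zip(names, cl.membership))
    return Partition(membership, modularity(g, membership), run_index=run_index, seed=run_seed)


def detect_communities(
    network: BipartiteNetwork,
    params: SpinglassParams,
) -> tuple[Partition, pd.DataFrame]:
    """Best-of-n_runs spinglass partition, per connected component.

    Each connected component with at least one edge is clustered independently
    (the spinglass model is undefined across disconnected graphs) with
    run_seed = seed + run_index. Candidate partitions of a component — every
    annealing run plus the trivial one-community partition — are scored by
    their contribution to the modularity of the FULL network (per-component
    subgraph modularity uses the wrong null model when other components hold
    part of the edge mass); the highest contribution wins, ties going to the
    lowest run index. Component-wise labels are merged disjointly; isolated
    nodes get singleton communities. The returned modularity is that of the
    merged partition on the full network.
    """
    g = network.to_igraph()
    m_full = g.ecount()
    comps = g.components()
    merged: dict[str, int] = {}
    offset = 0
    runs: list[dict] = []

    def contribution(sub: igraph.Graph, membership: list[int]) -> float:
        within: dict[int, float] = {}
        dsum: dict[int, float] = {}
        for v, c in enumerate(membership):
            dsum[c] = dsum.get(c, 0.0) + sub.degree(v)
        for e in sub.es:
            if membership[e.source] == membership[e.target]:
                c = membership[e.source]
                within[c] = within.get(c, 0.0) + 1.0
        return sum(
            within.get(c, 0.0) / m_full - (d / (2.0 * m_full)) ** 2
            for c, d in dsum.items()
        )

    for ci, comp in enumerate(comps):
        sub = g.subgraph(comp)
        names = sub.vs["name"]
        if sub.ecount() == 0:
            for n in names:
                merged[n] = offset
                offset += 1
            continue
        best_membership = [0] * sub.vcount()  # trivial single community
        best_score = contribution(sub, best_membership)
        for r in range(params.n_runs):
            part = spinglass_once(sub, params, run_seed=params.seed + r, run_index=r)
            mem = [part.membership[n] for n in names]
            score = contribution(sub, mem)
            runs.append({"component": ci, "run_index": r, "seed": params.seed + r,
                         "modularity": part.modularity_q, "contribution": score})
            if score > best_score:
                best_score = score
                best_membership = mem
        relabel = {c: offset + i for i, c in enumerate(sorted(set(best_membership)))}
        for n, c in zip(names, best_membership):
            merged[n] = relabel[c]
        offset += len(relabel)
    q = modularity(network, merged) if network.edges else 0.0
    best_part = Partition(merged, q, run_index=-1, seed=params.seed)
    return best_part, pd.DataFrame(runs)


def extract_genome_clusters(
    partition: Partition, network: BipartiteNetwork
) -> dict[str, str]:
    """Genome-side cluster labels (PGC-like), by decreasing cluster size.

    Communities restricted to genome nodes are renamed A, B, C, ... in
    decreasing genome-count order (ties by smallest member id); genomes with
    no family edge are labelled "unassigned".
    """
    degree_zero = set(network.degree_zero_genomes())
    by_comm: dict[int, list[str]] = {}
    for gnode in network.genome_nodes:
        if gnode in degree_zero:
            continue
        by_comm.setdefault(partition.membership[gnode], []).append(gnode)
    ordered = sorted(by_comm.values(), key=lambda ms: (-len(ms), sorted(ms)[0]))
    labels: dict[str, str] = {}
    for i, members in enumerate(ordered):
        label = _alpha_label(i)
        for m in members:
            labels[m] = label
    for gnode in degree_zero:
        labels[gnode] = "unassigned"
    return labels


def _alpha_label(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def summarize_clusters(
    assignments: dict[str, str],
    metadata: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-cluster composition tables.

    ``metadata`` may carry genome_id plus any of: length_bp, environment,
    host_phylum. Missing metadata values fall into an "NA" class.
    """
    assign = pd.DataFrame(
        sorted(assignments.items()), columns=["genome_id", "cluster"]
    )
    if metadata is None:
        metadata = pd.DataFrame({"genome_id": assign["genome_id"]})
    merged = assign.merge(metadata, on="genome_id", how="left")
    out: dict[str, pd.DataFrame] = {"membership": assign}
    if "length_bp" in merged.columns:
        out["length_summary"] = (
            merged.groupby("cluster")["length_bp"]
            .agg(["count", "min", "median", "max"])
            .reset_index()
        )
    for col in ("environment", "host_phylum"):
        filled = merged[col].fillna("NA") if col in merged.columns else pd.Series(
            ["NA"] * len(merged)
        )
        counts = (
            pd.DataFrame({"cluster": merged["cluster"], col: filled})
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["cluster", col])
            .reset_index(drop=True)
        )
        out[f"{col}_counts"] = counts
    return out
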