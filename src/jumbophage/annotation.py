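"""Consensus functional annotation and per-cluster functional profiles.

Each gene carries hits against up to three protein-family databases (Pfam,
eggNOG, VOG). The consensus takes the best Pfam hit when one exists, else the
higher-bit-score of the best eggNOG and best VOG hits; genes with no hit are
"hypothetical protein" (category "unknown"). Profiles aggregate category
proportions per genome and average them within genome clusters; families
whose per-cluster genome-presence fractions vary strongly (sample variance
above a cutoff) and that have a known function are the discriminating genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

E_VALUE_MAX = 0.001  # strict <
DB_ORDER = ("pfam", "eggnog", "vog")

HYPOTHETICAL = ("none", "none", "hypothetical protein", "unknown")


@dataclass(frozen=True)
class Hit:
    db: str
    family_id: str
    e_value: float
    bit_score: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.db not in DB_ORDER:
            raise ValueError(f"unknown db {self.db!r}")
        if self.e_value < 0:
            raise ValueError("negative e_value")


def default_category_map() -> pd.DataFrame:
    """Curated example family -> functional category map shipped as TSV.

    Columns: family_id, category, known (bool), description. Synthetic
    worlds generate their own map; this resource illustrates the format.
    """
    with resources.files("jumbophage.data").joinpath("functional_categories.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["known"] = df["known"].astype(bool)
    return df


def consensus_annotation(
    hits: list[Hit],
    category_map: pd.DataFrame | None = None,
    e_max: float = E_VALUE_MAX,
) -> tuple[str, str, str, str]:
    """Consensus (db, family_id, function, category) for one gene.

    Precedence: any Pfam hit beats everything; otherwise the higher bit score
    of the best eggNOG vs best VOG hit. Ties break by lower e-value, then
    lexicographic family id. Hits at e_value >= e_max are ignored.
    """
    usable = [h for h in hits if h.e_value < e_max]
    if not usable:
        return HYPOTHETICAL

    def best(cands: list[Hit]) -> Hit:
        return min(cands, key=lambda h: (-h.bit_score, h.e_value, h.family_id))

    pfam = [h for h in usable if h.db == "pfam"]
    if pfam:
        chosen = best(pfam)
    else:
        others = [h for h in usable if h.db in ("eggnog", "vog")]
        if not others:
            return HYPOTHETICAL
        chosen = best(others)
    category = "unknown"
    function = chosen.description or chosen.family_id
    if category_map is not None:
        row = category_map.loc[category_map["family_id"] == chosen.family_id]
        if len(row):
            category = str(row.iloc[0]["category"])
            if not bool(row.iloc[0].get("known", True)):
                category = "unknown"
    return (chosen.db, chosen.family_id, function, category)


def consensus_table(
    hit_table: pd.DataFrame,
    category_map: pd.DataFrame | None = None,
    e_max: float = E_VALUE_MAX,
) -> pd.DataFrame:
    """Per-gene consensus from a long hit table.

    ``hit_table`` columns: gene_id, db, family_id, e_value, bit_score and
    optionally description. Genes appearing in the table with no qualifying
    hit come out hypothetical.
    """
    rows = []
    for gene_id, sub in hit_table.groupby("gene_id", sort=True):
        hits = [
            Hit(r.db, str(r.family_id), float(r.e_value), float(r.bit_score),
                getattr(r, "description", "") or "")
            for r in sub.itertuples()
        ]
        db, fam, func, cat = consensus_annotation(hits, category_map, e_max)
        rows.append({"gene_id": gene_id, "source_db": db, "family_id": fam,
                     "function": func, "category": cat})
    return pd.DataFrame(rows)


@dataclass
class ClusterFunctionProfile:
    category_means: pd.DataFrame  # cluster x category, mean proportion of genes
    presence_fractions: pd.DataFrame  # cluster x family, fraction of genomes with >=1 copy
    per_genome_categories: pd.DataFrame  # genome x category proportions


def profile_clusters(
    gene_table: pd.DataFrame,
    cluster_of: dict[str, str],
) -> ClusterFunctionProfile:
    """Functional profile per genome cluster.

    ``gene_table`` columns: genome_id, gene_id, family_id, category (the
    consensus output joined with genome membership). Per genome, category
    proportions (unknowns included) sum to 1; cluster profiles are the means
    of the member-genome proportions. Presence fractions count genomes in the
    cluster encoding at least one gene of the family.
    """
    missing = {str(g) for g in gene_table["genome_id"]} - set(cluster_of)
    if missing:
        raise ValueError(f"genomes without cluster assignment: {sorted(missing)[:5]}")
    tab = gene_table.copy()
    tab["cluster"] = tab["genome_id"].map(cluster_of)

    counts = (
        tab.groupby(["genome_id", "category"], sort=True).size().unstack(fill_value=0)
    )
    per_genome = counts.div(counts.sum(axis=1), axis=0)
    cat_means = (
        per_genome.assign(cluster=[cluster_of[g] for g in per_genome.index])
        .groupby("cluster")
        .mean()
    )

    genomes_per_cluster = (
        tab[["genome_id", "cluster"]].drop_duplicates().groupby("cluster").size()
    )
    with_family = (
        tab[tab["family_id"] != "none"][["cluster", "family_id", "genome_id"]]
        .drop_duplicates()
        .groupby(["cluster", "family_id"])
        .size()
        .unstack(fill_value=0)
    )
    presence = with_family.div(genomes_per_cluster, axis=0).fillna(0.0)
    return ClusterFunctionProfile(cat_means, presence, per_genome)


def select_discriminating_genes(
    presence_fractions: pd.DataFrame,
    known_families: set[str] | None = None,
    var_min: float = 0.2,
    clusters: list[str] | None = None,
) -> list[str]:
    """Families whose presence varies across clusters and have known function.

    Variance is the sample variance (n-1 denominator) of the per-cluster
    genome-presence fractions; ``clusters`` restricts which clusters enter
    the variance (e.g. to drop a singleton cluster).
    """
    frame = presence_fractions if clusters is None else presence_fractions.loc[clusters]
    if len(frame) < 2:
        raise ValueError("need at least two clusters to compute variance")
    variances = frame.var(axis=0, ddof=1)
    selected = [
        str(fam)
        for fam, v in variances.items()
        if v > var_min and (known_families is None or fam in known_families)
    ]
    return sorted(selected)


def unknown_proportion_summary(per_genome_categories: pd.DataFrame) -> tuple[float, float]:
    """Mean and sd (percent) of the per-genome unknown-function proportion."""
    if "unknown" not in per_genome_categories.columns:
        return 0.0, 0.0
    vals = per_genome_categories["unknown"].to_numpy(dtype=float) * 100.0
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
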