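"""Detection, abundance and community-composition statistics.

Read-mapping summaries (covered fraction and mapped read count per phage
population per sample) become presence/absence and RPKM matrices; community
composition is compared between sample groupings (size-fraction class, depth
layer, biome) with ANOSIM permutation tests on Bray-Curtis distances and
per-sample richness/abundance with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DETECTION_THRESHOLD = 0.20  # inclusive: "min. 20% of genome covered"
EXACT_RANKSUM_MAX_N = 12

DEPTH_LAYERS = ("SRF", "DCM", "MES")


@dataclass
class AbundanceMatrix:
    """Population x sample abundance grids derived from read mapping."""

    covered_fraction: pd.DataFrame  # populations x samples, in [0, 1]
    read_count: pd.DataFrame  # nonnegative integers
    rpkm: pd.DataFrame
    presence: pd.DataFrame  # booleans
    genome_length: pd.Series  # bp per population
    total_reads: pd.Series  # per sample

    @property
    def populations(self) -> list[str]:
        return list(self.covered_fraction.index)

    @property
    def samples(self) -> list[str]:
        return list(self.covered_fraction.columns)


@dataclass
class StatResult:
    statistic: float
    p_value: float
    method: str
    grouping: str = ""
    matrix_type: str = ""
    n_permutations: int = 0
    seed: int | None = None


def detect_presence(covered_fraction, threshold: float = DETECTION_THRESHOLD):
    """Presence call: covered fraction >= threshold (inclusive)."""
    arr = np.asarray(covered_fraction, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("covered fractions must lie in [0, 1]")
    result = arr >= threshold
    return bool(result) if np.isscalar(covered_fraction) else result


def rpkm(read_count, genome_length, total_reads):
    """Reads per kilobase of genome per million sample reads."""
    genome_length = np.asarray(genome_length, dtype=float)
    total_reads = np.asarray(total_reads, dtype=float)
    if (genome_length <= 0).any() or (total_reads <= 0).any():
        raise ValueError("genome_length and total_reads must be positive")
    return np.asarray(read_count, dtype=float) / (
        (genome_length / 1_000.0) * (total_reads / 1_000_000.0)
    )


def build_abundance_matrix(
    mapping: pd.DataFrame,
    genome_length: dict[str, int],
    total_reads: dict[str, int] | int,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> AbundanceMatrix:
    """Assemble the abundance grids from a long mapping table.

    ``mapping`` columns: population_id, sample_id, covered_fraction,
    read_count. ``total_reads`` is per sample (dict) or one even depth (int).
    """
    cov = mapping.pivot_table(
        index="population_id", columns="sample_id", values="covered_fraction", fill_value=0.0
    ).sort_index()
    cnt = (
        mapping.pivot_table(
            index="population_id", columns="sample_id", values="read_count", fill_value=0
        )
        .sort_index()
        .astype(int)
    )
    samples = list(cov.columns)
    if isinstance(total_reads, int):
        totals = pd.Series({s: total_reads for s in samples})
    else:
        totals = pd.Series(total_reads).reindex(samples)
        if totals.isna().any():
            raise ValueError("total_reads missing for some samples")
    lengths = pd.Series(genome_length).reindex(cov.index)
    if lengths.isna().any():
        raise ValueError("genome_length missing for some populations")
    rpkm_grid = pd.DataFrame(
        rpkm(cnt.to_numpy(), lengths.to_numpy()[:, None], totals.to_numpy()[None, :]),
        index=cov.index,
        columns=cov.columns,
    )
    presence = pd.DataFrame(
        detect_presence(cov.to_numpy(), detection_threshold),
        index=cov.index,
        columns=cov.columns,
    )
    return AbundanceMatrix(cov, cnt, rpkm_grid, presence, lengths, totals)


def richness(presence: pd.DataFrame) -> pd.Series:
    """Populations detected per sample (column sums of the presence matrix)."""
    return presence.sum(axis=0).astype(int)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    d(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik). A pair of all-zero
    samples gets distance 0 with a warning (rather than NaN).
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative entries")
    n = x.shape[1]
    d = np.zeros((n, n))
    zero_pair = False
    for j in range(n):
        for k in range(j + 1, n):
            denom = (x[:, j] + x[:, k]).sum()
            if denom == 0:
                zero_pair = True
                val = 0.0
            else:
                val = float(np.abs(x[:, j] - x[:, k]).sum() / denom)
            d[j, k] = d[k, j] = val
    if zero_pair:
        logger.warning("all-zero sample pair(s): Bray-Curtis distance set to 0")
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def anosim(
    distances: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> StatResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2), the
    standard Clarke denominator, with ranks taken over all M = n(n-1)/2
    dissimilarities; the p-value counts label permutations with R >= observed,
    including the observed arrangement ((1 + hits) / (1 + n_permutations)).
    """
    labels = pd.Series(groups).reindex(distances.index)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 samples each")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    dvec = distances.to_numpy(dtype=float)[iu]
    ranks = sps.rankdata(dvec)
    m = len(ranks)
    denom = m / 2.0
    codes = labels.factorize()[0]

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    lab = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if r_stat(lab) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return StatResult(float(observed), float(p), method="anosim",
                      n_permutations=n_permutations, seed=seed)


def anosim_exhaustive(distances: pd.DataFrame, groups: pd.Series | dict[str, str]) -> StatResult:
    """Exact ANOSIM p by enumerating every distinct label arrangement.

    Only feasible for a handful of samples; used as the oracle for the
    permutation version.
    """
    labels = pd.Series(groups).reindex(distances.index)
    codes = labels.factorize()[0]
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks = sps.rankdata(distances.to_numpy(dtype=float)[iu])
    denom = len(ranks) / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(codes)
    hits = 0
    total = 0
    for perm in set(itertools.permutations(codes)):
        total += 1
        if r_stat(np.array(perm)) >= observed - 1e-12:
            hits += 1
    return StatResult(float(observed), hits / total, method="anosim_exhaustive",
                      n_permutations=total)


def rank_sum_test(values_a, values_b) -> StatResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of all rank splits when n_a + n_b <= 12 (handles ties,
    and makes identical groups give p = 1); otherwise the normal
    approximation with tie correction (Mann-Whitney U).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:na].sum()
    mean_w = na * (na + nb + 1) / 2.0
    if na + nb <= EXACT_RANKSUM_MAX_N:
        dev_obs = abs(w_obs - mean_w)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(na + nb), na):
            total += 1
            if abs(ranks[list(comb)].sum() - mean_w) >= dev_obs - 1e-12:
                hits += 1
        return StatResult(float(w_obs), hits / total, method="ranksum_exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StatResult(float(res.statistic), float(res.pvalue), method="ranksum_normal")


def fraction_class(size_fraction: str) -> str:
    """Classify a Tara-style size-fraction label relative to 0.22 um.

    A sample is below_022 when the fraction's upper bound is <= 0.22 um,
    above_022 when the lower bound is >= 0.22 um; anything else is mixed.
    Labels look like "0.1-0.22", "<-0.22", "0.22-3".
    """
    lab = size_fraction.replace("–", "-").replace("um", "").strip()
    if lab.startswith("<"):
        return "below_022"
    parts = [p for p in lab.split("-") if p not in ("", "<", ">")]
    try:
        bounds = [float(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"cannot parse size fraction {size_fraction!r}") from exc
    if len(bounds) == 1:
        return "below_022" if bounds[0] <= 0.22 else "above_022"
    lo, hi = min(bounds), max(bounds)
    if hi <= 0.22:
        return "below_022"
    if lo >= 0.22:
        return "above_022"
    return "mixed"


def fraction_exclusivity(
    presence: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per detected population: found only above, only below, or both sides of 0.22 um.

    Undetected populations are excluded from the denominators, matching the
    convention of reporting exclusivity among detected populations only.
    Returns a frame with columns population_id, exclusivity.
    """
    meta = metadata.set_index("sample_id")
    classes = meta["fraction_class"] if "fraction_class" in meta.columns else meta[
        "size_fraction"
    ].map(fraction_class)
    rows = []
    for pop, row in presence.iterrows():
        detected = row[row].index
        if len(detected) == 0:
            continue
        cls = set(classes.reindex(detected))
        has_above = "above_022" in cls
        has_below = "below_022" in cls
        if has_above and not has_below:
            label = "only_above_022"
        elif has_below and not has_above:
            label = "only_below_022"
        else:
            label = "both"
        rows.append({"population_id": pop, "exclusivity": label})
    return pd.DataFrame(rows, columns=["population_id", "exclusivity"])


def exclusivity_summary(exclusivity: pd.DataFrame) -> pd.DataFrame:
    total = len(exclusivity)
    counts = exclusivity["exclusivity"].value_counts()
    return pd.DataFrame(
        {
            "exclusivity": counts.index,
            "count": counts.to_numpy(),
            "fraction_of_detected": counts.to_numpy() / total if total else np.nan,
        }
    )


def co_collected_subset(
    metadata: pd.DataFrame,
    require: str = "both_fraction_classes",
) -> pd.DataFrame:
    """Samples from station-depth groups usable for paired comparisons.

    ``require`` = "both_fraction_classes": keep groups having both a
    below-0.22 and an above-0.22 sample; "all_depths": keep stations sampled
    at all three depth layers.
    """
    meta = metadata.copy()
    if "fraction_class" not in meta.columns:
        meta["fraction_class"] = meta["size_fraction"].map(fraction_class)
    if require == "both_fraction_classes":
        keep = []
        for (_, _), sub in meta.groupby(["station", "depth"]):
            cls = set(sub["fraction_class"])
            if {"above_022", "below_022"} <= cls:
                keep.append(sub[sub["fraction_class"].isin(["above_022", "below_022"])])
        return pd.concat(keep, ignore_index=True) if keep else meta.iloc[0:0]
    if require == "all_depths":
        keep = []
        for _, sub in meta.groupby("station"):
            if set(DEPTH_LAYERS) <= set(sub["depth"]):
                keep.append(sub)
        return pd.concat(keep, ignore_index=True) if keep else meta.iloc[0:0]
    raise ValueError(f"unknown mode {require!r}")


def compare_groups(
    abundance: AbundanceMatrix,
    metadata: pd.DataFrame,
    by: str,
    matrix_type: str = "presence",
    n_permutations: int = 9999,
    seed: int = 0,
) -> StatResult:
    """ANOSIM of community composition grouped by a metadata column."""
    grid = getattr(abundance, matrix_type)
    if matrix_type == "presence":
        grid = grid.astype(float)
    meta = metadata.set_index("sample_id").reindex(grid.columns)
    dist = bray_curtis(grid)
    res = anosim(dist, meta[by], n_permutations=n_permutations, seed=seed)
    res.grouping = by
    res.matrix_type = matrix_type
    return res
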