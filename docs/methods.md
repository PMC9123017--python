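# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic data generator does and does not emulate,
and the design decisions taken where the problem left them open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
compute.

## Bin quality control

A candidate jumbo phage bin passes QC only if it clears five independent
checks (all are always computed; nothing short-circuits, so reports are
complete even for failing bins).

**Structure.** Total length ≥ 200,000 bp, at most 5 contigs, every contig
≥ 5,000 bp. These bounds define the object of study — a jumbo phage genome
assembled into a small number of substantial contigs — and reject fragment
collections that binning should not have produced.

**Marker conflicts.** Phages lack the universal single-copy markers used to
score bacterial MAG contamination, so the check inverts the logic: more than
one ribosomal protein, or more than one NCLDV (giant eukaryotic virus) marker
gene, or at least as many NCLDV as phage best hits, all indicate the bin is
not a clean phage. "Fewer NCLDV than phage hits" is strict. A missing
annotation table passes vacuously with a logged warning rather than failing
the bin on absent evidence.

**Self-overlap.** Two strains of one smaller phage can be co-binned by
similar composition; the symptom is a pair of contigs aligning at high
identity across most of the shorter contig. Defaults operationalising "high
similarity across the majority of the length": identity ≥ 0.95 over ≥ 50 %
of the shorter contig, both strands. Implementation: exact shared 21-mers
(2-bit packed into 42-bit integers, so the hash is collision-free) are
grouped into diagonal bands (tolerance 100 bp); each band's bounding
substrings are aligned with edlib and the best identity × span band is
reported. A full-alignment oracle on small fixtures checks the estimate in
tests. Quadratic DP over 100-kb contig pairs is thereby avoided.

**Coverage evenness.** The contamination signal is *co-abundance*: contigs of
a genuine genome rise and fall together across samples. The statistic is,
per sample with length-weighted mean bin coverage ≥ 1× (`min_mean_coverage`),
the length-weighted coefficient of variation (CV) of contig mean coverages;
the bin's score is the median over qualifying samples. CV is scale-free
(immune to per-sample sequencing depth) and the median resists sparse
samples. Single-contig bins score 0. A bin with no qualifying sample fails
conservatively as "insufficient coverage evidence". The pass threshold is
not a constant: it is the empirical 0.95 quantile of the same statistic over
≥ 20 reference genomes fragmented the same way bins are (the spread of the
statistic depends on the unknown coverage noise level, so it must be
measured in-sample). The quantile is exposed; 0.95 trades a ~5 % clean-bin
loss for high contaminant sensitivity.

**Viral decision rule.** Bins are accepted as viral when the mean per-contig
dsDNA-phage classifier score exceeds 0.9, or exceeds 0.5 together with
either a genome-quality call of medium or better (ordinal order
not-determined < low < medium < high < complete) or a consensus viral call
from a second classifier. Both score gates are strict (> 0.9, > 0.5). The
classifiers themselves are external; their score tables are inputs.

## Populations

Two genomes belong to one viral population when they share > 80 % of genes at
> 95 % average nucleotide identity; populations are connected components
(single linkage) of that threshold graph, with strict inequalities matching
the "> 95 / > 80" convention. Per genome pair, every gene of the
smaller-gene-count genome is matched to its best-identity alignment in the
other genome (best hit, not reciprocal best hit; the reciprocal variant
would only lower shared fractions). Identity is 1 − edit-distance /
max(gene lengths) from a Needleman–Wunsch alignment (edlib); matches below a
90 % identity floor are discarded so chance alignments cannot deflate the
average; the pair's ANI is the alignment-length-weighted mean identity of
the surviving matches, and the shared fraction divides by the smaller gene
count. Candidate gene pairs are prefiltered by sampled 15-mers on a fixed
16 bp coordinate grid — substitution-diverged homologs keep coordinates, so
their sampled k-mer sets intersect, while unrelated genes share essentially
nothing; at 10 % divergence an average gene still yields dozens of shared
grid k-mers, far above the 3-k-mer candidate cutoff. The population
representative is the longest member genome (ties: lexicographically
smallest id), maximising the read-mapping target.

## Gene-sharing network and Phage Genome Clusters

Genomes and gene families are nodes of a bipartite graph; an edge records at
least one family hit with E-value ≤ 0.001. Genomes with no qualifying hit
stay in the graph as degree-0 "unassigned" nodes. Communities come from the
Reichardt–Bornholdt spinglass model (q = 50 spin states, γ = 1, annealing
from T = 1.0 to 0.01 at cooling factor 0.99) via igraph, run `n_runs` times
(default 100; the pipeline default is 20 at its small problem size) with
derived seeds `seed + run_index`, recorded per run. Determinism per seed is
guaranteed by seeding igraph's RNG.

Spinglass is undefined across disconnected graphs, so each connected
component is clustered independently. Candidate partitions of a component —
every annealing run plus the trivial one-community partition — are scored by
their **contribution to the modularity of the full network** (within-edges/m
− (degree-sum/2m)² summed over the component's communities, with m the full
edge count). Scoring by per-component subgraph modularity would use the
wrong null model whenever other components hold part of the edge mass: for a
disconnected pair of complete bipartite blocks it is indifferent (Q = 0)
between keeping a block whole and shattering it, while the full-graph
objective correctly prefers one community per block. Ties go to the lowest
run index. Genome-side communities are relabelled A, B, C, … in decreasing
genome-count order.

Modularity itself is computed in-package (per-community sums over the plain
undirected graph, not a bipartite-specific null model) and is verified
against a brute-force double sum to 1e-12 in tests.

## Annotation profiles

Consensus per gene: among hits with E-value < 0.001, any Pfam hit wins
(best bit score; ties by lower E-value, then family id); otherwise the
higher-scoring of the best eggNOG and best VOG hits; no hits means
"hypothetical protein" / category "unknown". Per genome, category
proportions over all genes (unknowns included) sum to 1; cluster profiles
average them over member genomes. A family's per-cluster presence fraction
is the share of member genomes encoding it at least once; families with a
known function whose presence fractions have cross-cluster sample variance
(n − 1 denominator) > 0.2 are the discriminating genes. The cluster subset
entering the variance is configurable (e.g. to drop a singleton cluster).
A small curated family → category table ships as an editable TSV resource
illustrating the format; synthetic worlds generate their own.

## Ecology

Detection is covered fraction ≥ 0.20, inclusive ("min. 20 %"). RPKM is
reads / (genome kb × sample megareads), with the fixed post-subsampling
depth (20 million reads/sample) as the denominator (configurable to
mapped-reads mode). Bray–Curtis distances are computed in-package because an
all-zero sample pair must yield distance 0 with a warning rather than NaN;
scipy cross-checks the non-degenerate case in tests. ANOSIM uses the
standard Clarke statistic R = (r̄_between − r̄_within)/(M/2) over the ranked
M = n(n−1)/2 dissimilarities — rank-based, hence invariant to monotone
transformations of the distances — with a seeded permutation p-value that
includes the observed labelling ((1 + hits)/(1 + permutations)), so p is
never 0 and the test is exactly valid; its type-I error at α = 0.05 is
verified at 0.05 ± 0.02 over 1000 null simulations. The Wilcoxon rank-sum
test enumerates all rank splits exactly when n₁ + n₂ ≤ 12 (ties handled;
identical groups give p = 1) and otherwise uses the tie-corrected normal
approximation. Size-fraction classes: a sample is `below_022` when its
fraction's upper bound is ≤ 0.22 µm, `above_022` when the lower bound is
≥ 0.22 µm. Exclusivity labels (`only_above_022`, `only_below_022`, `both`)
are reported among *detected* populations only. Co-collected subsets pair
samples from station–depth groups holding both fraction classes (or all
three depth layers, per mode).

## Host inference

Spacer matching is an ungapped full-length sliding comparison on both
strands, reporting every window with length > 24 bp and ≤ 1 mismatch;
ambiguous bases always count as mismatches (N never matches N). The
implementation seeds candidates by the pigeonhole principle — with at most
one mismatch, one spacer half occurs exactly — and verifies each candidate
window; tests prove equality with the brute-force every-window scan. tRNA
matching requires equal length and ≤ 1 mismatch (the stricter reading of
"100 % ID, ≤ 1 mismatch"); host tRNAs near-identical across phyla are
removed as promiscuous before voting, and a phage tRNA matching hosts of
more than one phylum likewise votes for nothing. The gene-content vote
assigns the top phylum when its hit count is ≥ 3× the runner-up (inclusive)
and at least 1. The consensus ignores methods that predict nothing; if every
predicting method names the same phylum it is assigned (a single predicting
method suffices), any disagreement yields none.

## Synthetic worlds

The generator emulates the complete input surface with planted truth:

* **Genomes.** Uniform ACGT sequences. Each cluster has one ancestor; each
  population ancestor is the cluster ancestor mutated at
  `between_divergence/2` per base, and each genome copy is its population
  ancestor mutated at `within_divergence/2`, so pairwise divergence is
  ≈ 2 % within and ≈ 10 % between populations (defaults). Substitutions
  only — no indels — so homologous genes keep coordinates. Gene lengths are
  drawn uniform [300, 3000] bp and rescaled to a 90 % coding fraction
  (guaranteeing the ≥ 80 % coverage contract for any genome size / gene
  count combination); defaults: 200–500 kb genomes, 250 genes. Gene
  families come from cluster-specific pools (default 60 families per
  cluster, so the gene-sharing network stays at a few hundred nodes while
  families recur across genomes as real orthologous groups do) with a 5 %
  cross-pool noise rate providing weak inter-cluster edges.
* **Bins.** Each genome is cut into 1–5 contigs of ≥ 5 kb (breakpoints by
  multinomial split). A contaminated bin carries exactly one extra contig,
  10–60 kb cut from a different genome — typical binner contig sizes; a
  5 kb splice would carry almost no co-abundance signal and is below what
  any coverage-based filter can see.
* **Coverage.** Per bin and sample, a latent lognormal abundance (µ = 2,
  σ = 1 on the log scale); contig coverages multiply it by lognormal noise
  with unit mean and CV `noise_cv` (default 0.1). The foreign contig of a
  contaminated bin follows its own independent latent profile — exactly the
  alternative hypothesis of the evenness filter.
* **Mapping and metadata.** Samples are stations × depth layers (SRF, DCM,
  MES) × size fractions; stations cycle through the three ocean biomes.
  Expected read counts are lognormal per population and station (median
  1000 reads), multiplied by per-cluster depth and fraction-class effect
  factors (default: one cluster ×10 in SRF, ×0.2 in MES — the planted
  biogeography), with Poisson counts and a Lander–Waterman covered fraction
  1 − exp(−reads × 100 bp / genome length). The even subsample depth
  (20 million reads) is recorded per sample.
* **Hosts.** Host–phage links are planted per gene-sharing cluster (near
  identical genomes cross-match each other's spacers, so per-genome truth
  would be inconsistent): every member phage donates a 32 bp spacer copied
  into its host with 0–1 mismatches, shares a 72 bp tRNA with it (≤ 1
  mismatch) and gets a ≥ 3× gene-hit count for the host phylum. Decoy
  spacers/tRNAs are independent random sequences (a chance ≤ 1-mismatch
  match of a random 25+ bp spacer is astronomically unlikely), and one
  cross-phylum identical tRNA pair exercises the promiscuity filter.

Everything regenerates bit-identically from (parameters, seed).

What the generator does **not** emulate: read-level data (no FASTQ, no
sequencing error or mapping ambiguity), assembly artefacts, indels or
rearrangements, strain microdiversity within populations, compositional
biases, or realistic taxon abundance distributions. Tests passing on these
worlds therefore demonstrate the correctness and calibration of the
*decision rules and statistics* under their stated models — not robustness
to every failure mode of real ocean metagenomes. The lognormal coverage
noise in particular is a stand-in for an unknown real-data noise process.

## Problem sizes and defaults

Module-level defaults follow the protocol constants (0.95 calibration
quantile, 50 spins, 100 spinglass restarts, 9999 ANOSIM permutations,
20-million-read depth). The end-to-end pipeline and the acceptance script
run at deliberately compact problem sizes chosen as this package's study
conditions: 4 clusters × 6 genomes (populations of 2), 250 genes/genome,
50 coverage samples, 20 stations × 3 depths × 2 fractions, 100 fragmented
references for calibration, 200 bins at 50 % contamination for the filter
operating point, 10 seeds × 10 restarts for planted-partition recovery, and
1000 null simulations at 199 permutations for ANOSIM calibration (at which
granularity P(p ≤ 0.05) is exactly 0.05 under the null). These sizes give
stable statistics while keeping a full run in minutes on one CPU.

## Known limitations

* The evenness metric and its 0.95 quantile are a declared operationalisation
  of "even read coverage below an empirically derived threshold"; other
  dispersion statistics (e.g. max pairwise log-ratio) would be drop-in
  replacements via the same calibration.
* Gene-ANI uses best-hit (not reciprocal-best-hit) matching and a 90 %
  per-gene identity floor; both are exposed as parameters.
* Spinglass restarts explore stochastically; on pathological graphs the
  best-of-n partition may miss the global optimum (tests bound this on small
  graphs: best-of-100 attains the exhaustive maximum in ≥ 95 % of cases).
* The co-abundance filter cannot detect contaminants whose abundance happens
  to track the host bin, nor very short foreign contigs.
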