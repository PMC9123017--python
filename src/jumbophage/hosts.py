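"""Host-phylum prediction for phages from three evidence streams.

CRISPR spacers from candidate hosts are scanned against the phage sequence
(full-length, ungapped, either strand, >24 bp with at most one mismatch);
phage tRNAs vote for the phylum of hosts carrying a near-identical tRNA,
after removing promiscuous tRNAs shared across phyla; taxon-labelled gene
hits vote for a phylum when the top phylum has at least three times the hits
of the runner-up. A consensus phylum is assigned only when every method that
makes a prediction agrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import revcomp

MIN_SPACER_LEN = 25  # ">24 bp"
MAX_SPACER_MISMATCHES = 1
MAX_TRNA_MISMATCHES = 1
GENE_VOTE_FACTOR = 3.0


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    host_id: str
    phylum: str
    phage_id: str
    start: int  # 0-based, half-open on the forward phage strand
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 24:
            raise ValueError("spacer matches must span > 24 bp")
        if self.mismatches > MAX_SPACER_MISMATCHES:
            raise ValueError("too many mismatches for a reported match")


@dataclass
class HostEvidence:
    phage_id: str
    crispr_phylum: str | None = None
    trna_phylum: str | None = None
    gene_vote_phylum: str | None = None
    spacer_matches: list[SpacerMatch] = field(default_factory=list)
    trna_votes: dict[str, str] = field(default_factory=dict)  # phage tRNA id -> phylum

    @property
    def consensus(self) -> str | None:
        return consensus_host(self)


_ACGT = frozenset("ACGT")


def _window_mismatches(phage: str, start: int, spacer: str, limit: int) -> int:
    """Mismatches of the spacer against phage[start:start+len], early exit.

    Ambiguous (non-ACGT) bases on either side always count as mismatches,
    so e.g. N never matches N.
    """
    mm = 0
    for qc, pc in zip(spacer, phage[start : start + len(spacer)]):
        if qc != pc or qc not in _ACGT:
            mm += 1
            if mm > limit:
                break
    return mm


def _candidate_starts(phage: str, spacer: str) -> set[int]:
    """Window starts that could hold a <=1-mismatch occurrence.

    Pigeonhole seeding: with at most one mismatch, one of the two spacer
    halves occurs exactly; every exact occurrence of either half nominates a
    window start.
    """
    L = len(spacer)
    half = L // 2
    starts: set[int] = set()
    for seed, offset in ((spacer[:half], 0), (spacer[half:], half)):
        pos = phage.find(seed)
        while pos != -1:
            s = pos - offset
            if 0 <= s <= len(phage) - L:
                starts.add(s)
            pos = phage.find(seed, pos + 1)
    return starts


def find_spacer_matches(
    spacers: list[tuple[str, str, str, str]],
    phage_id: str,
    phage_seq: str,
    min_len: int = MIN_SPACER_LEN,
    max_mismatches: int = MAX_SPACER_MISMATCHES,
) -> list[SpacerMatch]:
    """All full-length spacer occurrences in the phage on either strand.

    ``spacers`` rows are (spacer_id, host_id, phylum, sequence). Spacers
    shorter than ``min_len`` are rejected at intake. Matching is an ungapped
    sliding comparison; ambiguous (non-ACGT) bases count as mismatches.
    Reported coordinates always refer to the forward phage strand.
    """
    phage_fwd = phage_seq.upper()
    matches: list[SpacerMatch] = []
    for spacer_id, host_id, phylum, seq in spacers:
        if len(seq) < min_len:
            continue
        for strand, s in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
            for pos in sorted(_candidate_starts(phage_fwd, s)):
                mm = _window_mismatches(phage_fwd, pos, s, max_mismatches)
                if mm <= max_mismatches:
                    matches.append(
                        SpacerMatch(
                            spacer_id=spacer_id,
                            host_id=host_id,
                            phylum=phylum,
                            phage_id=phage_id,
                            start=pos,
                            end=pos + len(s),
                            strand=strand,
                            mismatches=mm,
                        )
                    )
    return matches


def crispr_phylum(matches: list[SpacerMatch]) -> str | None:
    """Unique phylum supported by spacer matches; conflicts give None."""
    phyla = {m.phylum for m in matches}
    if len(phyla) == 1:
        return phyla.pop()
    return None


def _hamming_le(a: str, b: str, max_mm: int) -> bool:
    """Full-length comparison: equal length and at most max_mm mismatches."""
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def promiscuous_host_trnas(
    host_trnas: list[tuple[str, str, str]],
    max_mismatches: int = MAX_TRNA_MISMATCHES,
) -> set[str]:
    """Host tRNAs near-identical to a tRNA of a host in another phylum.

    ``host_trnas`` rows are (trna_id, phylum, sequence). Such tRNAs carry no
    host signal and are removed before voting.
    """
    flagged: set[str] = set()
    for i, (id_a, phy_a, seq_a) in enumerate(host_trnas):
        for id_b, phy_b, seq_b in host_trnas[i + 1 :]:
            if phy_a != phy_b and _hamming_le(seq_a, seq_b, max_mismatches):
                flagged.add(id_a)
                flagged.add(id_b)
    return flagged


def match_trnas(
    phage_trnas: list[tuple[str, str]],
    host_trnas: list[tuple[str, str, str]],
    max_mismatches: int = MAX_TRNA_MISMATCHES,
) -> tuple[str | None, dict[str, str]]:
    """tRNA-based phylum vote.

    ``phage_trnas``: (trna_id, sequence); ``host_trnas``: (trna_id, phylum,
    sequence). A phage tRNA votes for a phylum when it matches a
    non-promiscuous host tRNA full-length with <= 1 mismatch; a phage tRNA
    matching hosts of more than one phylum is itself promiscuous and votes
    for nothing. Returns (phylum or None, per-tRNA votes).
    """
    flagged = promiscuous_host_trnas(host_trnas, max_mismatches)
    usable = [t for t in host_trnas if t[0] not in flagged]
    votes: dict[str, str] = {}
    for trna_id, seq in phage_trnas:
        phyla = {
            phy for hid, phy, hseq in usable if _hamming_le(seq, hseq, max_mismatches)
        }
        if len(phyla) == 1:
            votes[trna_id] = phyla.pop()
        # zero matches: no vote; >1 phylum: promiscuous, no vote
    distinct = set(votes.values())
    return (distinct.pop() if len(distinct) == 1 else None), votes


def gene_content_vote(
    phylum_counts: dict[str, int] | pd.Series,
    factor: float = GENE_VOTE_FACTOR,
) -> str | None:
    """Taxon-labelled gene-hit vote: top phylum needs factor x the runner-up."""
    counts = pd.Series(phylum_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative hit counts")
    counts = counts.sort_values(ascending=False, kind="stable")
    if len(counts) == 0 or counts.iloc[0] < 1:
        return None
    top = counts.iloc[0]
    second = counts.iloc[1] if len(counts) > 1 else 0.0
    if top >= factor * second:
        # deterministic under ties in the top count: a tie means top == second,
        # which fails the factor test for factor > 1 anyway
        return str(counts.index[0])
    return None


def consensus_host(evidence: HostEvidence) -> str | None:
    """Strict cross-method consensus: all predicting methods must agree."""
    preds = [
        p
        for p in (evidence.crispr_phylum, evidence.trna_phylum, evidence.gene_vote_phylum)
        if p is not None
    ]
    if not preds:
        return None
    return preds[0] if len(set(preds)) == 1 else None


def predict_hosts(
    phages: dict[str, str],
    spacers: list[tuple[str, str, str, str]],
    phage_trnas: dict[str, list[tuple[str, str]]],
    host_trnas: list[tuple[str, str, str]],
    gene_hit_counts: dict[str, dict[str, int]],
) -> list[HostEvidence]:
    """Run all three methods plus consensus for every phage."""
    out = []
    for phage_id, seq in sorted(phages.items()):
        matches = find_spacer_matches(spacers, phage_id, seq)
        trna_phy, votes = match_trnas(phage_trnas.get(phage_id, []), host_trnas)
        gene_phy = gene_content_vote(gene_hit_counts.get(phage_id, {}))
        out.append(
            HostEvidence(
                phage_id=phage_id,
                crispr_phylum=crispr_phylum(matches),
                trna_phylum=trna_phy,
                gene_vote_phylum=gene_phy,
                spacer_matches=matches,
                trna_votes=votes,
            )
        )
    return out


def evidence_to_frame(evidence: list[HostEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phage_id": e.phage_id,
                "crispr_phylum": e.crispr_phylum or "none",
                "trna_phylum": e.trna_phylum or "none",
                "gene_vote_phylum": e.gene_vote_phylum or "none",
                "consensus": e.consensus or "none",
                "n_spacer_matches": len(e.spacer_matches),
            }
            for e in evidence
        ]
    )
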