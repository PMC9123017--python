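"""Shared in-memory containers for the jumbo-phage recovery pipeline.

Coordinates are 0-based half-open internally; exported TSVs state their
convention in the header. Sequences are plain upper-case ACGT strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Gene:
    """A gene interval on a contig (0-based, half-open)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Contig:
    contig_id: str
    length: int
    sequence: str | None = None
    source_genome: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id} has non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.contig_id}: sequence/length mismatch")


@dataclass
class GenomeBin:
    """A candidate jumbo phage genome: a set of contigs plus gene coordinates."""

    bin_id: str
    contigs: list[Contig]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"bin {self.bin_id}: duplicate contig ids")
        by_id = {c.contig_id: c for c in self.contigs}
        for g in self.genes:
            c = by_id.get(g.contig_id)
            if c is None:
                raise ValueError(f"bin {self.bin_id}: gene {g.gene_id} on unknown contig")
            if g.end > c.length:
                raise ValueError(f"bin {self.bin_id}: gene {g.gene_id} exceeds contig")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def contig_lengths(self) -> dict[str, int]:
        return {c.contig_id: c.length for c in self.contigs}

    def gene_sequences(self) -> dict[str, str]:
        """Extract nucleotide gene sequences (reverse-complemented on '-')."""
        by_id = {c.contig_id: c for c in self.contigs}
        out: dict[str, str] = {}
        for g in self.genes:
            seq = by_id[g.contig_id].sequence
            if seq is None:
                raise ValueError(f"bin {self.bin_id}: contig {g.contig_id} has no sequence")
            sub = seq[g.start : g.end]
            out[g.gene_id] = revcomp(sub) if g.strand == "-" else sub
        return out


@dataclass
class Genome:
    """A complete (unfragmented) phage genome with gene coordinates."""

    genome_id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_sequences(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g in self.genes:
            sub = self.sequence[g.start : g.end]
            out[g.gene_id] = revcomp(sub) if g.strand == "-" else sub
        return out


class CoverageMatrix:
    """Per-contig mean read coverage across samples.

    Wraps a DataFrame (rows: contig_id, columns: sample_id) together with
    contig lengths and the contig -> bin membership map.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        lengths: dict[str, int],
        bin_of: dict[str, str],
    ) -> None:
        missing = set(values.index) - set(lengths)
        if missing:
            raise ValueError(f"contigs without lengths: {sorted(missing)[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative coverage values")
        self.values = values
        self.lengths = dict(lengths)
        self.bin_of = dict(bin_of)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def bin_submatrix(self, bin_id: str) -> pd.DataFrame:
        contigs = [c for c in self.values.index if self.bin_of.get(c) == bin_id]
        return self.values.loc[contigs]

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="contig_id").melt(
            id_vars="contig_id", var_name="sample_id", value_name="mean_coverage"
        )
        return long


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 for vectorised comparison."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
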