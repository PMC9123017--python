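"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; tables are TSV via pandas. Gene coordinate
tables are 1-based inclusive on disk (stated in the header comment) and
0-based half-open in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import Contig, CoverageMatrix, Gene, Genome, GenomeBin


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genes_tsv(genomes: list[Genome] | list[GenomeBin], path: str | Path) -> None:
    rows = []
    for g in genomes:
        parent = g.genome_id if isinstance(g, Genome) else g.bin_id
        for gene in g.genes:
            rows.append(
                {"gene_id": gene.gene_id, "parent_id": parent, "contig_id": gene.contig_id,
                 "start": gene.start + 1, "end": gene.end, "strand": gene.strand}
            )
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based, inclusive\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame["start"] = frame["start"] - 1  # to 0-based half-open
    return frame


def write_coverage_tsv(coverage: CoverageMatrix, path: str | Path) -> None:
    coverage.to_long().to_csv(path, sep="\t", index=False)


def read_coverage_tsv(
    path: str | Path, contig_map: pd.DataFrame
) -> CoverageMatrix:
    """Coverage from a long TSV (contig_id, sample_id, mean_coverage).

    ``contig_map`` supplies bin_id, contig_id and length per contig.
    """
    long = pd.read_csv(path, sep="\t")
    values = long.pivot_table(
        index="contig_id", columns="sample_id", values="mean_coverage", fill_value=0.0
    )
    lengths = dict(zip(contig_map["contig_id"], contig_map["length"]))
    bin_of = dict(zip(contig_map["contig_id"], contig_map["bin_id"]))
    return CoverageMatrix(values, lengths, bin_of)


def write_bins(bins: list[GenomeBin], outdir: str | Path) -> None:
    """One FASTA per bin plus a bin -> contig map TSV and a gene table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bins:
        seqs = {
            c.contig_id: c.sequence for c in b.contigs if c.sequence is not None
        }
        if seqs:
            write_fasta(seqs, outdir / f"{b.bin_id}.fasta")
        for c in b.contigs:
            rows.append({"bin_id": b.bin_id, "contig_id": c.contig_id, "length": c.length})
    pd.DataFrame(rows).to_csv(outdir / "contig_map.tsv", sep="\t", index=False)
    write_genes_tsv(bins, outdir / "genes.tsv")


def read_bins(bindir: str | Path) -> list[GenomeBin]:
    """Bins from a directory written by :func:`write_bins`."""
    bindir = Path(bindir)
    contig_map = pd.read_csv(bindir / "contig_map.tsv", sep="\t")
    genes = read_genes_tsv(bindir / "genes.tsv")
    bins = []
    for bin_id, sub in contig_map.groupby("bin_id", sort=True):
        fasta = bindir / f"{bin_id}.fasta"
        seqs = read_fasta(fasta) if fasta.exists() else {}
        contigs = [
            Contig(r.contig_id, int(r.length), seqs.get(r.contig_id))
            for r in sub.itertuples()
        ]
        gsub = genes[genes["parent_id"] == bin_id]
        gene_objs = [
            Gene(r.gene_id, r.contig_id, int(r.start), int(r.end), r.strand)
            for r in gsub.itertuples()
        ]
        bins.append(GenomeBin(str(bin_id), contigs, gene_objs))
    return bins


def write_spacers_fasta(
    spacers: list[tuple[str, str, str, str]], path: str | Path
) -> None:
    """Spacer FASTA; the header carries spacer_id|host_id|phylum."""
    write_fasta({f"{sid}|{hid}|{phy}": seq for sid, hid, phy, seq in spacers}, path)


def read_spacers_fasta(path: str | Path) -> list[tuple[str, str, str, str]]:
    out = []
    for name, seq in read_fasta(path).items():
        sid, hid, phy = name.split("|")
        out.append((sid, hid, phy, seq))
    return out
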