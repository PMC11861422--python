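"""File-format round-trips shared by the pipeline stages.

Conventions: FASTA wrapped at 80 columns; BED is 3+ column, 0-based
half-open, with chromosome names in the ``genomeid|contigindex`` dialect;
FASTQ is Phred+33 with a constant quality; Newick carries branch lengths
and internal-node support labels.  Genome FASTA files name contigs
``genomeid|contigindex`` so multi-contig genomes round-trip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio.tree import TreeNode

from . import __version__
from .errors import DataError
from .genomes import GenomeRecord
from .mapping import SAM_NAME_SEP, ReferenceSet, sam_reference_name
from .synthetic import Read, ReadSet

TSV_SCHEMA_HEADER = f"#aquadetect={__version__}"


# -- FASTA / FASTQ -----------------------------------------------------------

def write_genome_fasta(genome: GenomeRecord, path: str | Path, wrap: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=sam_reference_name(genome.genome_id, ci), description="")
        for ci, seq in enumerate(genome.contigs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read one genome; contig ids may be ``genomeid|i`` or arbitrary names."""
    contigs: list[str] = []
    gid = genome_id
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if SAM_NAME_SEP in name:
            prefix = name.rsplit(SAM_NAME_SEP, 1)[0]
            if gid is None:
                gid = prefix
        elif gid is None:
            gid = name
        contigs.append(str(rec.seq).upper())
    if not contigs:
        raise DataError(f"no FASTA records in {path}")
    return GenomeRecord(genome_id=gid, contigs=contigs)


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta_sequences(path: str | Path, records: list[tuple[str, str]], wrap: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.FastaIO.FastaWriter(fh, wrap=wrap).write_file(recs)


def write_reads(reads: ReadSet, path: str | Path, fmt: str = "fasta", quality: int = 40) -> None:
    """Write reads as FASTA or FASTQ (constant Phred+33 quality)."""
    recs = []
    for r in reads.reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        recs.append(rec)
    SeqIO.write(recs, str(path), fmt)


def read_reads(path: str | Path, fmt: str | None = None) -> ReadSet:
    """Read FASTA/FASTQ reads, recovering truth labels from id suffixes."""
    from .synthetic import parse_truth_read_id

    p = Path(path)
    if fmt is None:
        fmt = "fastq" if p.suffix.lower() in {".fq", ".fastq"} else "fasta"
    reads = []
    length = 0
    for rec in SeqIO.parse(str(p), fmt):
        gid, contig, start, strand = parse_truth_read_id(rec.id)
        seq = str(rec.seq).upper()
        length = max(length, len(seq))
        reads.append(Read(rec.id, seq, gid, contig, start, strand))
    if not reads:
        raise DataError(f"no reads in {path}")
    return ReadSet(reads=reads, read_length=length)


# -- BED ---------------------------------------------------------------------

def write_bed(genome: GenomeRecord, path: str | Path) -> None:
    """Write masked intervals as 3-column BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for ci, s, e in genome.masked_intervals:
            fh.write(f"{sam_reference_name(genome.genome_id, ci)}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, int]]:
    """Parse BED into (genome_id, contig_index, start, end) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom = parts[0]
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if SAM_NAME_SEP in chrom:
                gid, ci = chrom.rsplit(SAM_NAME_SEP, 1)
                out.append((gid, int(ci), s, e))
            else:
                out.append((chrom, 0, s, e))
    return out


# -- SAM ---------------------------------------------------------------------

def write_sam(
    alignments,
    ref: ReferenceSet,
    path: str | Path,
) -> None:
    """Export internal alignments as minimal SAM (ungapped, forward CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for gi, g in enumerate(ref.genomes):
            for ci, c in enumerate(g.contigs):
                fh.write(f"@SQ\tSN:{sam_reference_name(g.genome_id, ci)}\tLN:{len(c)}\n")
        for a in alignments:
            nm = a.aligned_length - a.matches
            fh.write(
                "\t".join(
                    [
                        a.read_id, "0",
                        sam_reference_name(a.genome_id, a.contig_index),
                        str(a.start + 1), "255", f"{a.aligned_length}M",
                        "*", "0", "0", "*", "*", f"NM:i:{nm}",
                    ]
                )
                + "\n"
            )


# -- Newick ------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# -- TSV ---------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with the versioned schema header line."""
    with open(path, "w") as fh:
        fh.write(TSV_SCHEMA_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
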