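"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are handled 1-based and inclusive internally
(GFF3 convention); any half-open arithmetic is confined to the writers.
Sequences are uppercased on read and ``U`` is mapped to ``T`` in
nucleotide records so that downstream matching is uniform.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__version__ = "0.1.0"

logger = logging.getLogger("hspscan")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AMINO_ACIDS + "X*")
NT_ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A single named sequence with a declared alphabet.

    Parameters
    ----------
    id:
        Record identifier (FASTA header up to first whitespace).
    sequence:
        Residue string, uppercase.
    alphabet:
        ``"aa"`` for amino acids or ``"nt"`` for nucleotides.
    """

    id: str
    sequence: str
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        if self.alphabet not in ("aa", "nt"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str, alphabet: str, record_id: str, allow_empty: bool) -> str:
    seq = seq.upper()
    if alphabet == "nt":
        seq = seq.replace("U", "T")
    if not seq and not allow_empty:
        raise FormatError(f"record {record_id!r} is empty")
    legal = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    for pos, ch in enumerate(seq):
        if ch not in legal:
            raise FormatError(
                f"record {record_id!r}: illegal symbol {ch!r} at position {pos + 1}"
            )
    return seq


def read_fasta(path: str | Path, alphabet: str = "aa",
               allow_empty: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Duplicate ids and symbols outside the declared alphabet are errors;
    lowercase residues are uppercased and ``U`` becomes ``T`` for
    nucleotide records.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    # fasta-pearson tolerates ';' comment lines such as our version header
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), alphabet, rec.id, allow_empty)
        records.append(SequenceRecord(rec.id, seq, alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as 60-column-wrapped FASTA.

    A ``;``-prefixed comment line with the tool version is emitted first;
    standard parsers skip text before the first ``>``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"; hspscan {__version__}\n")
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
            if not rec.sequence:
                fh.write("\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string (involution)."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene models / GFF3
# ---------------------------------------------------------------------------

_SUBGENOME_RE = re.compile(r"^(?:chr)?\d+([A-Za-z])$")


def parse_subgenome(chromosome: str) -> str | None:
    """Sub-genome label from a chromosome name: ``"7D"`` -> ``"D"``.

    Returns None for names without a trailing letter (e.g. ``"Un"``).
    """
    m = _SUBGENOME_RE.match(chromosome)
    return m.group(1).upper() if m else None


@dataclass
class GeneModel:
    """One annotated gene: coordinates, strand and exon structure.

    ``exons`` is the exon union of the gene's longest transcript, stored
    ascending by start even on the minus strand. Coordinates are 1-based
    inclusive with ``start <= end``.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    subgenome: str | None = None
    n_isoforms: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if e < s:
                raise FormatError(f"gene {self.gene_id}: exon end {e} < start {s}")
            if s <= prev_end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
            if s < self.start or e > self.end:
                raise FormatError(f"gene {self.gene_id}: exon outside gene span")
            prev_end = e
        if self.subgenome is None:
            self.subgenome = parse_subgenome(self.chromosome)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def unplaced(self) -> bool:
        return self.chromosome == "Un"


def chromosome_sort_key(chromosome: str) -> tuple:
    """Natural chromosome order 1A, 1B, 1D, ..., 7D; ``Un`` last."""
    m = re.match(r"^(?:chr)?(\d+)([A-Za-z]?)$", chromosome)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, chromosome)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (gene + mRNA + exon features) from GFF3.

    Exons are attributed to genes through their mRNA parent; each gene's
    exon set is the exon union of its longest transcript. Exons without a
    resolvable parent gene raise :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            # longest annotated transcript represents the gene
            best = max(mrnas, key=lambda m: (m.end - m.start + 1, m.id))
            exons = [(e.start, e.end)
                     for e in db.children(best, featuretype="exon")]
            n_iso = len(mrnas)
        else:
            exons = [(e.start, e.end)
                     for e in db.children(gene, featuretype="exon")]
            n_iso = 1
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(GeneModel(
            gene_id=gene.id, chromosome=gene.seqid, start=gene.start,
            end=gene.end, strand=gene.strand, exons=sorted(exons),
            n_isoforms=n_iso))
    # orphan exon check: every exon feature must trace to a gene
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon))
        if not any(p.featuretype in ("gene", "mRNA") for p in parents):
            raise FormatError(f"exon {exon.id} has no parent gene")
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# hspscan {__version__}\n")
        for g in models:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chromosome}\thspscan\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(f"{g.chromosome}\thspscan\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chromosome}\thspscan\texon\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n")
                fh.write(f"{g.chromosome}\thspscan\tCDS\t{s}\t{e}\t.\t"
                         f"{g.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n")


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def extract_promoter(genome: dict[str, str] | Sequence[SequenceRecord],
                     gene: GeneModel, length: int = 1500) -> SequenceRecord:
    """Upstream promoter of a gene, on the gene's coding strand.

    Plus strand: bases ``[start-length, start-1]``; minus strand: reverse
    complement of ``[end+1, end+length]``. Clipped at chromosome ends, so
    the result may be shorter than ``length``; a zero-length promoter is
    returned (and logged), not raised.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r.sequence for r in genome}
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in genome")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        lo = max(1, gene.start - length)
        seq = chrom[lo - 1:gene.start - 1]
    else:
        hi = min(len(chrom), gene.end + length)
        seq = reverse_complement(chrom[gene.end:hi])
    if not seq:
        logger.warning("zero-length promoter for gene %s", gene.gene_id)
    return SequenceRecord(f"{gene.gene_id}_promoter", seq, "nt")


# ---------------------------------------------------------------------------
# TPM matrices
# ---------------------------------------------------------------------------

def read_tpm_matrix(path: str | Path):
    """Read a genes x samples TPM table (TSV, first column = gene id).

    Returns an :class:`hspscan.expression_profiling.ExpressionMatrix`.
    Negative values, missing cells and duplicate gene ids are errors.
    """
    from .expression_profiling import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"duplicate gene ids in TPM matrix: {dups}")
    if df.isna().any().any():
        bad = [(str(idx), str(col))
               for idx in df.index for col in df.columns
               if pd.isna(df.at[idx, col])]
        raise FormatError(f"missing TPM value(s) at {bad[:5]}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise FormatError("negative TPM values present")
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_tpm_matrix(matrix, path: str | Path, float_format: str = "%.6g") -> None:
    """Write an ExpressionMatrix as TSV with a version comment header."""
    with Path(path).open("w") as fh:
        fh.write(f"# hspscan {__version__}\n")
        matrix.to_frame().to_csv(fh, sep="\t", float_format=float_format)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a DataFrame as TSV with a version comment header."""
    with Path(path).open("w") as fh:
        fh.write(f"# hspscan {__version__}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
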