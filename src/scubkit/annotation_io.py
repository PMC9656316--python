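"""Genome FASTA + GFF3 ingestion and codon-record construction.

One transcript is retained per protein-coding gene (the first mRNA child in
GFF3 document order), its CDS features are stitched in transcript
orientation, filtered by the standard CDS sanity rules, and each codon is
assigned to a coding exon with the phase convention: a codon split between
its 1st and 2nd nucleotide belongs to the downstream exon, one split between
its 2nd and 3rd nucleotide to the upstream exon.  Equivalently, a codon
belongs to the exon containing its middle nucleotide.
"""

from __future__ import annotations

import bisect
import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .codon_stats import GENETIC_CODE, STOP_SYMBOL, GeneticCode

logger = logging.getLogger(__name__)

FILTER_REASONS = ("not_multiple_of_three", "contains_N", "bad_start", "bad_stop", "none")


@dataclass(frozen=True)
class GenomeSource:
    """One species' genome: a FASTA file and its GFF3 annotation."""

    species_label: str
    fasta_path: Path
    gff3_path: Path


@dataclass(frozen=True)
class TranscriptModel:
    """A gene's chosen transcript: ordered coding exons plus the spliced CDS.

    ``coding_exons`` are genomic intervals (0-based half-open) in 5'->3'
    transcript order; for minus-strand genes that is descending genomic
    coordinate order.  ``cds_sequence`` is in transcript orientation and
    includes the stop codon.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    coding_exons: tuple[tuple[int, int], ...]
    cds_sequence: str

    @property
    def exon_count(self) -> int:
        return len(self.coding_exons)

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        span = sum(e - s for s, e in self.coding_exons)
        if span != len(self.cds_sequence):
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} != exon span {span}"
            )


@dataclass(frozen=True)
class FilterReport:
    gene_id: str
    transcript_id: str
    outcome: str  # retained | rejected
    reason: str   # one of FILTER_REASONS; "none" iff retained


@dataclass(frozen=True)
class CodonRecord:
    """One codon occurrence with its exon assignment and neighbour context.

    ``next_first_base`` is the first base of the following codon in CDS
    orientation; the stop codon donates context to the final sense codon and
    is itself the only record with ``next_first_base`` None.
    """

    codon: str
    amino_acid: str
    ordinal: int         # 1-based codon position within the CDS
    exon_ordinal: int    # 1-based coding-exon index owning this codon
    exon_count: int
    intron_count: int
    next_first_base: Optional[str]
    gene_id: str
    chromosome: str

    @property
    def is_stop(self) -> bool:
        return self.amino_acid == STOP_SYMBOL

    @property
    def is_start(self) -> bool:
        return self.ordinal == 1


def _open_text(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: Path) -> dict[str, str]:
    """Load a (possibly gzipped) FASTA into upper-cased strings.

    Soft-masked lowercase is folded to normal bases.
    """
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key] = value
    return attrs


@dataclass
class _Feature:
    seqid: str
    ftype: str
    start: int  # 0-based half-open after conversion
    end: int
    strand: str
    attrs: dict[str, str]
    line_no: int


def _parse_gff3(path: Path) -> Iterator[_Feature]:
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{line_no}: malformed GFF3 line ({len(fields)} fields)")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}:{line_no}: invalid interval {start}..{end}")
            # GFF3 is 1-based inclusive; internal convention is 0-based half-open.
            yield _Feature(seqid, ftype, start_i - 1, end_i, strand, _parse_attributes(attrs), line_no)


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def load_transcripts(source: GenomeSource) -> list[TranscriptModel]:
    """One TranscriptModel per gene, using the first mRNA in document order.

    Genes with no mRNA or whose chosen transcript carries no CDS features
    are skipped with a warning.  CDS features referencing a sequence region
    absent from the FASTA raise a hard error.
    """
    genome = read_fasta(source.fasta_path)

    gene_order: list[str] = []
    first_mrna_of_gene: dict[str, str] = {}
    mrna_meta: dict[str, _Feature] = {}
    cds_of_mrna: dict[str, list[_Feature]] = {}

    for feat in _parse_gff3(source.gff3_path):
        if feat.ftype == "gene":
            gene_id = feat.attrs.get("ID", "")
            if gene_id:
                gene_order.append(gene_id)
        elif feat.ftype == "mRNA":
            mrna_id = feat.attrs.get("ID", "")
            parent = feat.attrs.get("Parent", "")
            if parent not in first_mrna_of_gene:
                first_mrna_of_gene[parent] = mrna_id
            mrna_meta[mrna_id] = feat
        elif feat.ftype == "CDS":
            parent = feat.attrs.get("Parent", "")
            cds_of_mrna.setdefault(parent, []).append(feat)

    transcripts: list[TranscriptModel] = []
    for gene_id in gene_order:
        mrna_id = first_mrna_of_gene.get(gene_id)
        if mrna_id is None:
            logger.warning("gene %s has no mRNA child; skipped", gene_id)
            continue
        pieces = cds_of_mrna.get(mrna_id)
        if not pieces:
            logger.warning("gene %s transcript %s has no CDS features; skipped", gene_id, mrna_id)
            continue
        strand = pieces[0].strand
        chrom = pieces[0].seqid
        if chrom not in genome:
            raise ValueError(
                f"CDS of {mrna_id} references sequence region {chrom!r} absent from FASTA"
            )
        if strand == "-":
            pieces = sorted(pieces, key=lambda f: f.start, reverse=True)
        else:
            pieces = sorted(pieces, key=lambda f: f.start)
        seq = genome[chrom]
        if strand == "-":
            cds = "".join(reverse_complement(seq[f.start : f.end]) for f in pieces)
        else:
            cds = "".join(seq[f.start : f.end] for f in pieces)
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna_id,
                chromosome=chrom,
                strand=strand,
                coding_exons=tuple((f.start, f.end) for f in pieces),
                cds_sequence=cds,
            )
        )
    return transcripts


def filter_cds(t: TranscriptModel) -> FilterReport:
    """Apply the CDS sanity rules, reporting the first failure in fixed order:
    not_multiple_of_three, contains_N, bad_start, bad_stop."""
    cds = t.cds_sequence
    reason = "none"
    if len(cds) == 0 or len(cds) % 3 != 0:
        reason = "not_multiple_of_three"
    elif "N" in cds:
        reason = "contains_N"
    elif not cds.startswith("ATG"):
        reason = "bad_start"
    elif cds[-3:] not in GENETIC_CODE.stops:
        reason = "bad_stop"
    outcome = "retained" if reason == "none" else "rejected"
    return FilterReport(t.gene_id, t.transcript_id, outcome, reason)


def assign_codons(t: TranscriptModel, code: GeneticCode = GENETIC_CODE) -> list[CodonRecord]:
    """One CodonRecord per codon of the CDS, stop codon included.

    The exon owning a codon is the exon containing the codon's middle
    nucleotide, which realises the split-codon convention (phase-1 split ->
    downstream exon, phase-2 split -> upstream exon).
    """
    cds = t.cds_sequence
    if len(cds) % 3:
        raise ValueError(f"{t.transcript_id}: CDS not a multiple of three; filter first")
    # Exclusive cumulative ends of coding exons in CDS coordinates.
    cum_ends: list[int] = []
    acc = 0
    for s, e in t.coding_exons:
        acc += e - s
        cum_ends.append(acc)

    n_codons = len(cds) // 3
    records: list[CodonRecord] = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        middle = 3 * i + 1
        exon_ordinal = bisect.bisect_right(cum_ends, middle) + 1
        next_first = cds[3 * (i + 1)] if i + 1 < n_codons else None
        records.append(
            CodonRecord(
                codon=codon,
                amino_acid=code.codon_to_aa[codon],
                ordinal=i + 1,
                exon_ordinal=exon_ordinal,
                exon_count=t.exon_count,
                intron_count=t.intron_count,
                next_first_base=next_first,
                gene_id=t.gene_id,
                chromosome=t.chromosome,
            )
        )
    return records


def load_codon_records(
    source: GenomeSource,
) -> tuple[list[CodonRecord], list[FilterReport]]:
    """Full ingestion: transcripts -> filters -> codon records for retained genes."""
    records: list[CodonRecord] = []
    reports: list[FilterReport] = []
    for t in load_transcripts(source):
        report = filter_cds(t)
        reports.append(report)
        if report.outcome == "retained":
            records.extend(assign_codons(t))
    return records, reports


def write_filter_report(reports: Iterable[FilterReport], path: Path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\ttranscript_id\toutcome\treason\n")
        for r in reports:
            out.write(f"{r.gene_id}\t{r.transcript_id}\t{r.outcome}\t{r.reason}\n")
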