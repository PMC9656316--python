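"""Stratification of codon statistics by gene structure.

Codon records are pooled by chromosome, by intron number (classes 0-9) and
by exon ordinal within genes of a given coding-exon count (2-10).  All
stratum statistics are pooled-count ratios, never per-gene averages.  Stop
codons never enter SC statistics; genes outside a table's class range are
excluded from that table only (they remain in genome-wide totals).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotation_io import CodonRecord
from .codon_stats import CodonCounts, ScubSummary, scub_summary

MAX_INTRON_CLASS = 9
MIN_EXON_CLASS = 2
MAX_EXON_CLASS = 10


@dataclass(frozen=True)
class StratumKey:
    species_label: str = ""
    chromosome: Optional[str] = None
    intron_class: Optional[int] = None
    exon_count_class: Optional[int] = None
    exon_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        if self.exon_ordinal is not None and self.exon_count_class is None:
            raise ValueError("exon_ordinal requires exon_count_class")
        if self.intron_class is not None and self.exon_count_class is not None:
            raise ValueError("intron_class and exon_count_class are separate tables")


@dataclass
class PositionProfile:
    """Per-ordinal SCUB summaries for genes with exactly m coding exons."""

    exon_count_class: int
    ordinal_counts: list[CodonCounts]
    ordinal_summaries: list[Optional[ScubSummary]]

    @property
    def terminal_ordinals(self) -> set[int]:
        m = self.exon_count_class
        return {1, 2, m} if m >= 2 else {1}

    @property
    def internal_ordinals(self) -> set[int]:
        m = self.exon_count_class
        return set(range(3, m)) if m > 3 else set()


def stratify_by_introns(
    records: Iterable[CodonRecord],
    max_class: int = MAX_INTRON_CLASS,
) -> dict[int, CodonCounts]:
    """Pool codon counts per intron class 0..max_class.

    Genes with more introns than ``max_class`` are excluded from this table
    (but are still in whatever genome-wide tally the caller keeps).
    """
    table = {k: CodonCounts(scope_label=f"introns={k}") for k in range(max_class + 1)}
    for rec in records:
        if rec.intron_count <= max_class:
            table[rec.intron_count].counts[rec.codon] += 1
    return table


def exon_position_profiles(
    records: Iterable[CodonRecord],
    min_class: int = MIN_EXON_CLASS,
    max_class: int = MAX_EXON_CLASS,
) -> dict[int, PositionProfile]:
    """Per-ordinal pooled summaries for each exon-count class m in [min, max]."""
    counts: dict[int, list[CodonCounts]] = {
        m: [CodonCounts(scope_label=f"m={m},ordinal={o + 1}") for o in range(m)]
        for m in range(min_class, max_class + 1)
    }
    for rec in records:
        m = rec.exon_count
        if min_class <= m <= max_class:
            counts[m][rec.exon_ordinal - 1].counts[rec.codon] += 1

    profiles: dict[int, PositionProfile] = {}
    for m, per_ordinal in counts.items():
        summaries: list[Optional[ScubSummary]] = []
        for c in per_ordinal:
            summaries.append(scub_summary(c) if c.total_sc() > 0 else None)
        profiles[m] = PositionProfile(m, per_ordinal, summaries)
    return profiles


def chromosome_profiles(
    records: Sequence[CodonRecord],
) -> tuple[dict[str, ScubSummary], ScubSummary]:
    """One summary per chromosome plus the genome-wide summary."""
    per_chrom: dict[str, CodonCounts] = {}
    genome = CodonCounts(scope_label="genome")
    for rec in records:
        chrom = per_chrom.setdefault(rec.chromosome, CodonCounts(scope_label=rec.chromosome))
        chrom.counts[rec.codon] += 1
        genome.counts[rec.codon] += 1
    summaries = {name: scub_summary(c) for name, c in sorted(per_chrom.items()) if c.total_sc() > 0}
    return summaries, scub_summary(genome)


def first_exon_cv(
    profiles: dict[int, PositionProfile], statistic: str = "f_nnat", ordinal: int = 1
) -> float:
    """Coefficient of variation of one per-ordinal statistic across exon-count
    classes (default: first-exon f_NNAT across m = 2..10)."""
    values = []
    for m in sorted(profiles):
        summary = profiles[m].ordinal_summaries[ordinal - 1]
        if summary is not None:
            values.append(getattr(summary, statistic))
    if len(values) < 2:
        raise ValueError("need at least two classes with data")
    mean = statistics.fmean(values)
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return statistics.stdev(values) / mean
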