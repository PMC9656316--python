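"""Sequence-context codon-combination ratios tied to CpG deamination.

Methylated cytosine deaminates to thymine, turning CpG into TpG on the
sense strand and CpA on the antisense strand.  Two codon-level proxies are
computed over the 59 synonymous codons:

* second-base context — counts of A-ending vs G-ending SCs keyed by the
  second base X (the NCA/NCG ratio is the antisense-strand signal);
* next-codon context — counts of T-ending vs C-ending SCs keyed by the
  first base X of the following codon (NT|G / NC|G is the sense-strand
  signal); the stop codon donates context for the final sense codon, and
  records without context are dropped from these tallies only.

Per-amino-acid A/G-ending pair ratios are restricted to codon pairs sharing
their first two bases (Ala GCA/GCG, ... Arg CGA/CGG + AGA/AGG, etc.).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation_io import CodonRecord
from .codon_stats import BASES, GENETIC_CODE, GeneticCode
from .structure_strata import (
    MAX_EXON_CLASS,
    MAX_INTRON_CLASS,
    MIN_EXON_CLASS,
)


def _zero_by_base() -> dict[str, int]:
    return {b: 0 for b in BASES}


@dataclass
class ContextTally:
    """Raw counts behind the context ratios.

    nxa/nxg key the third-base-A/G SC counts by second base; ntx/ncx key the
    third-base-T/C SC counts by the next codon's first base.  ``a_ending``
    and ``g_ending`` keep per-codon counts of A-/G-ending SCs so that
    amino-acid pair ratios can be formed.
    """

    nxa: dict[str, int] = field(default_factory=_zero_by_base)
    nxg: dict[str, int] = field(default_factory=_zero_by_base)
    ntx: dict[str, int] = field(default_factory=_zero_by_base)
    ncx: dict[str, int] = field(default_factory=_zero_by_base)
    a_ending: Counter = field(default_factory=Counter)
    g_ending: Counter = field(default_factory=Counter)

    def __add__(self, other: "ContextTally") -> "ContextTally":
        merged = ContextTally()
        for b in BASES:
            merged.nxa[b] = self.nxa[b] + other.nxa[b]
            merged.nxg[b] = self.nxg[b] + other.nxg[b]
            merged.ntx[b] = self.ntx[b] + other.ntx[b]
            merged.ncx[b] = self.ncx[b] + other.ncx[b]
        merged.a_ending = self.a_ending + other.a_ending
        merged.g_ending = self.g_ending + other.g_ending
        return merged


@dataclass(frozen=True)
class ContextRatios:
    r_xa_xg: dict[str, Optional[float]]
    r_tx_cx: dict[str, Optional[float]]
    aa_pair_ratios: dict[str, Optional[float]]


def context_tally(
    records: Iterable[CodonRecord], code: GeneticCode = GENETIC_CODE
) -> ContextTally:
    tally = ContextTally()
    sc = code.sc_set
    for rec in records:
        codon = rec.codon
        if codon not in sc:
            continue
        third = codon[2]
        if third == "A":
            tally.nxa[codon[1]] += 1
            tally.a_ending[codon] += 1
        elif third == "G":
            tally.nxg[codon[1]] += 1
            tally.g_ending[codon] += 1
        elif third == "T":
            if rec.next_first_base is not None:
                tally.ntx[rec.next_first_base] += 1
        elif third == "C":
            if rec.next_first_base is not None:
                tally.ncx[rec.next_first_base] += 1
    return tally


def _aa_pairs(code: GeneticCode) -> dict[str, list[tuple[str, str]]]:
    """Per amino acid, the (NNA, NNG) codon pairs sharing first two bases."""
    pairs: dict[str, list[tuple[str, str]]] = {}
    for aa in code.degenerate_amino_acids:
        fam = set(code.families[aa]) & code.sc_set
        for codon in sorted(fam):
            if codon[2] == "A" and codon[:2] + "G" in fam:
                pairs.setdefault(aa, []).append((codon, codon[:2] + "G"))
    return pairs


def context_ratios(
    tally: ContextTally, code: GeneticCode = GENETIC_CODE
) -> ContextRatios:
    """All NXA/NXG and NT|X/NC|X ratios plus amino-acid pair ratios.

    Zero denominators yield ``None`` markers, never infinities.
    """
    r_xa_xg = {
        b: (tally.nxa[b] / tally.nxg[b]) if tally.nxg[b] > 0 else None for b in BASES
    }
    r_tx_cx = {
        b: (tally.ntx[b] / tally.ncx[b]) if tally.ncx[b] > 0 else None for b in BASES
    }
    aa_ratios: dict[str, Optional[float]] = {}
    for aa, pairs in _aa_pairs(code).items():
        num = sum(tally.a_ending[a] for a, _ in pairs)
        den = sum(tally.g_ending[g] for _, g in pairs)
        aa_ratios[aa] = (num / den) if den > 0 else None
    return ContextRatios(r_xa_xg=r_xa_xg, r_tx_cx=r_tx_cx, aa_pair_ratios=aa_ratios)


def context_by_intron_class(
    records: Iterable[CodonRecord],
    max_class: int = MAX_INTRON_CLASS,
    code: GeneticCode = GENETIC_CODE,
) -> dict[int, ContextRatios]:
    """NXA/NXG and NT|X/NC|X ratios per intron class 0..max_class."""
    tallies = {k: ContextTally() for k in range(max_class + 1)}
    grouped: dict[int, list[CodonRecord]] = {k: [] for k in range(max_class + 1)}
    for rec in records:
        if rec.intron_count <= max_class:
            grouped[rec.intron_count].append(rec)
    for k, recs in grouped.items():
        tallies[k] = context_tally(recs, code)
    return {k: context_ratios(t, code) for k, t in tallies.items()}


def context_by_exon_position(
    records: Iterable[CodonRecord],
    min_class: int = MIN_EXON_CLASS,
    max_class: int = MAX_EXON_CLASS,
    code: GeneticCode = GENETIC_CODE,
) -> dict[int, list[ContextRatios]]:
    """Per-ordinal context ratios for each exon-count class m in [min, max]."""
    grouped: dict[tuple[int, int], list[CodonRecord]] = {}
    for rec in records:
        m = rec.exon_count
        if min_class <= m <= max_class:
            grouped.setdefault((m, rec.exon_ordinal), []).append(rec)
    out: dict[int, list[ContextRatios]] = {}
    for m in range(min_class, max_class + 1):
        out[m] = [
            context_ratios(context_tally(grouped.get((m, o), []), code), code)
            for o in range(1, m + 1)
        ]
    return out


def stratified_context(
    records: list[CodonRecord],
    code: GeneticCode = GENETIC_CODE,
) -> dict[str, object]:
    """Convenience bundle: genome-wide, intron-class and exon-position ratios."""
    return {
        "genome": context_ratios(context_tally(records, code), code),
        "by_intron_class": context_by_intron_class(records, code=code),
        "by_exon_position": context_by_exon_position(records, code=code),
    }
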