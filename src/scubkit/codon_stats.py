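"""Genetic code bookkeeping and synonymous-codon usage statistics.

The central objects are :class:`GeneticCode` (the standard nuclear code,
its synonymous families and the 59-codon synonymous set), :class:`CodonCounts`
(a tally over all 64 codons for some scope) and the derived summaries:
third-base fractions, per-amino-acid C/G-vs-A/T usage ratios, RSCU, CAI,
CBI and Wright's effective number of codons (Nc).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")
STOP_SYMBOL = "*"


def _all_codons() -> tuple[str, ...]:
    return tuple(a + b + c for a in BASES for b in BASES for c in BASES)

ALL_CODONS: tuple[str, ...] = _all_codons()


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code plus the synonymous-codon machinery.

    Attributes
    ----------
    codon_to_aa
        Map over all 64 codons; stop codons map to ``"*"``.
    sense_codons
        The 61 amino-acid-encoding codons.
    sc_set
        The 59 synonymous codons: sense codons minus ATG (Met) and TGG (Trp).
    families
        Per amino acid, the tuple of its codons.  Ser is one six-codon
        family (TCN plus AGT/AGC).
    stops
        The three stop codons.
    """

    codon_to_aa: Mapping[str, str]
    sense_codons: frozenset[str]
    sc_set: frozenset[str]
    families: Mapping[str, tuple[str, ...]]
    stops: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = STOP_SYMBOL
        sense = frozenset(c for c, aa in codon_to_aa.items() if aa != STOP_SYMBOL)
        families: dict[str, list[str]] = {}
        for codon in sorted(sense):
            families.setdefault(codon_to_aa[codon], []).append(codon)
        sc = frozenset(c for c in sense if len(families[codon_to_aa[c]]) >= 2)
        return cls(
            codon_to_aa=codon_to_aa,
            sense_codons=sense,
            sc_set=sc,
            families={aa: tuple(cs) for aa, cs in families.items()},
            stops=frozenset(table.stop_codons),
        )

    @property
    def degenerate_amino_acids(self) -> tuple[str, ...]:
        """The amino acids encoded by two or more codons (18 of them)."""
        return tuple(sorted(aa for aa, fam in self.families.items() if len(fam) >= 2))

    def translate(self, cds: str) -> str:
        if len(cds) % 3:
            raise ValueError("CDS length is not a multiple of three")
        return "".join(self.codon_to_aa[cds[i : i + 3]] for i in range(0, len(cds), 3))

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]


GENETIC_CODE = GeneticCode.standard()

# Degeneracy classes used by Wright's Nc.  Ser counts as six-fold.
_NC_CLASS_OF_SIZE = {2: "2-fold", 3: "3-fold", 4: "4-fold", 6: "6-fold"}
_NC_CLASS_WEIGHT = {"2-fold": 9, "3-fold": 1, "4-fold": 5, "6-fold": 3}


@dataclass
class CodonCounts:
    """Codon tally over some scope (genome, chromosome, stratum).

    All 64 codons are present as keys; stop-codon counts are stored but
    excluded from every synonymous-codon statistic.
    """

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    scope_label: str = ""

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        full.update(self.counts)
        self.counts = full

    @classmethod
    def from_codon_iter(cls, codons: Iterable[str], scope_label: str = "") -> "CodonCounts":
        c = cls(scope_label=scope_label)
        for codon in codons:
            c.counts[codon] += 1
        return c

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts(counts=dict(merged), scope_label=self.scope_label)

    def total_sense(self, code: GeneticCode = GENETIC_CODE) -> int:
        return sum(self.counts[c] for c in code.sense_codons)

    def total_sc(self, code: GeneticCode = GENETIC_CODE) -> int:
        return sum(self.counts[c] for c in code.sc_set)


def count_codons(records, scope_label: str = "", include_stops: bool = True) -> CodonCounts:
    """Tally codons from an iterable of CodonRecord-like objects.

    Stop codons are counted (marked by the genetic code, not removed)
    unless ``include_stops`` is false; downstream SC statistics exclude
    them by construction of the 59-codon set, as they do ATG and TGG.
    """
    counts = CodonCounts(scope_label=scope_label)
    for rec in records:
        if not include_stops and rec.amino_acid == STOP_SYMBOL:
            continue
        counts.counts[rec.codon] += 1
    return counts


def codon_frequencies(c: CodonCounts, code: GeneticCode = GENETIC_CODE) -> dict[str, float]:
    """Frequency of each of the 61 sense codons relative to all sense codons."""
    total = c.total_sense(code)
    if total == 0:
        raise ValueError(f"empty scope {c.scope_label!r}: no sense codons counted")
    return {codon: c.counts[codon] / total for codon in sorted(code.sense_codons)}


@dataclass(frozen=True)
class ScubSummary:
    """Third-base composition of the 59 synonymous codons in a scope."""

    f_nna: float
    f_nnt: float
    f_nnc: float
    f_nng: float
    n_sc: int
    per_aa_scub: Mapping[str, Optional[float]]

    @property
    def f_nnat(self) -> float:
        return self.f_nna + self.f_nnt

    @property
    def f_nncg(self) -> float:
        return self.f_nnc + self.f_nng

    @property
    def ratio_at_over_cg(self) -> Optional[float]:
        return self.f_nnat / self.f_nncg if self.f_nncg > 0 else None

    @property
    def ratio_cg_over_at(self) -> Optional[float]:
        return self.f_nncg / self.f_nnat if self.f_nnat > 0 else None


def scub_summary(c: CodonCounts, code: GeneticCode = GENETIC_CODE) -> ScubSummary:
    """Third-base fractions over the 59 SCs plus per-amino-acid C/G:A/T ratios.

    Per-amino-acid values are the count ratio of that amino acid's C/G-ending
    synonymous codons to its A/T-ending ones; a zero A/T-ending count yields
    ``None`` (an explicit undefined marker), never infinity.
    """
    by_third = {b: 0 for b in BASES}
    for codon in code.sc_set:
        by_third[codon[2]] += c.counts[codon]
    n_sc = sum(by_third.values())
    if n_sc == 0:
        raise ValueError(f"empty scope {c.scope_label!r}: no synonymous codons counted")

    per_aa: dict[str, Optional[float]] = {}
    for aa in code.degenerate_amino_acids:
        cg = sum(c.counts[cd] for cd in code.families[aa] if cd[2] in "CG" and cd in code.sc_set)
        at = sum(c.counts[cd] for cd in code.families[aa] if cd[2] in "AT" and cd in code.sc_set)
        per_aa[aa] = (cg / at) if at > 0 else None

    return ScubSummary(
        f_nna=by_third["A"] / n_sc,
        f_nnt=by_third["T"] / n_sc,
        f_nnc=by_third["C"] / n_sc,
        f_nng=by_third["G"] / n_sc,
        n_sc=n_sc,
        per_aa_scub=per_aa,
    )


def rscu(c: CodonCounts, code: GeneticCode = GENETIC_CODE) -> dict[str, Optional[float]]:
    """Relative synonymous codon usage: count * family size / family total.

    Families with zero total yield ``None`` for each member.
    """
    values: dict[str, Optional[float]] = {}
    for aa, family in code.families.items():
        if aa == STOP_SYMBOL:
            continue
        total = sum(c.counts[cd] for cd in family)
        k = len(family)
        for cd in family:
            values[cd] = (c.counts[cd] * k / total) if total > 0 else None
    return values


@dataclass(frozen=True)
class BiasIndices:
    rscu: Mapping[str, Optional[float]]
    cai: float
    cbi: float
    enc: float
    gc3: float


def _relative_adaptiveness(
    c: CodonCounts, code: GeneticCode
) -> dict[str, float]:
    """w_j = RSCU_j / max family RSCU, from the scope's own usage."""
    r = rscu(c, code)
    w: dict[str, float] = {}
    for aa, family in code.families.items():
        vals = [r[cd] for cd in family if r[cd] is not None]
        top = max(vals) if vals else 0.0
        for cd in family:
            w[cd] = (r[cd] / top) if (r[cd] is not None and top > 0) else 0.0
    return w


def cai(
    c: CodonCounts,
    code: GeneticCode = GENETIC_CODE,
    reference_weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness
    over the 59 SC occurrences.

    Default weights are self-referential (derived from the scope's own
    RSCU); pass ``reference_weights`` for an external reference set.
    Observed codons with zero reference weight are floored at 1e-4 so the
    geometric mean stays finite (Sharp & Li style guard).
    """
    w = dict(reference_weights) if reference_weights is not None else _relative_adaptiveness(c, code)
    log_sum = 0.0
    n = 0
    for codon in code.sc_set:
        cnt = c.counts[codon]
        if cnt == 0:
            continue
        weight = max(w.get(codon, 0.0), 1e-4)
        log_sum += cnt * math.log(weight)
        n += cnt
    if n == 0:
        raise ValueError("no synonymous codons observed")
    return math.exp(log_sum / n)


def cbi(c: CodonCounts, code: GeneticCode = GENETIC_CODE) -> float:
    """Bennetzen–Hall codon bias index with self-derived preferred codons.

    The preferred codon of each family is its most frequent member (ties
    broken alphabetically).  CBI = (Npref - Nrand) / (Ntot - Nrand) where
    Nrand is the preferred-codon count expected under uniform usage.
    """
    n_pref = 0.0
    n_rand = 0.0
    n_tot = 0
    for aa in code.degenerate_amino_acids:
        family = code.families[aa]
        counts = {cd: c.counts[cd] for cd in family}
        n_aa = sum(counts.values())
        if n_aa == 0:
            continue
        preferred = min(family, key=lambda cd: (-counts[cd], cd))
        n_pref += counts[preferred]
        n_rand += n_aa / len(family)
        n_tot += n_aa
    if n_tot == 0:
        raise ValueError("no synonymous codons observed")
    denom = n_tot - n_rand
    return (n_pref - n_rand) / denom if denom > 0 else 0.0


def effective_number_of_codons(c: CodonCounts, code: GeneticCode = GENETIC_CODE) -> float:
    """Wright's Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, clamped to [20, 61].

    F for one amino acid is the codon homozygosity (n*sum(p^2) - 1)/(n - 1)
    over its family, computed only when n >= 2; class means average over
    the amino acids with defined F.  A missing three-fold class mean is
    replaced by (F2 + F4)/2, Wright's recommendation.
    """
    class_fs: dict[str, list[float]] = {k: [] for k in _NC_CLASS_WEIGHT}
    for aa in code.degenerate_amino_acids:
        family = code.families[aa]
        counts = [c.counts[cd] for cd in family]
        n = sum(counts)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in counts)
        f = (n * sum_p2 - 1) / (n - 1)
        class_fs[_NC_CLASS_OF_SIZE[len(family)]].append(f)

    means: dict[str, float] = {}
    for klass, fs in class_fs.items():
        if fs:
            means[klass] = sum(fs) / len(fs)
    if "3-fold" not in means and "2-fold" in means and "4-fold" in means:
        means["3-fold"] = (means["2-fold"] + means["4-fold"]) / 2

    enc = 2.0
    for klass, weight in _NC_CLASS_WEIGHT.items():
        mean_f = means.get(klass)
        if mean_f is None or mean_f <= 0:
            # Degenerate scope; treat the class as maximally diverse.
            mean_f = 1.0 / int(klass[0])
        enc += weight / mean_f
    return min(61.0, max(20.0, enc))


def gc3(c: CodonCounts, code: GeneticCode = GENETIC_CODE) -> float:
    """Fraction of SC occurrences whose third base is G or C."""
    total = c.total_sc(code)
    if total == 0:
        raise ValueError("no synonymous codons observed")
    cg = sum(c.counts[cd] for cd in code.sc_set if cd[2] in "CG")
    return cg / total


def bias_indices(
    c: CodonCounts,
    reference_weights: Optional[Mapping[str, float]] = None,
    code: GeneticCode = GENETIC_CODE,
) -> BiasIndices:
    return BiasIndices(
        rscu=rscu(c, code),
        cai=cai(c, code, reference_weights),
        cbi=cbi(c, code),
        enc=effective_number_of_codons(c, code),
        gc3=gc3(c, code),
    )
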