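"""Synthetic annotated genomes with known codon-usage structure.

Genomes are emitted as standard FASTA + GFF3 (gene/mRNA/CDS, 1-based
inclusive, phase column populated) together with a truth manifest recording
every sampled codon and its exon assignment, so each pipeline stage can be
validated against ground truth.

Codon sampling is two-pass.  Pass one draws, per gene, the exon
architecture and for every codon the amino acid and its first-two-base
group; pass two draws third bases with logistic weights

    log-odds(C/G vs A/T third base) = beta0 - beta1 * introns - beta2 * w

where w is a centrality weight (0 at exons 1, 2 and m, peaking mid-gene),
then multiplies the weight of A by gamma when the codon's second base is C
and the weight of T by gamma when the next codon starts with G.  Drawing
first-two-base choices before third bases makes the next-codon context
well defined at sampling time.
"""

from __future__ import annotations

import bisect
import json
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .annotation_io import GenomeSource, reverse_complement
from .codon_stats import GENETIC_CODE, GeneticCode

_STOPS = ("TAA", "TAG", "TGA")


def _default_exon_count_weights() -> dict[int, float]:
    return {m: 1.0 for m in range(1, 11)}


def _family_groups(code: GeneticCode) -> dict[str, list[tuple[str, tuple[str, ...]]]]:
    """Per amino acid: [(first_two_bases, available third bases), ...]."""
    groups: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    for aa, family in code.families.items():
        if aa == "*":
            continue
        by_prefix: dict[str, list[str]] = {}
        for codon in family:
            by_prefix.setdefault(codon[:2], []).append(codon[2])
        groups[aa] = [(p, tuple(sorted(t))) for p, t in sorted(by_prefix.items())]
    return groups

_GROUPS = _family_groups(GENETIC_CODE)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic species.

    ``exon_count_weights`` supports 1..10 coding exons; exon lengths are
    uniform in codons on [exon_length_min, exon_length_max] with a floor of
    2.  ``amino_acid_composition`` defaults to uniform over the 18
    degenerate amino acids; ``met_trp_weight`` optionally adds internal
    Met/Trp codons.
    """

    seed: int
    n_genes: int
    species_label: str = "synthetic"
    n_chromosomes: int = 2
    exon_count_weights: dict[int, float] = field(default_factory=_default_exon_count_weights)
    exon_length_min: int = 4
    exon_length_max: int = 12
    amino_acid_composition: Optional[dict[str, float]] = None
    met_trp_weight: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    gamma: float = 1.0
    intron_length: int = 10

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_chromosomes < 1:
            raise ValueError("need n_genes >= 0 and n_chromosomes >= 1")
        if not self.exon_count_weights:
            raise ValueError("exon_count_weights is empty")
        for m, wgt in self.exon_count_weights.items():
            if not 1 <= m <= 10 or wgt < 0:
                raise ValueError("exon_count_weights support must lie in 1..10 with weights >= 0")
        if sum(self.exon_count_weights.values()) <= 0:
            raise ValueError("exon_count_weights sum to zero")
        if self.exon_length_min < 2 or self.exon_length_max < self.exon_length_min:
            raise ValueError("exon lengths in codons need 2 <= min <= max")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.intron_length < 4:
            raise ValueError("intron_length must be >= 4 (GT..AG)")
        if self.amino_acid_composition is not None:
            unknown = set(self.amino_acid_composition) - set(GENETIC_CODE.degenerate_amino_acids)
            if unknown:
                raise ValueError(f"unknown/non-degenerate amino acids in composition: {unknown}")
            if sum(self.amino_acid_composition.values()) <= 0:
                raise ValueError("amino_acid_composition sums to zero")

    def centrality_weight(self, ordinal: int, m: int) -> float:
        """0 at ordinals 1, 2 and m; symmetric about the middle; peak 1."""
        if m <= 3 or ordinal <= 2 or ordinal >= m:
            return 0.0
        return math.sin(math.pi * (ordinal - 2) / (m - 2))


@dataclass
class _GeneStructure:
    gene_id: str
    chromosome_index: int
    strand: str
    exon_codon_lengths: list[int]     # body codons per exon (start/stop extra)
    break_offsets: list[int]          # nt offsets of exon boundaries in the CDS
    intron_seqs: list[str]
    # pass-one codon content: (amino acid, first two bases, third-base options)
    body_groups: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    # pass-two realized body codons (start/stop excluded)
    body_codons: list[str] = field(default_factory=list)
    stop_codon: str = "TAA"

    @property
    def exon_count(self) -> int:
        return len(self.exon_codon_lengths)

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1

    @property
    def n_codons(self) -> int:
        return sum(self.exon_codon_lengths) + 2  # + start + stop

    def exon_ordinal_of_codon(self, i: int) -> int:
        """Ordinal of 0-based codon i: the exon holding its middle base."""
        return bisect.bisect_right(self.break_offsets, 3 * i + 1) + 1


@dataclass
class TruthManifest:
    """Ground truth for a generated genome: parameters plus, per gene, the
    realized exon architecture, the full CDS and each codon's exon ordinal."""

    params: dict
    genes: list[dict]

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "genes": self.genes}, indent=1)

    def write_tsv(self, path: Path) -> None:
        with open(path, "w") as out:
            out.write("gene_id\tchromosome\tstrand\texon_count\tintron_count\tcds\texon_ordinals\n")
            for g in self.genes:
                ords = ",".join(map(str, g["codon_exon_ordinals"]))
                out.write(
                    f"{g['gene_id']}\t{g['chromosome']}\t{g['strand']}\t"
                    f"{g['exon_count']}\t{g['intron_count']}\t{g['cds']}\t{ords}\n"
                )


@dataclass
class SyntheticGenome:
    fasta_text: str
    gff3_text: str
    manifest: TruthManifest
    species_label: str

    def write(self, out_dir: Path, prefix: Optional[str] = None) -> GenomeSource:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.species_label
        fasta = out_dir / f"{prefix}.fa"
        gff3 = out_dir / f"{prefix}.gff3"
        fasta.write_text(self.fasta_text)
        gff3.write_text(self.gff3_text)
        (out_dir / f"{prefix}.manifest.json").write_text(self.manifest.to_json())
        return GenomeSource(self.species_label, fasta, gff3)


def _draw_structures(spec: GeneratorSpec, rng: random.Random) -> list[_GeneStructure]:
    ms = sorted(spec.exon_count_weights)
    weights = [spec.exon_count_weights[m] for m in ms]
    structures = []
    for g in range(spec.n_genes):
        m = rng.choices(ms, weights=weights)[0]
        lengths = [rng.randint(spec.exon_length_min, spec.exon_length_max) for _ in range(m)]
        breaks: list[int] = []
        acc = 0
        for length in lengths[:-1]:
            acc += length
            # Boundary near the codon boundary 3*(acc+1), jittered across the
            # three phases so split codons of both kinds occur.
            breaks.append(3 * (acc + 1) + rng.choice((-2, -1, 0)))
        introns = [
            "GT" + "".join(rng.choice("ACGT") for _ in range(spec.intron_length - 4)) + "AG"
            for _ in range(m - 1)
        ]
        structures.append(
            _GeneStructure(
                gene_id=f"g{g + 1:05d}",
                chromosome_index=g % spec.n_chromosomes,
                strand=rng.choice("+-"),
                exon_codon_lengths=lengths,
                break_offsets=breaks,
                intron_seqs=introns,
            )
        )
    return structures


def _draw_codon_content(
    structures: list[_GeneStructure], spec: GeneratorSpec, rng: random.Random
) -> None:
    """Pass one: amino acids and first-two-base groups; pass two: third bases."""
    if spec.amino_acid_composition is not None:
        aa_items = sorted(spec.amino_acid_composition.items())
        aas = [a for a, _ in aa_items]
        aa_weights = [w for _, w in aa_items]
    else:
        aas = list(GENETIC_CODE.degenerate_amino_acids)
        aa_weights = [1.0] * len(aas)
    if spec.met_trp_weight > 0:
        aas = aas + ["M", "W"]
        aa_weights = aa_weights + [spec.met_trp_weight, spec.met_trp_weight]

    third_cache: dict[tuple, tuple[list[str], list[float]]] = {}

    def third_base(
        prefix: str,
        thirds: tuple[str, ...],
        introns: int,
        ordinal: int,
        m: int,
        next_is_g: bool,
    ) -> str:
        if len(thirds) == 1:
            return thirds[0]
        key = (prefix[1], thirds, introns, ordinal, m, next_is_g)
        cached = third_cache.get(key)
        if cached is None:
            eta = spec.beta0 - spec.beta1 * introns - spec.beta2 * spec.centrality_weight(ordinal, m)
            weights = []
            for b in thirds:
                wgt = math.exp(eta / 2) if b in "CG" else math.exp(-eta / 2)
                if b == "A" and prefix[1] == "C":
                    wgt *= spec.gamma
                if b == "T" and next_is_g:
                    wgt *= spec.gamma
                weights.append(wgt)
            total = sum(weights)
            cum = []
            acc = 0.0
            for wgt in weights:
                acc += wgt / total
                cum.append(acc)
            cached = (list(thirds), cum)
            third_cache[key] = cached
        opts, cum = cached
        return opts[bisect.bisect_left(cum, rng.random())]

    for s in structures:
        n_body = sum(s.exon_codon_lengths)
        pass1 = []
        for _ in range(n_body):
            aa = aas[rng.choices(range(len(aas)), weights=aa_weights)[0]]
            groups = _GROUPS[aa]
            if len(groups) > 1:
                sizes = [len(t) for _, t in groups]
                prefix, thirds = groups[rng.choices(range(len(groups)), weights=sizes)[0]]
            else:
                prefix, thirds = groups[0]
            pass1.append((aa, prefix, thirds))
        s.stop_codon = rng.choice(_STOPS)
        s.body_groups = pass1

    for s in structures:
        m = s.exon_count
        introns = s.intron_count
        codons: list[str] = []
        for j, (_aa, prefix, thirds) in enumerate(s.body_groups):
            codon_index = j + 1  # 0 is the start codon
            ordinal = s.exon_ordinal_of_codon(codon_index)
            next_first = (
                s.body_groups[j + 1][1][0] if j + 1 < len(s.body_groups) else s.stop_codon[0]
            )
            codons.append(prefix + third_base(prefix, thirds, introns, ordinal, m, next_first == "G"))
        s.body_codons = codons


def _cds_of(structure: _GeneStructure) -> str:
    return "ATG" + "".join(structure.body_codons) + structure.stop_codon


def generate_genome(spec: GeneratorSpec) -> SyntheticGenome:
    """Generate FASTA + GFF3 + truth manifest; byte-deterministic under seed."""
    spec.validate()
    struct_rng = random.Random(f"{spec.seed}:structure")
    codon_rng = random.Random(f"{spec.seed}:{spec.species_label}:codons")

    structures = _draw_structures(spec, struct_rng)
    _draw_codon_content(structures, spec, codon_rng)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chrom_seqs: list[list[str]] = [[struct_rng.choice("ACGT")] for _ in chrom_names]
    chrom_len = [1] * spec.n_chromosomes

    gff_lines = ["##gff-version 3"]
    manifest_genes: list[dict] = []

    for s in structures:
        cds = _cds_of(s)
        bounds = [0] + s.break_offsets + [len(cds)]
        exon_nt = [cds[bounds[i] : bounds[i + 1]] for i in range(s.exon_count)]
        region_parts = []
        for i, piece in enumerate(exon_nt):
            region_parts.append(piece)
            if i < s.intron_count:
                region_parts.append(s.intron_seqs[i])
        region = "".join(region_parts)

        # exon intervals within the plus-orientation region (0-based half-open)
        region_exons = []
        pos = 0
        for i, piece in enumerate(exon_nt):
            region_exons.append((pos, pos + len(piece)))
            pos += len(piece)
            if i < s.intron_count:
                pos += len(s.intron_seqs[i])

        ci = s.chromosome_index
        g0 = chrom_len[ci]
        if s.strand == "+":
            placed = region
            genomic_exons = [(g0 + a, g0 + b) for a, b in region_exons]
        else:
            placed = reverse_complement(region)
            L = len(region)
            genomic_exons = [(g0 + L - b, g0 + L - a) for a, b in region_exons]
        chrom_seqs[ci].append(placed)
        chrom_seqs[ci].append(struct_rng.choice("ACGT"))  # intergenic spacer
        chrom_len[ci] += len(placed) + 1

        chrom = chrom_names[ci]
        tid = f"{s.gene_id}.t1"
        lo = min(a for a, _ in genomic_exons) + 1
        hi = max(b for _, b in genomic_exons)
        attrs_gene = f"ID={s.gene_id};biotype=protein_coding"
        gff_lines.append(
            f"{chrom}\tscubkit\tgene\t{lo}\t{hi}\t.\t{s.strand}\t.\t{attrs_gene}"
        )
        gff_lines.append(
            f"{chrom}\tscubkit\tmRNA\t{lo}\t{hi}\t.\t{s.strand}\t.\tID={tid};Parent={s.gene_id}"
        )
        # CDS rows in transcript order with correct phase; coordinates 1-based.
        # genomic_exons follows region (= transcript) order on both strands:
        # for minus-strand genes that is descending genomic coordinates.
        transcript_order = genomic_exons
        nt_before = 0
        for a, b in transcript_order:
            phase = (3 - nt_before % 3) % 3
            gff_lines.append(
                f"{chrom}\tscubkit\tCDS\t{a + 1}\t{b}\t.\t{s.strand}\t{phase}\tID={tid}.cds;Parent={tid}"
            )
            nt_before += b - a

        manifest_genes.append(
            {
                "gene_id": s.gene_id,
                "chromosome": chrom,
                "strand": s.strand,
                "exon_count": s.exon_count,
                "intron_count": s.intron_count,
                "exon_nt_lengths": [b - a for a, b in region_exons],
                "cds": cds,
                "codon_exon_ordinals": [
                    s.exon_ordinal_of_codon(i) for i in range(len(cds) // 3)
                ],
            }
        )

    fasta_lines = []
    for name, parts in zip(chrom_names, chrom_seqs):
        fasta_lines.append(f">{name}")
        seq = "".join(parts)
        for i in range(0, len(seq), 70):
            fasta_lines.append(seq[i : i + 70])

    params = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "species_label": spec.species_label,
        "n_chromosomes": spec.n_chromosomes,
        "beta0": spec.beta0,
        "beta1": spec.beta1,
        "beta2": spec.beta2,
        "gamma": spec.gamma,
        "exon_length_min": spec.exon_length_min,
        "exon_length_max": spec.exon_length_max,
    }
    return SyntheticGenome(
        fasta_text="\n".join(fasta_lines) + "\n",
        gff3_text="\n".join(gff_lines) + "\n",
        manifest=TruthManifest(params=params, genes=manifest_genes),
        species_label=spec.species_label,
    )


def paired_species(
    spec_wild: GeneratorSpec, spec_cultivated: GeneratorSpec
) -> tuple[SyntheticGenome, SyntheticGenome]:
    """Two genomes with identical exon architecture but independent codon
    draws under each spec's beta/gamma parameters.

    Both specs must agree on every structural field; the shared structure is
    seeded from ``spec_wild.seed``.
    """
    structural = (
        "n_genes", "n_chromosomes", "exon_count_weights",
        "exon_length_min", "exon_length_max", "intron_length",
    )
    for name in structural:
        if getattr(spec_wild, name) != getattr(spec_cultivated, name):
            raise ValueError(f"paired species must share {name}")
    shared = replace(spec_cultivated, seed=spec_wild.seed)
    return generate_genome(spec_wild), generate_genome(shared)
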