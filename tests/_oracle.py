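"""Independent naive oracles used to cross-check the package.

Deliberately implemented with different mechanisms than the package:
pyfaidx for sequences, a from-scratch GFF3 line walk, per-nucleotide exon
labelling, and direct textbook formulas for the statistics.
"""

from __future__ import annotations

import math
from collections import Counter

from pyfaidx import Fasta

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Standard genetic code as the classic TCAG-ordered 64-character string,
# independent of any library's table object.
_NCBIEAA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TO_AA = {
    b1 + b2 + b3: _NCBIEAA[16 * i + 4 * j + k]
    for i, b1 in enumerate("TCAG")
    for j, b2 in enumerate("TCAG")
    for k, b3 in enumerate("TCAG")
}


def synonymous_codons() -> set[str]:
    """The 59 synonymous codons, derived by family-size grouping."""
    families: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    return {c for fam in families.values() if len(fam) >= 2 for c in fam}


def naive_context_tally(cds_list):
    """Second-base and next-first-base tallies by direct string walking."""
    sc = synonymous_codons()
    nxa = {b: 0 for b in "ACGT"}
    nxg = {b: 0 for b in "ACGT"}
    ntx = {b: 0 for b in "ACGT"}
    ncx = {b: 0 for b in "ACGT"}
    for cds in cds_list:
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for i, codon in enumerate(codons[:-1]):  # stop never tallied
            if codon not in sc:
                continue
            if codon[2] == "A":
                nxa[codon[1]] += 1
            elif codon[2] == "G":
                nxg[codon[1]] += 1
            elif codon[2] == "T":
                ntx[codons[i + 1][0]] += 1
            elif codon[2] == "C":
                ncx[codons[i + 1][0]] += 1
    return nxa, nxg, ntx, ncx


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def splice_and_scan(fasta_path, gff3_path):
    """Return {gene_id: (cds_string, [exon_ordinal per codon])} using a naive
    per-nucleotide walk. The first mRNA per gene in file order is used."""
    fa = Fasta(str(fasta_path))

    mrnas_of_gene: dict[str, list[str]] = {}
    cds_rows: dict[str, list[tuple[str, int, int, str]]] = {}
    gene_order: list[str] = []
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gene_order.append(a["ID"])
                mrnas_of_gene.setdefault(a["ID"], [])
            elif ftype == "mRNA":
                mrnas_of_gene.setdefault(a["Parent"], []).append(a["ID"])
            elif ftype == "CDS":
                cds_rows.setdefault(a["Parent"], []).append((seqid, int(start), int(end), strand))

    out = {}
    for gene_id in gene_order:
        mrnas = mrnas_of_gene.get(gene_id, [])
        if not mrnas or mrnas[0] not in cds_rows:
            continue
        rows = cds_rows[mrnas[0]]
        strand = rows[0][3]
        rows = sorted(rows, key=lambda r: r[1])
        # spliced sequence plus, per nucleotide, the exon it came from
        # (exon index in transcript order)
        pieces, exon_ids = [], []
        for idx, (seqid, start, end, _s) in enumerate(rows):
            piece = str(fa[seqid][start - 1 : end]).upper()
            pieces.append(piece)
            exon_ids.extend([idx] * len(piece))
        seq = "".join(pieces)
        if strand == "-":
            seq = revcomp(seq)
            n_exons = len(rows)
            exon_ids = [n_exons - 1 - e for e in reversed(exon_ids)]

        ordinals = []
        for i in range(0, len(seq) - 2, 3):
            e1, e2, e3 = exon_ids[i], exon_ids[i + 1], exon_ids[i + 2]
            if e1 != e2:        # split between 1st and 2nd nt -> downstream
                owner = e2
            elif e2 != e3:      # split between 2nd and 3rd nt -> upstream
                owner = e2
            else:
                owner = e1
            ordinals.append(owner + 1)
        out[gene_id] = (seq, ordinals)
    return out


def codon_counter(cds_by_gene) -> Counter:
    c = Counter()
    for seq, _ in cds_by_gene.values():
        for i in range(0, len(seq) - 2, 3):
            c[seq[i : i + 3]] += 1
    return c


def welch_t(x, y):
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def chisq_2x2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
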