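from __future__ import annotations

from pathlib import Path

import pytest

from scubkit.annotation_io import GenomeSource, load_codon_records
from scubkit.synthetic_data import GeneratorSpec, generate_genome


@pytest.fixture(scope="session")
def oracle_genome(tmp_path_factory):
    """A 200-gene genome with every effect switched on, written to disk."""
    spec = GeneratorSpec(
        seed=11,
        n_genes=200,
        species_label="oracle200",
        beta0=0.4,
        beta1=0.05,
        beta2=0.8,
        gamma=1.3,
        met_trp_weight=0.5,
    )
    genome = generate_genome(spec)
    source = genome.write(tmp_path_factory.mktemp("oracle200"))
    return spec, genome, source


@pytest.fixture(scope="session")
def oracle_records(oracle_genome):
    _, _, source = oracle_genome
    records, reports = load_codon_records(source)
    return records, reports


def write_genome(tmp_path: Path, chroms: dict[str, str], gff3_body: str) -> GenomeSource:
    """Write a hand-built FASTA/GFF3 pair and return its GenomeSource."""
    fasta = tmp_path / "genome.fa"
    gff3 = tmp_path / "genome.gff3"
    with open(fasta, "w") as out:
        for name, seq in chroms.items():
            out.write(f">{name}\n{seq}\n")
    gff3.write_text("##gff-version 3\n" + gff3_body)
    return GenomeSource("handmade", fasta, gff3)
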