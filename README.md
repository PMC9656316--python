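# scubkit

Genome-wide **synonymous codon usage bias (SCUB)** analysis for annotated
genomes, with a synthetic-genome generator that makes every pipeline stage
testable offline against known ground truth.

Given a genome FASTA plus GFF3 annotation per species, scubkit:

- selects one transcript per protein-coding gene (the first mRNA in GFF3
  document order), stitches its CDS in transcript orientation and applies the
  standard sanity filters (length multiple of three, no N, ATG start,
  TAA/TAG/TGA stop);
- assigns every codon to a coding exon with the phase-aware convention
  (a codon split after its first nucleotide belongs to the downstream exon,
  after its second nucleotide to the upstream exon);
- computes per-codon frequencies, third-base (NNA/NNT/NNC/NNG) fractions,
  per-amino-acid C/G-vs-A/T usage ratios, RSCU, CAI, CBI and Wright's
  effective number of codons (Nc);
- stratifies all statistics by chromosome, by intron number (classes 0–9)
  and by exon position within genes of 2–10 coding exons (terminal vs
  internal exons);
- computes CpG-deamination sequence-context ratios: NXA/NXG keyed by the
  second codon base (the NCA/NCG antisense-strand signal), NT|X/NC|X keyed
  by the next codon's first base (the NT|G/NC|G sense-strand signal), and
  per-amino-acid A/G-ending pair ratios, all in genome-wide and stratified
  forms;
- compares species with chi-square cross-table tests, Welch t-tests and CV,
  and summarises profiles with average-linkage correlation-distance
  clustering (Newick output) and PCA score coefficients.

## Layout

| module | contents |
| --- | --- |
| `scubkit.annotation_io` | FASTA/GFF3 ingestion, transcript selection, CDS filters, codon-to-exon assignment |
| `scubkit.codon_stats` | genetic code, codon counts, SCUB frequencies, RSCU/CAI/CBI/Nc |
| `scubkit.structure_strata` | chromosome / intron-class / exon-position stratification |
| `scubkit.methylation_context` | NXA/NXG, NT|X/NC|X and amino-acid pair ratios |
| `scubkit.inference` | chi-square, t-test, CV, clustering, PCA |
| `scubkit.synthetic_data` | parameterised genome generator with truth manifest |
| `scubkit.cli_pipeline` | end-to-end runs, YAML config, click CLI |

## CLI

```bash
# generate a synthetic species (FASTA + GFF3 + truth manifest)
scubkit simulate --seed 1 --n-genes 500 --label demo --beta0 0.5 --gamma 1.5 --out sim/

# single-species stages
scubkit extract   --fasta sim/demo.fa --gff3 sim/demo.gff3 --label demo --out demo_filter.tsv
scubkit summarize --fasta sim/demo.fa --gff3 sim/demo.gff3 --label demo --out demo_tables/
scubkit stratify  --fasta sim/demo.fa --gff3 sim/demo.gff3 --label demo --out demo_tables/
scubkit context   --fasta sim/demo.fa --gff3 sim/demo.gff3 --label demo --out demo_tables/

# full multi-species run
scubkit all --config run.yaml
```

`run.yaml`:

```yaml
species:
  - {label: wild,       fasta: wild.fa,       gff3: wild.gff3}
  - {label: cultivated, fasta: cultivated.fa, gff3: cultivated.gff3}
pairs:
  - [wild, cultivated]          # ordered (wild, cultivated) contrasts
output_dir: out
options:
  include_chromosome_profiles: true
  max_intron_class: 9
  min_exon_class: 2
  max_exon_class: 10
  t_test_equal_var: false
  pca_standardize: false
  drop_final_codon_context: false
seed: 0
```

The output bundle contains, per species, the filter report, codon/RSCU/index
tables and all stratified SCUB and context tables (TSV), and across species
the chi-square contrast table, feature matrices, dendrograms (Newick) and
PCA scores, plus a machine-readable `run_manifest.json`.

## Generator model

`GeneratorSpec` controls the synthetic genomes: third-base log-odds
`beta0` (baseline C/G preference), `beta1` (per-intron shift toward A/T),
`beta2` (internal-exon A/T boost, zero at exons 1, 2 and the last, peaking
mid-gene) and `gamma` (multiplicative boost of A-ending codons after a
second-position C and of T-ending codons before a G-starting codon).
Codon sampling is two-pass — amino acids and first-two-base groups first,
third bases second — so the neighbour context is well defined at draw time.
`paired_species` builds two genomes sharing exon architecture but with
independent codon draws, emulating a wild/cultivated contrast. Output is
byte-deterministic under a fixed seed.
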