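# bivalveseq

A DNA metabarcoding toolkit for identifying bivalve species — mussels
(Mytilidae), scallops (Pectinidae) and oysters (Ostreidae) — in foods and
mixed samples, built around a ~150 bp mini-barcode of mitochondrial 16S
rDNA amplified by a seven-primer triplex PCR assay (three forward and four
reverse target-specific primers, each carrying an Illumina overhang
adapter).

It is aimed at food-authentication and molecular-ecology workflows: given a
reference FASTA plus a taxonomy table it builds the customized barcode
database (with in-silico PCR and species resolution groups), simulates
seeded paired-end mixture samples, and analyses paired FASTQ data with a
merge → primer-trim → dereplicate → classify pipeline.

## The method in brief

For a reference template *T* the triplex assay predicts a product whenever a
forward primer *f* anneals (≤ `max_mm` IUPAC-aware mismatches, none in the
3 terminal 3′ bases) and a reverse primer *r* of the same family set anneals
downstream on the opposite strand, with primer-inclusive length inside
80–300 bp. The *insert* is the interior between the primer-matched regions —
the species-diagnostic barcode. Species with byte-identical inserts are
merged into a **resolution group** reported as "*Genus* spp." (or a
slash-joined list across genera).

Reads are classified per dereplicated representative *x* against every
database insert *y* by global edit-distance identity

```
identity(x, y) = 1 − editdist(x, y) / max(|x|, |y|)
```

with the best hit winning when identity ≥ 0.97 (configurable); ties collapse
to the enclosing resolution group or shared genus. Per-sample results report
each label's read count and its percentage of the reads passing the
workflow; a component counts as *detected* at ≥ 1 % of passing reads.

## Worked example

Generate a synthetic three-family reference fixture (sequences are
generator-made; each record embeds its family's exact primer sites around a
randomized insert giving a 150 bp product), simulate the ternary
98 : 1.5 : 0.5 % mixture design at 50,000 read pairs, and analyse it:

```
bivalveseq make-fixture --outdir refs --n-per-family 1 --seed 7

printf 'species\tproportion\nMagallana gigas\t0.98\nMytilus galloprovincialis\t0.015\nPecten jacobaeus\t0.005\n' > mix.tsv
bivalveseq simulate --fasta refs/references.fasta --taxonomy refs/taxonomy.tsv \
    --mix mix.tsv --pairs 50000 --error-rate 0.001 --seed 42 --out-prefix tern
# emitted pairs: Magallana gigas=49036, Mytilus galloprovincialis=745, Pecten jacobaeus=219

bivalveseq run --r1 tern_R1.fastq --r2 tern_R2.fastq \
    --fasta refs/references.fasta --taxonomy refs/taxonomy.tsv \
    --out-report report.tsv
# tern_R1: 50000 raw pairs, 50000 passing, detected: Magallana gigas, Mytilus galloprovincialis
```

`report.tsv` then contains:

```
Sample ID  Species Identified         Total Number of Raw Reads  Total Number of Reads Passing the Workflow  Number of Reads Assigned Correctly  Percentage of Reads Assigned Correctly (%)  Detected
tern_R1    Magallana gigas            50000                      50000                                       49036                               98.07                                       True
tern_R1    Mytilus galloprovincialis  50000                      50000                                       745                                 1.49                                        True
tern_R1    Pecten jacobaeus           50000                      50000                                       219                                 0.44                                        False
```

The recovered percentages (98.07 / 1.49 / 0.44) sit within binomial sampling
noise of the specified mixing proportions (98.0 / 1.5 / 0.5); the 0.5 %
component is assigned reads but falls below the 1 % detection convention, so
its `Detected` flag is False while still being listed in the full report.

Other subcommands: `build-db` (write the database bundle: inserts FASTA,
groups TSV, load report), `insilico-pcr` (per-record product table),
`mixture-study` (simulate + analyse the packaged ternary / single-family /
off-target designs across replicates with mean rows), and `report`
(re-tabulate a per-cluster assignments TSV). All accept `--log-level`; study
and simulation commands require `--seed` and are byte-deterministic under it.

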