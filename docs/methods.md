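# Methods

## Scope and model

`bivalveseq` implements a mini-barcode metabarcoding method for three
bivalve families. The marker is a ~150 bp fragment of mitochondrial 16S
rDNA flanked by family-conserved primer binding sites; species identity is
carried entirely by the primer-free interior (the *insert*). Seven
target-specific primers form the triplex assay: one forward and two reverse
primers for Mytilidae (mussel 16S is variable enough that a single reverse
primer cannot cover the species of interest), and one forward/reverse pair
each for Pectinidae and Ostreidae. Each primer is synthesized with a
constant Illumina overhang adapter 5′ of the target-specific part; the
overhang never appears in the biological barcode and plays no role in
matching.

## In-silico PCR

Primer annealing is modelled as IUPAC-aware string matching: a template
window matches a primer position when the template base is in the primer
code's expansion. A site is accepted with at most `max_mm` mismatches
(default 2) and **no** mismatch in the 3 terminal bases at the primer 3′
end, mimicking the polymerase's intolerance of 3′-terminal mispairs. Both
defaults are configurable.

A product is any same-family (forward site, downstream reverse site) pair
whose primer-inclusive length falls in 80–300 bp. The window excludes
spurious long-range pairings while comfortably containing the designed
150 bp product; a 300-cycle (2×151) sequencing kit could not cover products
much beyond it anyway. Templates are scanned in both orientations and
products are reported in their own plus orientation (forward primer first),
so prediction is invariant under reverse-complementing the template. When a
record yields several products (e.g. both mussel reverse primers bind), all
are retained for inspection, the record is flagged ambiguous, and
downstream consumers use the shortest product — short products dominate PCR
kinetics.

Coordinates are 0-based half-open on the template plus strand throughout.

## Reference database

The loader takes any FASTA plus a tab-separated taxonomy (`accession`,
`species`, `genus`, `family`, `synonyms`). Sequences are uppercased;
records with non-IUPAC characters are rejected into a load report rather
than silently dropped. Scientific-name synonymy is normalized at load time:
a built-in table (Crassostrea gigas → Magallana gigas, Crassostrea
bilineata → Magallana bilineata, Patinopecten yessoensis → Mizuhopecten
yessoensis) is extended by the per-record `synonyms` column, and lookups
resolve either name to the accepted one.

Digestion stores each record's insert. Inserts are primer-exclusive by
design: sequencing reads have their primers trimmed before classification,
so database entries must be primer-free too (the widely quoted "150 bp
barcode" is taken as the primer-inclusive product size; the assumption is
recorded here because either convention is defensible). A record whose
insert contains N is dropped when the same species has an N-free record,
implementing a prefer-the-cleanest-reference rule.

Resolution groups are equivalence classes of species under exact insert
identity. Singletons are labelled with the species name, within-genus
groups as "*Genus* spp.", cross-genus groups as a sorted slash-joined list
(never a genus label). Species with no predicted product form a single
"non-amplifiable" class so that every species still belongs to exactly one
group. Grouping is deliberately exact-match only — near-identical inserts
remain separate species, consistent with a barcode whose diagnostic signal
can be a single substitution.

## Read simulation

The fixture generator emulates the reference panel the method needs without
any database download: per family it embeds the exact primer sites around a
uniformly random insert sized so the product is exactly 150 bp, with 30 bp
random flanks, verifying by in-silico PCR that exactly one product arises.
Mussel records alternate between the two reverse primers. Within a family,
inserts differ pairwise by at least `divergence` substitutions (default 5 —
comfortably above the classifier's resolution while far below the ~75 %
divergence of random sequences, and satisfiable for any fixture size used).
An off-target "squid-like" record with no binding sites is included, and a
duplicate mode produces two Pecten species with byte-identical inserts for
exercising genus-level collapse. Species names are real bivalve binomials
so mixture designs read naturally; every sequence is synthetic.

The simulator draws per-component read-pair counts from a multinomial over
the mixture proportions — DNA proportion maps directly to read proportion,
i.e. equal amplification efficiency across species. Real mixtures show
strong species-dependent amplification bias (observed recoveries of a 98 %
component run several points low, and within-family minors can swing an
order of magnitude); modelling that bias is out of scope, though a
per-species efficiency multiplier exists (default 1) for sensitivity
studies. Consequently, passing simulation-based tests demonstrates that the
*analysis* recovers mixing proportions under unbiased amplification, not
that wet-lab percentages would be quantitatively reproduced.

Reads are 2×151 (300-cycle kit): R1 is the amplicon 5′ prefix, R2 the
reverse complement of its 3′ end, truncated to the amplicon length (150 bp
here, so pairs overlap fully). Errors are i.i.d. per-base substitutions
(default rate 0.001, the order of the platform error measured on spike-in
controls); indels, position-dependent quality and chimeras are not
modelled, and quality strings are a constant 'I' (Q40) since the pipeline
uses quality only for overlap tie-breaking. FASTQ output plus a read-level
ground-truth table are byte-deterministic under the seed.

## Analysis pipeline

1. **Merge.** R2 is reverse-complemented and slid against R1 over every
   ungapped offset with overlap ≥ `min_overlap` (20); the offset maximizing
   matches − mismatches wins if its mismatch fraction is ≤ 0.1. Overlap
   disagreements take the higher-quality base, ties going to R1. These
   parameter defaults are this package's own choices; merging is required
   because 2×151 reads fully span a 150 bp product.
2. **Trim.** A merged read must begin with a forward primer and end with
   the reverse complement of a reverse primer of the *same* family set,
   each within `max_mm` (2) mismatches; the flipped orientation is tried
   before rejecting. Rejections are categorized (no-forward, no-reverse,
   family-conflict) and counted in the run log. The surviving interior is
   the read's insert; "reads passing the workflow" = merge + trim
   survivors, the denominator of all report percentages.
3. **Dereplicate.** Exact-identity collapse with counts (no OTU
   clustering), ordered by count then sequence for determinism.
4. **Classify.** Each representative is scored against every database
   insert by global edit-distance identity, 1 − d/max(|x|,|y|) (edlib
   backend; an exhaustive alignment rather than a seeded heuristic search,
   which at these database sizes is both simpler and exact). Below
   `min_identity` (default 0.97, the conventional species-level amplicon
   threshold) the cluster is unassigned; identity exactly at the threshold
   is assigned, which keeps the zero-error limit (identity 1, threshold 1)
   fully assigned. Tied species collapse to their resolution group when
   they share one, else to "*Genus* spp." when they share a genus, else to
   "ambiguous".

Counts are conserved at every stage (raw = passing + categorized
rejections; passing = Σ cluster counts = Σ per-label counts). Percentages
are rounded to 2 decimals; a label is *detected* at ≥ 1.0 % of passing
reads, but all labels remain listed. Identical pairs are collapsed before
merging purely as a computational shortcut — results are identical to
per-read processing because both merge and trim are pure functions.

## Mixture study designs

Packaged presets mirror the method's validation designs: the ternary
three-family mixture 98.0 : 1.5 : 0.5 % in all six role permutations;
single-family mixtures with 1.0 % minors (scallop panel of six species,
oyster panel with a scallop main component, mussel panel); and an off-target
design whose 97 % main component (squid) has no primer sites and must
surface as zero assigned reads. Study tables carry per-replicate rows plus
arithmetic means of per-replicate percentages. Replicate seeds derive
deterministically from the study seed, making whole study tables
byte-reproducible.

## Problem sizes and numerical choices

Simulated validations use 50,000 read pairs per sample — the order of the
per-sample depth the method targets on a pooled flow cell — and a 0.1 %
substitution rate; at that depth the 3-binomial-σ band on a 0.5 % component
is about ±0.09 points. The acceptance script and test suite run these sizes
directly. Tie-breaks everywhere are deterministic (lexicographic or
count-descending order); identity comparisons use a 1e-12 tolerance when
collecting ties.

## Known limitations

- No amplification-efficiency or copy-number correction: recovered read
  percentages estimate *DNA mixing proportions* only under the equal-
  efficiency assumption.
- Substitution-only error model; indels would surface as slightly lower
  identities but are not simulated.
- Exact-match dereplication and grouping; no OTU/ASV denoising stage.
- Primer QC (Wallace-rule Tm, longest self-complementary run) is advisory
  only and deliberately simple; nearest-neighbor thermodynamics are out of
  scope.
- The classifier's genus-collapse depends on the taxonomy table's species
  binomials being well-formed (genus = first token).
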