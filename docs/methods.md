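# Methods

## Scope and model

The pipeline quantifies mature-miRNA expression from small-RNA
sequencing libraries in a design with **one pooled library per
condition** and no biological replicates. All statistics are therefore
descriptive: a differential-expression "call" is a thresholded log2
fold change, not a hypothesis test, and no p-values or dispersion
estimates exist anywhere in the package. Analyses that need replicate
variance (edgeR/DESeq-style inference) are intentionally out of scope.

The unit of quantification is the **tag**: a unique clean-read sequence
with a non-negative count in each library. Every downstream quantity —
TPM, fold change, representative-group sums — is a function of the tag
count table and the per-library clean-read totals.

## Read cleaning

A read is cleaned in three ordered steps, and lands in exactly one
accounting bucket so that `raw = clean + discarded` per library:

1. **3′ adapter trimming.** The leftmost occurrence of an adapter prefix
   with ≥ 7 nt overlap is removed; overlaps of 7–9 nt must match
   exactly, overlaps ≥ 10 nt tolerate one mismatch. Reads without a
   detectable adapter are kept by default (they may be full-length
   inserts); `require_adapter=True` discards them instead.
2. **Quality.** Mean PHRED over the trimmed insert ≥ 20 (inclusive;
   PHRED+33 fixed, no offset autodetection). An empty insert fails.
3. **Length.** 18 ≤ insert length ≤ 35 nt, both bounds inclusive.

Mean-quality filtering rather than sliding-window trimming is the
simplest defensible reading of "remove low-quality reads"; the stats
ledger makes the policy auditable for any input.

## Catalog matching

A tag is assigned to at most one mature miRNA. Every ungapped placement
of the tag on every mature with 5′/3′ end offsets in [−2, +2] is scored
exhaustively (catalogs are a few hundred entries; no seed-and-extend
heuristics are needed, and exhaustive search makes results exactly
reproducible). Mismatches are Hamming distance over the overlapping
positions; tag bases overhanging the mature are validated against the
precursor when one is available and otherwise each count as a mismatch —
a deliberately skeptical treatment of unverifiable extensions. The
overlap must cover at least (mature length − 2) positions. The best hit
minimizes `(mismatches, |off5| + |off3|, name)`; the lexicographic name
tie-break makes multi-catalog-hit assignment deterministic, which the
source experiment left unspecified. Mismatch budget is 0 or 2 (the two
policies of the original search).

## Category classification

A tag is assigned to exactly one ncRNA category by fixed precedence —
miRNA, mt, cp, rRNA, tRNA, snRNA, snoRNA, lncRNA, mRNA, repeats,
unclassified — where a category applies when any exact genome hit
overlaps one of its annotation intervals by at least half the tag
length. A catalog match wins outright. The original study's published
category table does not sum to 100%, i.e. its classifier was not a
strict partition; this implementation partitions (categories are
disjoint by construction), which is the relevant difference to keep in
mind when comparing composition tables.

## Quantification and DE calls

`TPM = 10^6 · raw / clean_total`; row TPMs of a library sum to 10^6
exactly. Fold change is `log2((TPM_t + p) / (TPM_c + p))` with
pseudocount `p = 1 TPM` on both sides. The published analysis is silent
on zero handling while printing finite fold changes throughout; the
pseudocount is the package's choice, surfaced as a parameter
(`pseudo`) in every API and report so sensitivity to p ∈ {0.1, 1, 10}
can be checked directly. Calls: **up** iff FC ≥ 1, **down** iff
FC ≤ −1 (inclusive, as the thresholds are printed), **low_count** when
the raw count fails to reach 50 in every library; the floor is
evaluated across all libraries once per row, keeping a row that is
well-measured anywhere.

## Representative grouping

Mature anchors of the same family merge when their sequences are within
the end-offset rule of each other (some zero-mismatch ungapped placement
with both end offsets ≤ 2 nt, checked in both orientations and closed
transitively by union-find). Merging across families is forbidden, so
paralogs with similar sequences but different family labels never
conflate. Group names concatenate the sorted variant letters
(miR167c/d/e/g → miR167cdeg). Tags join the merged anchor set of their
best hit; group counts are member sums per library, and group fold
change is recomputed from those pooled counts — never averaged over
member-level fold changes, which would weight members incorrectly. The
group's reported anchor sequence is its most abundant member, ties
broken lexicographically. Polymorphic (internal-mismatch) hits stay as
separate rows flagged by their mismatch count; they are matched but not
silently merged into the zero-mismatch group.

## Cross-condition analysis

The responsive set is the rows with |FC| ≥ 1 in at least one column.
Directional two-column overlaps partition rows into eight disjoint sets
(both up, both down, discordant, four exclusive sets, neither) that
always sum to the row total. "Attenuated" under alternated stress has
no quantitative definition in the source study; here it is operational:
same sign, regulated under the single stress, and smaller in magnitude
under the alternated treatment; "lost" additionally means the
alternated response falls below the threshold. Overlap analysis runs on
representative groups by default and on raw sequences when given a
sequence-level matrix — both granularities occur in practice.

## Organelle hotspots

Tags are exact-mapped to the mitochondrial and plastid contigs;
overlapping hit intervals merge into maximal regions reported with
span, summed member-tag TPM, and tag count, sorted by TPM. Strand is
ignored in reporting (a hotspot is a genomic interval). Note that with
many diffuse organelle reads, merged regions can grow large; the
TPM threshold, not the span, is the filter.

## Bench formulas

RWC = 100 × (fresh − dry)/(turgid − dry) from leaf-section weights.
STC = Σ(treated lengths + dry weights) / Σ(control lengths + dry
weights) — the formula literally adds lengths (cm) and masses (g) into
one scalar per group, so units are mixed by construction; that is the
coefficient as defined, documented rather than "fixed". Columns can be
restricted to shoots, roots, or both. ΔΔCt uses a single reference
assay: 2^−((Ct_tgt − Ct_ref)_treat − (Ct_tgt − Ct_ref)_ctrl);
multi-reference geometric-mean normalization and amplification-
efficiency (Pfaffl) correction are not implemented.

## Synthetic data

`make_reference` plants each precursor (15-nt flanks around a 21-nt
mature) once in a toy nuclear genome, gives every background category
two disjoint 300-nt intervals, records inter-feature spacers as
intergenic source regions, and builds 2-kb mt/cp contigs carrying the
configured hotspot regions (defaults: a 53-bp mitochondrial and a 32-bp
plastid region, echoing the NADH-dehydrogenase-subunit-2 and trnF
small-RNA signatures).

`simulate_library` draws one multinomial per library at the configured
depth. Each miRNA's expected fraction is `baseline × 2^trueFC`
(baseline = miRNA fraction / n), hotspots contribute `TPM / 10^6`, and
the background categories are rescaled to absorb the miRNA weight shift
so the total is 1. This makes the treatment/control TPM ratio an
unbiased estimator of the configured truth; a plain renormalized
multinomial would bias every estimate by the library-total shift, which
would contaminate parameter-recovery checks with a composition artifact.
If strong upregulation leaves no mass for the background, the
configuration errors out rather than silently renormalizing.

miRNA reads are positional variants cut from the precursor according to
the isomiR offset profile (default 60% exact mature, 28% ±1 nt, 12%
±2 nt, single-ended; the real plant isomiR offset distribution is not
well characterized and this symmetric default is arbitrary). Background
reads come from category intervals with a length profile whose mode is
24 nt — the siRNA-dominated size peak of plant libraries — on either
strand. The 3′ adapter (default `TGGAATTCTCGGGTGCCAAGG`, the standard
small-RNA adapter; the source experiment's linker sequence is not
public) is appended, then reads are padded with random bases or
truncated to a uniform 50-nt raw length. Qualities are constant Q40:
quality filtering is not the object of study.

**What the generator does not emulate:** sequencing errors, 5′ adapter
read-through, PCR duplicates, replicate-level overdispersion (the
design has none to mirror), hairpin secondary structure, and
expression-dependent isomiR profiles. Passing tests therefore
demonstrate the correctness of the analysis chain on idealized
libraries, not robustness to platform artifacts.

### Default composition

The default library is composition-realistic: 3% miRNA, with repeats
(18%) the largest annotated class and 66% unannotated intergenic
genome, loosely matching published plant shoot libraries. Depth
defaults to 10^5 reads per library — large enough for the conservation
and composition invariants (3σ binomial checks) while keeping a full
simulated study in seconds.

### The recovery benchmark

`recovery_scenario(seed)` fixes 20 miRNAs, depth 10^5, and true log2
fold changes in {−3, −1, 0, 1, 3} at multiplicities (2, 5, 8, 4, 1) —
downregulation-dominated, as plant submergence responses are. The miRNA
fraction is 0.70, chosen by a power computation: the benchmark's
tolerance of ±0.2 log2 units is meant to be three sigma of pure
counting noise, and at the strongest depletion (baseline 3500 reads per
miRNA, ~437 after 8-fold depletion) the binomial standard error of the
log ratio is ≈ 0.073, i.e. 3σ ≈ 0.22. At the composition-realistic 3%
miRNA fraction the same depth gives 3σ > 0.5, so fold-change recovery
to ±0.2 is not resolvable there; the benchmark deliberately enriches
the miRNA signal to isolate the quantification chain from composition
realism, which the default profile covers separately.

## Numerical choices

- Coordinates are 0-based half-open with explicit strand throughout.
- Table floats print with two decimals, halves rounded away from zero
  (−4.385 → −4.39), matching conventional table precision.
- Percentages are 100 × reads/clean rounded to two decimals and always
  recomputed from counts, never stored.
- All tie-breaks (catalog hits, group anchors, hotspot ordering) are
  lexicographic after the primary criteria, so every output is
  deterministic for a given input and seed.
- Degenerate inputs error loudly: zero clean reads (percentages
  undefined), zero control sums (STC), turgid = dry (RWC),
  non-positive pseudocounts and thresholds.

## Known limitations

- Exact substring search over toy-scale references; for a real genome
  the mapping step would be replaced by an external aligner feeding the
  same `GenomeHit` interface.
- The catalog matcher is exhaustive and Python-level; fine for
  catalog-scale search (hundreds of matures), not for genome-scale
  discovery.
- Novel-miRNA discovery (hairpin folding, precursor read-distribution
  checks) and target prediction are out of scope.
- Fig-2-style overlap percentages depend on denominators that published
  analyses often leave implicit; this package reports counts and leaves
  denominators explicit in its outputs.
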