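# Methods

## Scope and model

`argskew` analyzes somatic single-nucleotide substitutions at codon
resolution, with the arginine codon family as the instance of interest. The
analysis has four layers: (i) pure genetic-code combinatorics (what *can*
happen to a codon family), (ii) codon-level annotation of observed genomic
point mutations (what *did* happen), (iii) frequency tables comparing
observed spectra with controls, and (iv) a thresholded scan for genes whose
arginine substitutions are dominated by one target residue. Only
single-base substitutions are modeled; indels, MNVs, splice effects and
transcript-isoform choice are out of scope (the first gene model per symbol
wins, with a warning).

The standard genetic code (DNA alphabet, uppercase) is hard-coded once in
`genetic_code.py` and is the package's single source of truth; human somatic
data never needs an alternative code. In tests, biopython's translator is
the independent oracle against this table, never the implementation.

Functional classification follows the usual rules: synonymous iff the
residue is unchanged; nonsense iff a sense codon gains a stop; everything
else — including the rare stop-loss case, which only arises when synthetic
minus-strand partner CDSs contain internal stops — is counted as missense.

## Coordinates and strand

All coordinates are 1-based inclusive, matching both COSMIC exports and
GFF3. Mutation records carry plus-strand alleles; annotated events are
coding-strand. Strand conversion (complementing the alleles and reading the
codon as a reverse complement) happens in exactly one place,
`annotate_record`, which prevents double-complement bugs. A codon split by
an intron is represented as two genomic sub-ranges; the phase attribute of
the transcription-first CDS feature anchors the reading frame, and CDS
lengths not divisible by three after phase trimming are truncated with a
warning. Positions inside a CDS interval but outside a complete codon
(phase-trimmed bases) are routed to the non-coding stream, like intronic and
intergenic positions: every input row ends up annotated, counted as a
reference mismatch, or non-coding, and the three counts always sum to the
input size. Reference mismatches are excluded and counted rather than
fatal, mirroring tolerant batch processing of heterogeneous catalogue rows.

## Counting conventions

* The counting unit is the mutation record after de-duplication on
  (sample, chromosome, position, mutant allele); catalogues can list one
  mutation in several rows, and de-duplication is the conservative choice.
* Figure-facing spectra default to **coding-strand** orientation (so a
  CGG→TGG tryptophan event reads C>T regardless of the gene's genomic
  strand); genomic orientation is available by flag and is used wherever
  non-coding records, which have no reading frame, must be compared with
  coding streams (strand spectra, transition enrichment, the non-coding
  control).
* The transition-enrichment table reports both the {C>T, G>A} aggregate and
  the all-transitions aggregate, since either reading answers a slightly
  different question about transition load.
* In the coding control, a record's category is the residue it *produced*
  (alt residue for missense, the unchanged residue for silent); nonsense
  records produce no residue and are tallied in a separate `stop` category.
* Percentages are kept at full precision internally and rounded to two
  decimals only at serialization.

## Skew criteria

A gene is skewed when its dominant target residue accounts for ≥ 60%
(inclusive) of its missense arginine substitutions and ≥ 40 distinct
samples carry the dominant substitution. Synonymous and nonsense records
are excluded from the denominator: neither produces an amino acid. The
sample threshold is applied to samples carrying the *dominant* change
("contributing to this skew"); the count of samples with any missense
arginine substitution is also reported for the alternative reading. Exact
residue ties can never satisfy the 60% rule (two residues at ≥ 60% each
would exceed 100%), so tied genes are reported non-skewed with the
lexicographically first residue for determinism; nucleotide-change ties
break the same way and are flagged.

## Synthetic studies

The generator emits a complete seeded study (FASTA, GFF3, CSV, JSON truth
manifest). Defaults describe a desk-scale cohort: 24 genes of 120 codons on
two chromosomes, half on the minus strand, 400 samples with
Poisson-distributed mutation counts (mean 15, the simplest stated count
model), 25% of records non-coding, and a 12-channel signature with C>T and
G>A at 28% each, the other transitions at 6% and transversions at 4% — the
qualitative shape of pan-cancer spectra, where the two deamination-driven
transitions dominate. Arginine codons are seeded into gene bodies at
fraction 0.15 with usage weights 20/20/10/20/20/10 for
AGA/AGG/CGA/CGC/CGG/CGT, the qualitative human pattern (four common codons
near 20%, CGA and CGT near 10%); exact published usage tables are
deliberately not redistributed.

Construction guarantees, each load-bearing for the test suite:

* every record's wild-type allele matches the reference (zero mismatches
  downstream);
* (sample, chromosome, position, alt) keys are unique by bounded
  resampling, so de-duplication is a no-op and manifest counts equal
  pipeline counts exactly;
* background mutations are drawn channel-first from the signature and
  placed uniformly among plus-strand-base-matching sites, so channel
  frequencies are recoverable with plain binomial error bars;
* background placement skips genes named in `skew_specs`, making each
  injected dominant fraction construction-exact: `n_carriers` distinct
  samples receive the specific codon change yielding the target residue,
  topped up with ⌊n·(1−f)/f⌋ non-target missense arginine changes;
* terminal stop codons are not mutagenized, and a skew spec naming a
  residue unreachable from the gene's arginine codons fails loudly with
  the reachable set.

`strand_paired=True` emits genes in +/− pairs whose plus-strand genomic
sequence is identical (the minus partner's CDS is the reverse complement of
the plus partner's). This makes the mutable-site composition of the two
strand groups exactly equal, which is the clean null for strand-bias
checks: with unpaired random genes the expected C>T count ratio between
strand groups is the ratio of their C-site counts, not 1, and composition
noise would be mistaken for strand bias.

What the generator does **not** emulate: trinucleotide (96-channel)
context, tissue-specific signatures, realistic human gene structure or
length distributions, germline polymorphism, sequencing error, or selection
dynamics. Passing tests therefore demonstrate correctness of the
bookkeeping and detection machinery under known ground truth — not that
real-catalogue percentages will take any particular value.

## Numerical and testing choices

Sampled-quantity checks use 3-standard-error bands from the exact binomial
or multinomial oracle at stated sizes: signature recovery at n ≈ 100,000
records, codon-usage recovery at ≈ 10,000 arginine codons, strand balance on
the paired-gene null. Annotation is validated against a brute-force oracle
that re-extracts and translates the whole wild-type and mutant CDS with
biopython and diffs the proteins — 1,000 random mutations across 100 random
±strand genes with intron-split codons. Skew detection is characterized
over 20 seeded replicates (two injected skews at fraction 0.8 with 60
carriers among 20 background genes of ~120 records each, uniform signature,
arginine fraction 0.3 so every codon sub-family is present); the 60%/40
thresholds are probed exactly at 59%/60% and 39/40 carriers. These problem
sizes keep the full suite under ten seconds on one CPU while leaving the
statistical bands meaningfully narrow.

## Known limitations

* One transcript per gene symbol; no isoform-aware annotation.
* The annotator is row-at-a-time Python; ~100k records annotate in a few
  seconds, but catalogue-scale runs (tens of millions of rows) would want a
  vectorized or chunked path.
* The skew scan is a threshold rule, not a significance test; no multiple-
  testing machinery is attached, matching its intended use as a screen.
* Protein-change strings are parsed only in the simple `p.R132H` / `p.R7=`
  forms; anything else is ignored rather than validated.
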