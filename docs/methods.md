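# Methods

## The curation model

`coiref` treats reference-collection building as a fixed sequence of pure
per-record gates followed by integration steps. Each record carries an
ordered audit trail (stage → pass/fail/skipped → detail), and a record is
kept iff no stage fails; because every gate is a pure predicate of the
record, the outcome is independent of stage order — only the audit trail
and the "first failing stage" label depend on it. The fixed order is:

1. **length** — inclusive window, default 100–60 000 nt. The lower bound
   excludes primer artifacts and uninformative fragments; the upper bound
   excludes nuclear genomes and scaffolds while keeping the longest known
   mitogenomes. Applied to both sources by default (`apply_length_to`
   switches to flat-file records only).
2. **hmm** — six-frame conceptual translation under the record's
   mitochondrial genetic code, then plan7-lite local Viterbi of every frame
   against the marker profile; the best frame wins, ties broken in frame
   order (+1, +2, +3, −1, −2, −3). Translation proceeds *through* stop
   codons: localizing the coding region is the profile's job, and the stop
   filter later inspects only the matched envelope. Codons containing any
   non-ACGT symbol translate to `X`.
3. **tc** — accept iff the best bit score reaches the profile's trusted
   cutoff (inclusive, matching `hmmsearch --cut_tc` semantics). TC applies
   to the best single frame's best alignment, not to summed domains.
4. **annotation** (flat-file records only) — the CDS with maximal overlap
   against the HMM footprint decides: pseudogene-tagged → reject; overlap
   fraction ≥ 0.80 (inclusive; denominator = CDS sites, numerator = CDS ∩
   footprint, both as unions of 0-based half-open spans) → keep. Records
   without any CDS annotation follow `no_cds_policy` (default: keep on HMM
   evidence — the conservative reading when annotation is simply absent;
   set to `reject` to require annotation). Strand is deliberately ignored:
   the comparison is positional. Gene/product labels of every
   profile-consistent feature are harvested as marker-name synonyms.
5. **contamination** — optional; consumes a precomputed BLAST outfmt-6
   table (the similarity search itself is out of scope and skippable), and
   rejects iff the best hit by bit score has an ancestor among the reject
   clades (default Bacteria, Archaea, Viridiplantae). Queries with no hit,
   or hits that cannot be placed in the taxonomy, pass — the screen only
   rejects what it can classify.
6. **internal_n** — maximal terminal `N` runs are trimmed (the trimmed
   sequence is what gets written out) and records with more than five
   remaining `N`s are rejected. Other IUPAC ambiguity codes are not
   counted.
7. **stop_codon** — reject iff `*` occurs inside the matched peptide
   envelope (`stop_check_scope=full_frame` widens this to the whole frame).

Integration joins curated sets on versionless accessions (ENA sequence and
features take precedence for shared records, BOLD fills missing metadata);
taxonomy resolution prefers `accession2taxid`, then the flat file's own
`taxon:` cross-reference, then the lowest-rank BOLD name resolvable in the
reference; homonyms are disambiguated by requiring an ancestor consistent
with the record's higher ranks, otherwise the taxid stays `NA`. Only nodes
whose rank label is literally one of the seven canonical ranks fill a
lineage slot (no promotion of e.g. subfamily), and "kingdom" is the NCBI
rank of that name (Metazoa for animals).

## The profile scorer

The built-in scorer is a local Viterbi over plan7 states (B, M, I, D, E)
in bit space:

- match/insert emissions are log-odds bits against the standard Swiss-Prot
  amino-acid background (insert emissions in practice equal the background,
  i.e. 0 bits); residues outside the 20-letter alphabet (`X`, `*`)
  contribute 0 bits (background-neutral);
- transitions are log₂ of the profile's transition probabilities;
- local entry into any match state costs log₂(2/(M(M+1))) — the classic
  uniform entry distribution — and exit is free.

There are no MSV/bias heuristics, no forward scores and no E-values: the
trusted-cutoff gate is a plain bit-score comparison, which is all it needs.
The dynamic program is exact; the test suite verifies it against exhaustive
path enumeration on 1000 random toy instances (M ≤ 3, peptide ≤ 4) with
zero deviation. HMMER itself parameterizes local entry/exit differently
(occupancy-weighted entry, per-node exit), so its scores differ by a few
percent on strong hits; the cross-backend tests therefore assert band
agreement (< 15 % relative on an ~800-bit hit) and identical trusted-cutoff
verdicts rather than score equality. An `hmmsearch --domtblout` file can be
parsed into the same hit representation (best domain per query; frame
recovered from a `record/+2`-style sequence-name convention).

## The synthetic corpus

The generator emulates the *shape* of real inputs, not their biology. Each
planted record is a codon-level construction: a coding block that
reverse-translates the toy profile's consensus (match emission 0.9,
alternatives uniform; trusted cutoff 34 bits, the value curated COI
profiles carry) flanked by glycine codons whose residues score strongly
negative everywhere in the model. This makes the optimal alignment
envelope *provably* the planted block — extending it in either direction
strictly decreases the score — so CDS/footprint overlap fractions are
exact by construction (the overlap-violation class plants a CDS sharing
479/600 sites, one site below the 80 % threshold). Codons are drawn only
from those whose translation agrees across NCBI tables 1, 2 and 5, so the
same construction is valid for records under either mitochondrial code; a
quarter of clean records are reverse-complemented to exercise the reverse
frames. The toy profile has M = 200 (600 nt coding blocks) and clean
records centre on 658 nt, the canonical barcode amplicon length, which
also fixes the expected length mode. Default corpus: 20 ENA + 20 BOLD
records with half the smaller side shared, one record per violation class,
the rest clean. Everything is a pure function of (seed, params) and
regenerates byte-identically.

What the corpus does **not** emulate: real sequence diversity (flanks are
homopolymeric codon repeats, coding blocks are near-consensus), weak true
positives near the trusted cutoff, partial or frameshifted CDS annotation,
indel-rich alignments, and real taxonomies' depth and homonymy. Passing
the end-to-end tests therefore demonstrates that the gates, bookkeeping
and integration are correct, not that the thresholds are well calibrated
for any particular clade.

## Numerical and formatting choices

- Coordinates: flat-file locations (1-based inclusive, `join`,
  `complement`, partial markers `<`/`>`) convert once on ingest to 0-based
  half-open spans; `join` becomes multiple spans of one feature and overlap
  arithmetic uses their union.
- Accessions are stored versionless, which is what makes the
  cross-database join and the `accession2taxid` lookup stable.
- Percentage rounding is explicit per report (`half_up` default,
  `truncate` available) because published tables mix both conventions;
  decimal-degree coordinates are formatted at 4 decimal places and
  round-trip stably at that precision; S/W hemispheres are negative; DMS
  converts as deg + min/60 + sec/3600; out-of-range coordinates become
  `NA`, never an exception.
- Collection dates: `DD-MMM-YYYY`, `YYYY-MM-DD` and bare `YYYY` are
  accepted; two-digit years are rejected as ambiguous; the year is salvaged
  from a calendar-invalid complete date.
- Length-histogram mode ties break to the smaller length; merge keeps the
  first record of an intra-source duplicate id with a warning; unresolved
  anything is the string `NA` in the output TSV.
- In the Viterbi DP, log(0) transitions are replaced by −10³⁰ rather than
  −∞ to keep the delete-chain prefix-scan NaN-free; an empty peptide scores
  −∞ with no envelope.

## Problem sizes

The test suite runs five end-to-end seeds at the default corpus size
(30 distinct records each) plus all unit and property tests in about half
a minute. The acceptance script builds one 150-record corpus and two
default corpora (210 records, ~25 s total) — sizes chosen so the whole
verification cycle stays interactive while every violation class and both
sources are exercised at each seed.

## Known limitations

- The HMM footprint and stop-codon envelope are computed on the untrimmed
  sequence; coordinates are not re-derived after terminal-N trimming (the
  trimmed output sequence differs from the scored one only in terminal Ns).
- The built-in scorer is uni-hit: a record whose marker region is split
  into two distant domains scores only the better one.
- BOLD name resolution consults scientific names only; taxonomic synonyms
  in the reference are deliberately ignored to avoid homonym explosions,
  at the cost of labeling some resolvable names `NA`.
- The contamination stage classifies only the single best hit; a
  near-tied metazoan/bacterial pair is decided by bit score alone.
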