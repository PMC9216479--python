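# coiref

Builder for curated reference collections of animal **COI** barcodes
(mitochondrial cytochrome c oxidase subunit I — the standard DNA barcode
marker for metazoans). DNA-barcoding and metabarcoding pipelines assign
taxonomy by comparing reads against a reference collection; the quality of
every downstream assignment rests on how those references were screened,
deduplicated and labeled. `coiref` implements that curation workflow as a
reusable library plus a thin command line:

- **ingest** ENA-style EMBL flat files (with feature tables) and BOLD-style
  specimen/sequence TSV dumps;
- **screen sequences**: length window 100 bp–60 kbp, six-frame conceptual
  translation under each record's mitochondrial genetic code (from the NCBI
  taxdump), profile-HMM search of all frames with acceptance at the
  profile's trusted cutoff (TC, the HMMER `--cut_tc` gate), a ≥ 80 %
  overlap requirement between the annotated CDS and the HMM footprint for
  flat-file records, pseudogene rejection, terminal-N trimming with at most
  five internal `N`s, no stop codon inside the matched envelope, and an
  optional contamination screen over a precomputed `blastn` tabular result
  (best hit under Bacteria/Archaea/Viridiplantae rejects);
- **integrate**: merge the two sources, dereplicate on versionless INSDC
  accessions (BOLD records without an accession keep their process ID), and
  label provenance (unique to either source, or shared);
- **harmonize taxonomy** to the seven-rank NCBI backbone (kingdom …
  species) via `accession2taxid` or lowest-resolvable-name lookup, keeping
  unknown names verbatim with taxid `NA` and reporting every updated BOLD
  classification;
- **normalize metadata**: nine fields per record, including decimal-degree
  coordinates and ISO collection dates;
- **emit** FASTA + taxonomy/metadata TSV, a marker-name synonym list
  harvested from profile-consistent `gene`/`product` labels, a taxonomy
  update table, a rejection report with the failing stage per record, and
  summary statistics (provenance split, per-phylum composition, length
  histogram).

The profile search is a self-contained "plan7-lite" **local Viterbi** over
the classic match/insert/delete profile architecture, scored in bits
against the standard amino-acid background with uniform local entry/exit —
a deterministic, dependency-free stand-alone scorer whose gate is exactly
the bit-score threshold that the trusted cutoff defines. Output from an
external `hmmsearch --domtblout` run can be parsed and used
interchangeably. A deterministic synthetic-corpus generator
(`coiref.fixtures`) produces dialect-faithful miniature inputs with a
ground-truth manifest for every quality-violation class, and is what the
test suite and the acceptance script build on.

## Worked example

```bash
python examples/01_build_collection.py
```

```
input records: 30  (ENA + BOLD, 10 shared accessions)
kept after curation: 22
provenance split: {'BOLD_unique': 10, 'ENA_unique': 2, 'BOTH': 10}
rejections by stage:
  ACC420011: failed at 'contamination'
  ACC420012: failed at 'annotation'
  ACC420013: failed at 'tc'
  ...
most frequent sequence length: 658 nt
marker-name synonyms harvested from ENA feature tables: ['CO1', 'COI', 'COX1', 'cox1', 'cytochrome c oxidase subunit I', 'cytochrome oxidase subunit 1']
```

Thirty synthetic records go in; every planted violation (a 99 nt fragment,
a non-coding sequence below the trusted cutoff, a CDS sharing only 479/600
sites with the HMM footprint, a pseudogene, six internal Ns, an in-frame
stop, a bacterial best BLAST hit) is rejected at exactly the stage that
screens for it, and the surviving records split into source-unique and
shared provenance classes. The length mode lands on 658 nt, the canonical
animal barcode amplicon. `examples/02_profile_screen.py`,
`03_taxonomy_harmonization.py` and `04_summaries.py` demonstrate the
frame-level profile search, the three taxonomy-resolution paths and the
summary tables.

The same run is available from the shell:

```bash
coiref fixtures --seed 42 --outdir corpus
coiref build --config corpus/config.yaml --output-dir corpus/out
coiref summarize --collection-tsv corpus/out/collection.tsv
```

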