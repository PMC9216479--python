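"""Deterministic synthetic-corpus generator with ground truth.

Emits a miniature but dialect-faithful copy of every input the pipeline
reads — EMBL flat file, BOLD TSV, HMMER3/f profile, NCBI taxdump, an
accession2taxid mapping and a BLAST tabular file — together with a manifest
stating, per record, the expected curation verdict and failing stage, plus
the expected provenance counts, synonym list, taxonomy-update count and
length mode. Everything is a pure function of (seed, params): regenerating
with the same seed reproduces the corpus byte-identically.

Planted sequences are concatenations of codons: a "coding" block that
reverse-translates the profile's consensus peptide (scoring far above the
trusted cutoff by construction) framed by glycine-codon flanks whose
residues score strongly negative, so the profile footprint is exactly the
planted block. Violation classes perturb one aspect each: length bounds,
a non-coding sequence (below TC), a CDS annotation shifted to 479/600
overlap, a pseudogene tag, six internal Ns, an in-frame stop codon, a
bacterial best BLAST hit, an unknown taxonomy path, and an outdated BOLD
family name.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .profile_search import AMINO_ALPHABET, AMINO_BACKGROUND
from .translation import CODONS, GeneticCode, reverse_complement

__all__ = ["CorpusParams", "CorpusManifest", "RecordPlan", "generate_corpus", "VIOLATION_CLASSES"]

# ---------------------------------------------------------------------------
# static reference data

#: (taxid, parent, rank, name, mitochondrial genetic code [0 = inherit])
_TAX_NODES = [
    (1, 1, "no rank", "root", 0),
    (131567, 1, "no rank", "cellular organisms", 0),
    (2, 131567, "superkingdom", "Bacteria", 0),
    (2157, 131567, "superkingdom", "Archaea", 0),
    (2759, 131567, "superkingdom", "Eukaryota", 1),
    (33090, 2759, "kingdom", "Viridiplantae", 1),
    (33208, 2759, "kingdom", "Metazoa", 5),
    # Arthropoda
    (6656, 33208, "phylum", "Arthropoda", 0),
    (50557, 6656, "class", "Insecta", 0),
    (7147, 50557, "order", "Diptera", 0),
    (7214, 7147, "family", "Drosophilidae", 0),
    (7215, 7214, "genus", "Drosophila", 0),
    (7227, 7215, "species", "Drosophila melanogaster", 0),
    (7399, 50557, "order", "Hymenoptera", 0),
    (7458, 7399, "family", "Apidae", 0),
    (7459, 7458, "genus", "Apis", 0),
    (7460, 7459, "species", "Apis mellifera", 0),
    (6854, 6656, "class", "Arachnida", 0),
    (6893, 6854, "order", "Araneae", 0),
    (74881, 6893, "family", "Salticidae", 0),
    (900001, 74881, "genus", "Salticus", 0),
    (900002, 900001, "species", "Salticus scenicus", 0),
    # Chordata (vertebrate mitochondrial code)
    (7711, 33208, "phylum", "Chordata", 2),
    (186623, 7711, "class", "Actinopteri", 0),
    (7952, 186623, "order", "Cypriniformes", 0),
    (7953, 7952, "family", "Cyprinidae", 0),
    (7954, 7953, "genus", "Danio", 0),
    (7955, 7954, "species", "Danio rerio", 0),
    # Mollusca
    (6447, 33208, "phylum", "Mollusca", 0),
    (6448, 6447, "class", "Gastropoda", 0),
    (6527, 6448, "order", "Stylommatophora", 0),
    (6531, 6527, "family", "Helicidae", 0),
    (6532, 6531, "genus", "Helix", 0),
    (6536, 6532, "species", "Helix pomatia", 0),
    # a bacterial chain for the contamination screen
    (1224, 2, "phylum", "Pseudomonadota", 0),
    (1236, 1224, "class", "Gammaproteobacteria", 0),
    (91347, 1236, "order", "Enterobacterales", 0),
    (543, 91347, "family", "Enterobacteriaceae", 0),
    (561, 543, "genus", "Escherichia", 0),
    (562, 561, "species", "Escherichia coli", 0),
]

_RANK_CHAIN = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: species available to planted records: (species taxid, lineage names)
_SPECIES_POOL = (7227, 7460, 900002, 7955, 6536)

_GENE_LABELS = ("COI", "COX1", "cox1", "CO1")
_PRODUCT_LABELS = (
    "cytochrome c oxidase subunit I",
    "cytochrome oxidase subunit 1",
)

VIOLATION_CLASSES = (
    "too_short",
    "too_long",
    "low_hmm",
    "cds_overlap_79",
    "pseudogene",
    "internal_n",
    "internal_stop",
    "bacterial_hit",
    "unknown_taxon",
    "changed_name",
)

#: classes only expressible on one source
_ENA_ONLY = {"cds_overlap_79", "pseudogene", "too_long"}
_BOLD_ONLY = {"unknown_taxon", "changed_name"}

_CLASS_STAGE = {
    "clean": None,
    "too_short": "length",
    "too_long": "length",
    "low_hmm": "tc",
    "cds_overlap_79": "annotation",
    "pseudogene": "annotation",
    "internal_n": "internal_n",
    "internal_stop": "stop_codon",
    "bacterial_hit": "contamination",
    "unknown_taxon": None,
    "changed_name": None,
}

_UNKNOWN_LINEAGE = {
    "kingdom": "Metazoa",
    "phylum": "Imaginophora",
    "class": "Imaginea",
    "order": "Imaginales",
    "family": "Imaginidae",
    "genus": "Imaginarius",
    "species": "Imaginarius nonexistens",
}

_MODEL_LENGTH = 200          # profile nodes -> 600 nt planted coding block
_CODING_NT = 3 * _MODEL_LENGTH
_TRUSTED_CUTOFF = 34.0


def _lineage_names(taxid: int) -> dict[str, str]:
    parent = {t: p for t, p, *_ in _TAX_NODES}
    rank = {t: r for t, _, r, *_ in _TAX_NODES}
    name = {t: n for t, _, _, n, _ in _TAX_NODES}
    out: dict[str, str] = {}
    t = taxid
    while True:
        if rank[t] in _RANK_CHAIN:
            out[rank[t]] = name[t]
        if parent[t] == t:
            break
        t = parent[t]
    return out


def _safe_codon_table() -> dict[str, list[str]]:
    """Codons whose translation agrees across NCBI tables 1, 2 and 5."""
    tables = [GeneticCode.from_table_id(i) for i in (1, 2, 5)]
    safe: dict[str, list[str]] = {}
    for codon in CODONS:
        aas = {t.codon_to_aa[codon] for t in tables}
        if len(aas) == 1:
            safe.setdefault(aas.pop(), []).append(codon)
    return safe


# ---------------------------------------------------------------------------
# parameters / manifest


@dataclass
class CorpusParams:
    """Corpus shape. ``overlap_fraction`` of min(n_ena, n_bold) records are
    shared between the sources (same accession on both sides)."""

    n_ena: int = 20
    n_bold: int = 20
    overlap_fraction: float = 0.5
    violation_mix: dict[str, int] = field(
        default_factory=lambda: {c: 1 for c in VIOLATION_CLASSES}
    )

    @property
    def n_shared(self) -> int:
        return int(round(self.overlap_fraction * min(self.n_ena, self.n_bold)))


@dataclass
class RecordPlan:
    """Ground truth for one planted record."""

    record_id: str
    sources: list[str]          # ["ENA"], ["BOLD"] or ["ENA", "BOLD"]
    category: str
    expect_kept: bool
    expect_fail_stage: str | None
    expect_provenance: str | None
    final_length: int
    species_taxid: int | None
    lineage: dict[str, str] | None
    expect_changed: bool
    process_id: str | None = None


@dataclass
class CorpusManifest:
    seed: int
    params: dict
    records: list[RecordPlan]
    expected_provenance: dict[str, int]
    expected_total: int
    expected_synonyms: list[str]
    expected_updated_bold: int
    expected_mode_length: int | None
    expected_distinct: dict[str, int]
    bold_rows_skipped: int

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CorpusManifest":
        payload = json.loads(text)
        payload["records"] = [RecordPlan(**r) for r in payload["records"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# sequence construction


def _flank(length: int) -> str:
    return ("GGA" * (length // 3 + 1))[:length]


def _coding_block(consensus: str, rng: random.Random, safe: dict[str, list[str]]) -> str:
    return "".join(rng.choice(safe[aa]) for aa in consensus)


class _Builder:
    """Assembles one planted record's sequence and annotation."""

    def __init__(self, consensus: str, rng: random.Random, safe: dict[str, list[str]]):
        self.consensus = consensus
        self.rng = rng
        self.safe = safe

    def build(self, category: str, reverse: bool):
        """Returns (sequence, cds_span(0-based, forward axis), cds_strand,
        pseudo_flag, final_kept_length)."""
        rng = self.rng
        if category == "too_short":
            return _flank(99), (0, 99), "+", False, 99
        if category == "too_long":
            return _flank(60_001), (0, 600), "+", False, 60_001
        if category == "low_hmm":
            seq = "".join(rng.choice("ACGT") for _ in range(658))
            return seq, (0, 600), "+", False, 658

        if rng.random() < 0.6:
            total = 658
        else:
            total = rng.randrange(632, 700)
        fl = rng.randrange(0, total - _CODING_NT + 1)
        coding = _coding_block(self.consensus, rng, self.safe)

        if category == "internal_stop":
            pos = 3 * rng.randrange(40, 160)
            coding = coding[:pos] + "TAA" + coding[pos + 3 :]

        cds = (fl, fl + _CODING_NT)
        if category == "cds_overlap_79":
            # CDS shifted 121 nt right of the footprint: shares 479/600 sites
            total = fl + _CODING_NT + 150
            cds = (fl + 121, fl + 721)

        seq = _flank(fl) + coding + _flank(total - fl - _CODING_NT)

        if category == "internal_n":
            tail_start = fl + _CODING_NT
            pos = tail_start + 2
            if pos + 6 >= len(seq):  # keep the Ns internal
                seq = seq + _flank(9)
                total = len(seq)
            seq = seq[:pos] + "NNNNNN" + seq[pos + 6 :]

        strand = "+"
        if reverse:
            L = len(seq)
            seq = reverse_complement(seq)
            cds = (L - cds[1], L - cds[0])
            strand = "-"
        return seq, cds, strand, category == "pseudogene", len(seq)


# ---------------------------------------------------------------------------
# file writers


def _write_taxdump(outdir: Path) -> None:
    with open(outdir / "nodes.dmp", "w") as fh:
        for taxid, parent, rank, _name, mgc in _TAX_NODES:
            fields = [
                str(taxid), str(parent), rank, "", "0", "1", "1", "1",
                str(mgc), "1", "0", "0", "",
            ]
            fh.write("\t|\t".join(fields) + "\t|\n")
    with open(outdir / "names.dmp", "w") as fh:
        for taxid, _parent, _rank, name, _mgc in _TAX_NODES:
            fh.write("\t|\t".join([str(taxid), name, "", "scientific name"]) + "\t|\n")
        # one synonym-class row: must never enter the name index
        fh.write("\t|\t".join(["7227", "Sophophora melanogaster", "", "synonym"]) + "\t|\n")
    with open(outdir / "gencode.dmp", "w") as fh:
        for code_id, abbrev in ((1, "SGC0"), (2, "SGC1"), (5, "SGC4")):
            code = GeneticCode.from_table_id(code_id)
            ncbieaa = "".join(code.codon_to_aa[c] for c in CODONS)
            fh.write(
                "\t|\t".join([str(code_id), abbrev, code.name, ncbieaa, "-" * 64]) + "\t|\n"
            )


def _write_profile(path: Path, consensus: str) -> None:
    M = len(consensus)
    bg = [AMINO_BACKGROUND[a] for a in AMINO_ALPHABET]

    def nll(p: float) -> str:
        return "  *    " if p <= 0 else f"{-math.log(p):7.5f}"

    def emission_line(target: str | None) -> str:
        probs = []
        for i, a in enumerate(AMINO_ALPHABET):
            if target is None:
                probs.append(bg[i])
            elif a == target:
                probs.append(0.9)
            else:
                probs.append(0.1 / 19.0)
        return "  ".join(nll(p) for p in probs)

    lines = [
        "HMMER3/f [3.4 | synthetic]",
        "NAME  COX1_toy",
        "ACC   SYN00001.1",
        "DESC  synthetic cytochrome oxidase subunit I toy profile",
        f"LENG  {M}",
        "ALPH  amino",
        "RF    no",
        "MM    no",
        "CONS  yes",
        "CS    no",
        "MAP   yes",
        "NSEQ  10",
        "EFFN  10.000000",
        "CKSUM 0",
        f"GA    {_TRUSTED_CUTOFF:.2f} {_TRUSTED_CUTOFF:.2f};",
        f"TC    {_TRUSTED_CUTOFF:.2f} {_TRUSTED_CUTOFF:.2f};",
        "NC    30.00 30.00;",
        "STATS LOCAL MSV       -9.9014  0.70957",
        "STATS LOCAL VITERBI  -10.7224  0.70957",
        "STATS LOCAL FORWARD   -4.1637  0.70957",
        "HMM          "
        + "        ".join(AMINO_ALPHABET)
        + "\n            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
        "  COMPO   " + emission_line(None),
        "          " + emission_line(None),
        "          "
        + "  ".join(nll(p) for p in (0.95, 0.025, 0.025, 0.5, 0.5, 0.5, 0.5)),
    ]
    for k, aa in enumerate(consensus, start=1):
        lines.append(f"{k:7d}   " + emission_line(aa) + f"  {k} {aa.lower()} - - -")
        lines.append("          " + emission_line(None))
        if k < M:
            trans = (0.93, 0.02, 0.05, 0.5, 0.5, 0.5, 0.5)
        else:
            trans = (1.0, 0.0, 0.0, 0.5, 0.5, 1.0, 0.0)
        lines.append("          " + "  ".join(nll(p) for p in trans))
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")


def _embl_entry(
    accession: str,
    sequence: str,
    organism: str,
    taxid: int | None,
    cds_span: tuple[int, int] | None,
    cds_strand: str,
    gene: str | None,
    product: str | None,
    pseudo: bool,
    metadata: dict[str, str],
) -> str:
    L = len(sequence)
    lines = [
        f"ID   {accession}; SV 1; linear; genomic DNA; STD; INV; {L} BP.",
        "XX",
        f"AC   {accession};",
        "XX",
        f"DE   {organism} cytochrome oxidase subunit I gene.",
        "XX",
        f"OS   {organism}",
        "OC   Eukaryota; Metazoa.",
        "XX",
        "FH   Key             Location/Qualifiers",
        "FH",
        f"FT   source          1..{L}",
        f'FT                   /organism="{organism}"',
    ]
    if taxid is not None:
        lines.append(f'FT                   /db_xref="taxon:{taxid}"')
    for key in ("country", "lat_lon", "collection_date", "host"):
        if key in metadata:
            lines.append(f'FT                   /{key}="{metadata[key]}"')
    if cds_span is not None:
        loc = f"{cds_span[0] + 1}..{cds_span[1]}"
        if cds_strand == "-":
            loc = f"complement({loc})"
        lines.append(f"FT   CDS             {loc}")
        if gene:
            lines.append(f'FT                   /gene="{gene}"')
        if product:
            lines.append(f'FT                   /product="{product}"')
        if pseudo:
            lines.append("FT                   /pseudo")
    lines.append("XX")
    counts = {b: sequence.count(b) for b in "ACGT"}
    other = L - sum(counts.values())
    lines.append(
        f"SQ   Sequence {L} BP; {counts['A']} A; {counts['C']} C; "
        f"{counts['G']} G; {counts['T']} T; {other} other;"
    )
    seq = sequence.lower()
    for i in range(0, L, 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        pos = min(i + 60, L)
        lines.append(f"     {groups:<66}{pos:>9}")
    lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# generator


def generate_corpus(seed: int, outdir, params: CorpusParams | None = None) -> CorpusManifest:
    """Write a complete synthetic corpus under ``outdir``; returns the manifest.

    Raises ValueError when the violation mix does not fit into the number of
    source-unique records requested.
    """
    params = params or CorpusParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    safe = _safe_codon_table()

    n_shared = params.n_shared
    n_ena_unique = params.n_ena - n_shared
    n_bold_unique = params.n_bold - n_shared

    ena_classes = [c for c in VIOLATION_CLASSES if c not in _BOLD_ONLY]
    bold_classes = [c for c in VIOLATION_CLASSES if c not in _ENA_ONLY]
    ena_plan: list[str] = []
    bold_plan: list[str] = []
    for cls, count in params.violation_mix.items():
        if cls not in VIOLATION_CLASSES:
            raise ValueError(f"unknown violation class {cls!r}")
        target = ena_plan if cls in ena_classes and cls not in _BOLD_ONLY else bold_plan
        target.extend([cls] * count)
    # rebalance source-agnostic classes onto BOLD when ENA is oversubscribed
    while len(ena_plan) > n_ena_unique:
        movable = [c for c in ena_plan if c not in _ENA_ONLY]
        if not movable or len(bold_plan) >= n_bold_unique:
            raise ValueError("violation mix does not fit the requested corpus size")
        ena_plan.remove(movable[-1])
        bold_plan.append(movable[-1])
    if len(bold_plan) > n_bold_unique:
        raise ValueError("violation mix does not fit the requested corpus size")
    ena_plan += ["clean"] * (n_ena_unique - len(ena_plan))
    bold_plan += ["clean"] * (n_bold_unique - len(bold_plan))
    rng.shuffle(ena_plan)
    rng.shuffle(bold_plan)

    consensus = "".join(
        rng.choice([a for a in AMINO_ALPHABET if a != "G"]) for _ in range(_MODEL_LENGTH)
    )
    builder = _Builder(consensus, rng, safe)

    records: list[RecordPlan] = []
    embl_entries: list[str] = []
    bold_rows: list[dict[str, str]] = []
    acc2taxid_rows: list[tuple[str, int]] = []
    blast_rows: list[str] = []
    synonyms: set[str] = set()

    lineage_cache = {t: _lineage_names(t) for t in _SPECIES_POOL}
    counter = 0

    def next_ids():
        nonlocal counter
        counter += 1
        return f"ACC{seed % 100:02d}{counter:04d}", f"FIX{seed % 100:02d}{counter:04d}-21"

    def plant(category: str, sources: list[str]):
        accession, process_id = next_ids()
        reverse = category == "clean" and counter % 4 == 0
        seq, cds, strand, pseudo, length = builder.build(category, reverse)

        if category == "unknown_taxon":
            taxid, lineage = None, dict(_UNKNOWN_LINEAGE)
        else:
            taxid = rng.choice(_SPECIES_POOL)
            lineage = dict(lineage_cache[taxid])

        stage = _CLASS_STAGE[category]
        kept = stage is None
        record_id = accession if "ENA" in sources else process_id
        if "ENA" in sources and "BOLD" in sources:
            provenance = "BOTH"
        elif "ENA" in sources:
            provenance = "ENA_unique"
        else:
            provenance = "BOLD_unique"

        raw_bold = dict(lineage) if "BOLD" in sources else None
        changed = False
        if category == "changed_name" and raw_bold is not None:
            raw_bold["family"] = "Oldfamilidae"
            changed = True

        if "ENA" in sources:
            gene = rng.choice(_GENE_LABELS)
            product = rng.choice(_PRODUCT_LABELS)
            if kept:
                synonyms.add(gene)
                synonyms.add(product)
            meta = {
                "country": "Italy: Apulia, Bari",
                "lat_lon": "41.1200 N 16.8700 E",
                "collection_date": "12-Jul-2019",
            }
            if counter % 5 == 0:
                meta["host"] = "Apis mellifera"
            embl_entries.append(
                _embl_entry(
                    accession,
                    seq,
                    lineage.get("species", "unknown organism"),
                    taxid,
                    cds,
                    strand,
                    gene,
                    product,
                    pseudo,
                    meta,
                )
            )
            if taxid is not None:
                acc2taxid_rows.append((accession, taxid))
        if "BOLD" in sources:
            bold_rows.append(
                {
                    "processid": process_id,
                    "genbank_accession": accession if "ENA" in sources else "",
                    "nucleotides": seq,
                    "markercode": "COI-5P",
                    "phylum_name": raw_bold.get("phylum", ""),
                    "class_name": raw_bold.get("class", ""),
                    "order_name": raw_bold.get("order", ""),
                    "family_name": raw_bold.get("family", ""),
                    "genus_name": raw_bold.get("genus", ""),
                    "species_name": raw_bold.get("species", ""),
                    "lat": f"{40 + rng.random():.4f}",
                    "lon": f"{16 + rng.random():.4f}",
                    "country": "Italy",
                    "exactsite": "Bari",
                    "collectiondate": "2019-07-12",
                }
            )

        if category == "bacterial_hit":
            blast_rows.append(
                f"{record_id}\tENA|FAKE01|metazoan\t91.2\t600\t50\t0\t1\t600\t1\t600\t1e-150\t750\t{taxid}"
            )
            blast_rows.append(
                f"{record_id}\tENA|FAKE02|bacterial\t98.5\t640\t9\t0\t1\t640\t1\t640\t1e-170\t990\t562"
            )
        elif kept and taxid is not None and counter % 2 == 0:
            blast_rows.append(
                f"{record_id}\tENA|SELF{counter:04d}|match\t99.0\t600\t6\t0\t1\t600\t1\t600\t1e-160\t{900 + rng.randrange(300)}\t{taxid}"
            )

        records.append(
            RecordPlan(
                record_id=record_id,
                sources=sources,
                category=category,
                expect_kept=kept,
                expect_fail_stage=stage,
                expect_provenance=provenance if kept else None,
                final_length=length,
                species_taxid=taxid,
                lineage=lineage if kept else None,
                expect_changed=changed and kept,
                process_id=process_id if "BOLD" in sources else None,
            )
        )

    for _ in range(n_shared):
        plant("clean", ["ENA", "BOLD"])
    for category in ena_plan:
        plant(category, ["ENA"])
    for category in bold_plan:
        plant(category, ["BOLD"])

    # two parser-coverage rows: wrong marker (filtered) and empty nucleotides
    bold_rows.append(
        {
            "processid": f"FIX{seed % 100:02d}9998-21",
            "genbank_accession": "",
            "nucleotides": "ATGCATGCATGC",
            "markercode": "rbcL",
            "phylum_name": "Tracheophyta",
            "class_name": "",
            "order_name": "",
            "family_name": "",
            "genus_name": "",
            "species_name": "",
            "lat": "",
            "lon": "",
            "country": "",
            "exactsite": "",
            "collectiondate": "",
        }
    )
    bold_rows.append(
        {
            "processid": f"FIX{seed % 100:02d}9999-21",
            "genbank_accession": "",
            "nucleotides": "",
            "markercode": "COI-5P",
            "phylum_name": "Arthropoda",
            "class_name": "",
            "order_name": "",
            "family_name": "",
            "genus_name": "",
            "species_name": "",
            "lat": "",
            "lon": "",
            "country": "",
            "exactsite": "",
            "collectiondate": "",
        }
    )

    # ---- write files
    (outdir / "ena.dat").write_text("".join(embl_entries))
    columns = [
        "processid", "genbank_accession", "nucleotides", "markercode",
        "phylum_name", "class_name", "order_name", "family_name",
        "genus_name", "species_name", "lat", "lon", "country", "exactsite",
        "collectiondate",
    ]
    with open(outdir / "bold.tsv", "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in bold_rows:
            fh.write("\t".join(row[c] for c in columns) + "\n")
    _write_profile(outdir / "profile.hmm", consensus)
    _write_taxdump(outdir)
    with open(outdir / "acc2taxid.tsv", "w") as fh:
        fh.write("accession\taccession.version\ttaxid\tgi\n")
        for acc, taxid in acc2taxid_rows:
            fh.write(f"{acc}\t{acc}.1\t{taxid}\t0\n")
    (outdir / "blast.tsv").write_text("\n".join(blast_rows) + ("\n" if blast_rows else ""))

    # ---- expectations
    kept = [r for r in records if r.expect_kept]
    provenance = {"BOLD_unique": 0, "ENA_unique": 0, "BOTH": 0}
    for r in kept:
        provenance[r.expect_provenance] += 1
    lengths = [r.final_length for r in kept]
    mode_length = None
    if lengths:
        top = max(lengths.count(x) for x in set(lengths))
        mode_length = min(x for x in set(lengths) if lengths.count(x) == top)
    distinct = {
        rank: len({r.lineage[rank] for r in kept if r.lineage and r.lineage.get(rank)})
        for rank in _RANK_CHAIN
    }

    manifest = CorpusManifest(
        seed=seed,
        params={
            "n_ena": params.n_ena,
            "n_bold": params.n_bold,
            "overlap_fraction": params.overlap_fraction,
            "violation_mix": dict(params.violation_mix),
        },
        records=records,
        expected_provenance=provenance,
        expected_total=len(kept),
        expected_synonyms=sorted(synonyms),
        expected_updated_bold=sum(1 for r in kept if r.expect_changed),
        expected_mode_length=mode_length,
        expected_distinct=distinct,
        bold_rows_skipped=1,
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")

    config = {
        "ena_flatfiles": ["ena.dat"],
        "bold_tsv": ["bold.tsv"],
        "hmm_profile": "profile.hmm",
        "taxdump_nodes": "nodes.dmp",
        "taxdump_names": "names.dmp",
        "taxdump_gencode": "gencode.dmp",
        "acc2taxid": "acc2taxid.tsv",
        "blast_tab": "blast.tsv",
        "output_dir": "out",
    }
    with open(outdir / "config.yaml", "w") as fh:
        for key, value in config.items():
            if isinstance(value, list):
                fh.write(f"{key}:\n")
                for v in value:
                    fh.write(f"  - {v}\n")
            else:
                fh.write(f"{key}: {value}\n")
    return manifest
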