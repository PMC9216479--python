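"""Readers and writers for every external format the pipeline touches.

Input dialects: EMBL flat files (ENA standard releases), BOLD-style
specimen/sequence TSV dumps, HMMER3/f ASCII profiles, NCBI taxdump ``.dmp``
files plus 4-column ``accession2taxid`` mappings. Output: FASTA plus one
taxonomy+metadata TSV.

Conventions applied at the boundary, once:

* flat-file feature locations (1-based, inclusive) are converted to 0-based
  half-open coordinates on ingest;
* accessions are stored versionless (``ACC00001.2`` -> ``ACC00001``);
* sequences are upper-cased with gaps and whitespace stripped;
* ``join(...)`` locations become multiple spans of one feature, and partial
  location markers (``<``, ``>``) are dropped.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from Bio import SeqIO

from .profile_search import AMINO_ALPHABET, AMINO_BACKGROUND, ProfileHMM
from .translation import GeneticCode

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "CdsFeature",
    "SequenceRecord",
    "ParseIssue",
    "TaxonomyStore",
    "DEFAULT_BOLD_COLUMNS",
    "read_embl_flatfile",
    "read_bold_tsv",
    "read_hmm_profile",
    "read_taxdump",
    "read_acc2taxid",
    "write_collection",
    "COLLECTION_COLUMNS",
    "RANKS",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_IUPAC_DNA = set("ACGTRYKMBVDHSWN")


class Source(str, Enum):
    ENA = "ENA"
    BOLD = "BOLD"


@dataclass
class CdsFeature:
    """An annotated coding region (CDS or gene feature).

    ``spans`` holds one or more 0-based half-open intervals (several for
    ``join(...)`` locations); overlap computations use their union.
    """

    spans: list[tuple[int, int]]
    strand: str = "+"
    gene_label: str | None = None
    product_label: str | None = None
    is_pseudogene: bool = False
    feature_key: str = "CDS"

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    @property
    def site_count(self) -> int:
        """Number of nucleotide sites in the union of spans."""
        return sum(e - s for s, e in merge_intervals(self.spans))


def merge_intervals(spans) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted((s, e) for s, e in spans if e > s):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class SequenceRecord:
    """One nucleotide entry from either source database."""

    record_id: str
    source: Source
    sequence: str
    accession: str | None = None
    process_id: str | None = None
    features: list[CdsFeature] = field(default_factory=list)
    raw_taxon_names: dict[str, str] = field(default_factory=dict)
    raw_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.source is Source.ENA and not self.accession:
            raise ValueError(f"ENA record {self.record_id} lacks an accession")
        if self.source is Source.BOLD and not self.accession and not self.process_id:
            raise ValueError(f"BOLD record {self.record_id} lacks both accession and process ID")


@dataclass(frozen=True)
class ParseIssue:
    """A record-level parse problem (the entry was skipped, not fatal)."""

    entry_hint: str
    reason: str


def strip_version(accession: str | None) -> str | None:
    if accession is None:
        return None
    return re.sub(r"\.\d+$", "", accession.strip())


# ---------------------------------------------------------------------------
# EMBL flat files


_ID_BP = re.compile(r"(\d+)\s+BP\b")


def read_embl_flatfile(stream) -> tuple[list[SequenceRecord], list[ParseIssue]]:
    """Parse an EMBL flat-file stream into records plus a parse-error report.

    Entries are delimited by ``//``. A malformed entry (no ID line, declared
    length disagreeing with the sequence, truncated tail) is skipped and
    reported; it never aborts the whole file.
    """
    records: list[SequenceRecord] = []
    issues: list[ParseIssue] = []
    seen_ids: set[str] = set()
    for text in _split_embl_entries(stream):
        hint = _entry_hint(text)
        try:
            rec = SeqIO.read(io.StringIO(text), "embl")
        except Exception as exc:  # record-level: collect and move on
            issues.append(ParseIssue(hint, f"unparseable entry: {exc}"))
            continue
        declared = _declared_length(text)
        if declared is not None and declared != len(rec.seq):
            issues.append(
                ParseIssue(hint, f"declared length {declared} != sequence length {len(rec.seq)}")
            )
            continue
        accession = strip_version(rec.id) or strip_version(rec.name)
        sequence = re.sub(r"[\s\-]", "", str(rec.seq).upper())
        features = []
        raw_taxa: dict[str, str] = {}
        raw_meta: dict[str, str] = {}
        organism = rec.annotations.get("organism")
        if organism:
            raw_taxa["organism"] = organism
        for feat in rec.features:
            if feat.type == "source":
                for q in ("country", "lat_lon", "host", "collection_date"):
                    if q in feat.qualifiers:
                        raw_meta[q] = feat.qualifiers[q][0]
                for xref in feat.qualifiers.get("db_xref", []):
                    if xref.startswith("taxon:"):
                        raw_taxa["taxid"] = xref.split(":", 1)[1]
            elif feat.type in ("CDS", "gene"):
                spans = [(int(p.start), int(p.end)) for p in feat.location.parts]
                strand = "-" if feat.location.strand == -1 else "+"
                features.append(
                    CdsFeature(
                        spans=spans,
                        strand=strand,
                        gene_label=feat.qualifiers.get("gene", [None])[0],
                        product_label=feat.qualifiers.get("product", [None])[0],
                        is_pseudogene="pseudo" in feat.qualifiers
                        or "pseudogene" in feat.qualifiers,
                        feature_key=feat.type,
                    )
                )
        if accession in seen_ids:
            issues.append(ParseIssue(hint, f"duplicate accession {accession} within file"))
            continue
        seen_ids.add(accession)
        records.append(
            SequenceRecord(
                record_id=accession,
                source=Source.ENA,
                sequence=sequence,
                accession=accession,
                features=features,
                raw_taxon_names=raw_taxa,
                raw_metadata=raw_meta,
            )
        )
    return records, issues


def _split_embl_entries(stream):
    buf: list[str] = []
    for line in stream:
        buf.append(line)
        if line.startswith("//"):
            text = "".join(buf)
            buf = []
            if text.strip("/ \n"):
                yield text
    tail = "".join(buf)
    if tail.strip():
        yield tail  # truncated final entry; the EMBL parser will reject it


def _entry_hint(text: str) -> str:
    for line in text.splitlines():
        if line.startswith("ID"):
            return line[:60]
    return text.splitlines()[0][:60] if text.splitlines() else "<empty>"


def _declared_length(text: str) -> int | None:
    for line in text.splitlines():
        if line.startswith("ID"):
            m = _ID_BP.search(line)
            return int(m.group(1)) if m else None
    return None


# ---------------------------------------------------------------------------
# BOLD TSV


#: Default column names of a BOLD combined specimen+sequence TSV export.
DEFAULT_BOLD_COLUMNS = {
    "process_id": "processid",
    "accession": "genbank_accession",
    "nucleotides": "nucleotides",
    "marker": "markercode",
    "phylum": "phylum_name",
    "class": "class_name",
    "order": "order_name",
    "family": "family_name",
    "genus": "genus_name",
    "species": "species_name",
    "lat": "lat",
    "lon": "lon",
    "country": "country",
    "region": "exactsite",
    "collection_date": "collectiondate",
}

_BOLD_RANK_KEYS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def read_bold_tsv(
    stream,
    column_map: dict[str, str] | None = None,
    marker: str = "COI-5P",
) -> tuple[list[SequenceRecord], int]:
    """Parse a BOLD-style TSV dump; returns (records, n_rows_skipped).

    Only rows whose marker code equals ``marker`` are kept. Gaps and
    whitespace are stripped from the nucleotide column; rows with an empty
    sequence are skipped and counted. A mapped column missing from the
    header is a fatal configuration error.
    """
    colmap = dict(DEFAULT_BOLD_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c and c not in df.columns]
    if missing:
        raise KeyError(f"BOLD TSV is missing mapped column(s): {', '.join(sorted(missing))}")

    records: list[SequenceRecord] = []
    skipped = 0
    seen_ids: set[str] = set()
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        if row[colmap["marker"]].strip() != marker:
            continue
        sequence = re.sub(r"[\s\-]", "", row[colmap["nucleotides"]]).upper()
        if not sequence:
            skipped += 1
            continue
        process_id = row[colmap["process_id"]].strip() or None
        accession = strip_version(row[colmap["accession"]].strip()) or None
        record_id = accession or process_id
        if not record_id:
            skipped += 1
            continue
        if record_id in seen_ids:
            logger.warning("duplicate BOLD record id %s; keeping first", record_id)
            skipped += 1
            continue
        seen_ids.add(record_id)
        raw_taxa = {}
        for rank in _BOLD_RANK_KEYS:
            col = colmap.get(rank)
            if col and col in row and row[col].strip():
                raw_taxa[rank] = row[col].strip()
        raw_meta = {}
        for key in ("lat", "lon", "country", "region", "collection_date"):
            col = colmap.get(key)
            if col and col in row and row[col].strip():
                raw_meta[key] = row[col].strip()
        records.append(
            SequenceRecord(
                record_id=record_id,
                source=Source.BOLD,
                sequence=sequence,
                accession=accession,
                process_id=process_id,
                raw_taxon_names=raw_taxa,
                raw_metadata=raw_meta,
            )
        )
    return records, skipped


# ---------------------------------------------------------------------------
# HMMER3 ASCII profiles


def read_hmm_profile(stream) -> ProfileHMM:
    """Parse a HMMER3/f ASCII profile into bit-space scores.

    The file stores emissions and transitions as negative natural-log
    probabilities; emissions are converted to log-odds bits against the
    standard amino-acid background, transitions to log2 probabilities.
    TC/GA/NC cutoff lines are captured when present. Non-amino alphabets are
    rejected.
    """
    lines = iter(stream)
    header = next(lines, "")
    if not header.startswith("HMMER3"):
        raise ValueError("not a HMMER3 ASCII profile")
    name = "?"
    length = None
    cutoffs: dict[str, float] = {}
    alphabet_cols: list[str] | None = None
    for line in lines:
        tag = line[:6].strip()
        if tag == "NAME":
            name = line[6:].strip()
        elif tag == "LENG":
            length = int(line[6:].strip())
        elif tag == "ALPH":
            alph = line[6:].strip().lower()
            if alph != "amino":
                raise ValueError(f"profile alphabet is {alph!r}; an amino-acid profile is required")
        elif tag in ("TC", "GA", "NC"):
            cutoffs[tag] = float(line[6:].split()[0].rstrip(";"))
        elif tag == "HMM":
            alphabet_cols = line.split()[1:]
            break
    if length is None or alphabet_cols is None:
        raise ValueError("malformed profile: missing LENG or HMM header")
    if "".join(alphabet_cols) != AMINO_ALPHABET:
        raise ValueError("profile emission columns are not the 20 amino acids")

    next(lines)  # transition-order header line
    bg = np.array([AMINO_BACKGROUND[a] for a in AMINO_ALPHABET])
    log2 = math.log2

    def to_probs(tokens):
        return np.array([0.0 if t == "*" else math.exp(-float(t)) for t in tokens])

    match_bits = np.zeros((length + 1, 20))
    insert_bits = np.zeros((length + 1, 20))
    trans_bits = np.full((length + 1, 7), -np.inf)

    rows: list[list[str]] = []
    for line in lines:
        if line.strip() == "//":
            break
        rows.append(line.split())
    if rows and rows[0] and rows[0][0] == "COMPO":
        rows = rows[1:]
    # node 0: insert emissions + begin transitions
    if len(rows) < 2 + 3 * length:
        raise ValueError("malformed profile: truncated model table")
    with np.errstate(divide="ignore"):
        insert_bits[0] = np.log2(to_probs(rows[0][:20]) / bg)
        trans_bits[0] = np.log2(to_probs(rows[1][:7]))
        for k in range(1, length + 1):
            m_line, i_line, t_line = rows[2 + 3 * (k - 1) : 2 + 3 * k]
            if int(m_line[0]) != k:
                raise ValueError(f"malformed profile: expected node {k}, got {m_line[0]}")
            match_bits[k] = np.log2(to_probs(m_line[1:21]) / bg)
            insert_bits[k] = np.log2(to_probs(i_line[:20]) / bg)
            trans_bits[k] = np.log2(to_probs(t_line[:7]))
    return ProfileHMM(
        name=name,
        M=length,
        match_bits=match_bits,
        insert_bits=insert_bits,
        trans_bits=trans_bits,
        tc=cutoffs.get("TC"),
        ga=cutoffs.get("GA"),
        nc=cutoffs.get("NC"),
    )


# ---------------------------------------------------------------------------
# NCBI taxdump


@dataclass
class TaxonomyStore:
    """In-memory NCBI taxonomy: tree, names, genetic codes, accession map."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    name_to_taxid: dict[str, list[int]]
    mgc: dict[int, int]
    gencodes: dict[int, GeneticCode] = field(default_factory=dict)
    acc2taxid: dict[str, int] = field(default_factory=dict)
    root: int = 1

    def ancestors(self, taxid: int):
        """Yield taxid and its ancestors up to (and including) the root."""
        seen = set()
        t = taxid
        while t in self.parent and t not in seen:
            yield t
            seen.add(t)
            p = self.parent[t]
            if p == t:
                return
            t = p

    def contains(self, taxid: int) -> bool:
        return taxid in self.parent

    def is_descendant(self, taxid: int, clade: int) -> bool:
        return any(t == clade for t in self.ancestors(taxid))

    def mito_gencode_id(self, taxid: int) -> int | None:
        """Nearest-ancestor mitochondrial genetic code (0 = unspecified)."""
        for t in self.ancestors(taxid):
            code = self.mgc.get(t, 0)
            if code:
                return code
        return None

    def taxid_for_name(self, name: str) -> list[int]:
        return self.name_to_taxid.get(name.strip().lower(), [])


def _dmp_rows(stream):
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        line = re.sub(r"\t\|$", "", line)
        yield [f.strip() for f in line.split("\t|\t")]


def read_taxdump(nodes, names, gencode=None) -> TaxonomyStore:
    """Load ``nodes.dmp``/``names.dmp`` (and optionally ``gencode.dmp``).

    Only "scientific name" class names enter the name index. The
    mitochondrial genetic code column of nodes.dmp is kept per node and
    resolved per taxid by nearest-ancestor lookup. Cyclic parent links are
    fatal; unknown rank labels are preserved verbatim.
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    mgc: dict[int, int] = {}
    for fields in _dmp_rows(nodes):
        taxid = int(fields[0])
        parent[taxid] = int(fields[1])
        rank[taxid] = fields[2]
        if len(fields) > 8 and fields[8].isdigit():
            mgc[taxid] = int(fields[8])

    roots = [t for t, p in parent.items() if p == t]
    if len(roots) != 1:
        raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
    root = roots[0]
    for taxid in parent:
        seen = set()
        t = taxid
        while parent.get(t, t) != t:
            if t in seen:
                raise ValueError(f"cyclic parent links at taxid {t}")
            seen.add(t)
            t = parent[t]

    name: dict[int, str] = {}
    name_to_taxid: dict[str, list[int]] = {}
    for fields in _dmp_rows(names):
        taxid = int(fields[0])
        label, name_class = fields[1], fields[3]
        if name_class != "scientific name":
            continue
        name[taxid] = label
        name_to_taxid.setdefault(label.lower(), []).append(taxid)

    unknown = set(rank) - set(parent)
    if unknown:
        raise ValueError(f"rank entries for taxids missing from nodes: {sorted(unknown)[:5]}")

    gencodes: dict[int, GeneticCode] = {}
    if gencode is not None:
        for fields in _dmp_rows(gencode):
            code_id = int(fields[0])
            ncbieaa = fields[3]
            if len(ncbieaa) == 64:
                gencodes[code_id] = GeneticCode.from_ncbieaa(code_id, ncbieaa, fields[2])

    return TaxonomyStore(
        parent=parent,
        rank=rank,
        name=name,
        name_to_taxid=name_to_taxid,
        mgc=mgc,
        gencodes=gencodes,
        root=root,
    )


def read_acc2taxid(stream) -> dict[str, int]:
    """Parse a 4-column accession2taxid TSV into {versionless accession: taxid}."""
    mapping: dict[str, int] = {}
    for i, line in enumerate(stream):
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            continue
        if i == 0 and cols[0].lower() == "accession":
            continue
        try:
            mapping[strip_version(cols[0])] = int(cols[2])
        except ValueError:
            continue
    return mapping


# ---------------------------------------------------------------------------
# collection output


COLLECTION_COLUMNS = (
    ["record_id", "source"]
    + list(RANKS)
    + [f"{r}_taxid" for r in RANKS]
    + [
        "seq_length",
        "mito_gencode",
        "country",
        "region",
        "host",
        "collection_year",
        "collection_date",
        "lat_dd",
        "lon_dd",
        "permalink",
    ]
)


def write_collection(records, lineages, metadata, out_fasta, out_tsv) -> None:
    """Write the final FASTA + taxonomy/metadata TSV.

    ``records`` is a list of merged records (``record_id``, ``provenance``,
    ``sequence``); ``lineages`` and ``metadata`` are keyed by record_id.
    Rows are sorted by record_id; unresolved fields are written as "NA".
    """
    ordered = sorted(records, key=lambda r: r.record_id)
    with open(out_fasta, "w") as fh:
        for rec in ordered:
            fh.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")

    rows = []
    for rec in ordered:
        lineage = lineages.get(rec.record_id)
        meta = metadata.get(rec.record_id)
        if lineage is None or meta is None:
            logger.warning("record %s missing lineage or metadata; writing NA row", rec.record_id)
        row = {
            "record_id": rec.record_id,
            "source": getattr(rec, "provenance", getattr(rec, "source", "NA")),
        }
        for r in RANKS:
            row[r] = lineage.names[r] if lineage else "NA"
            row[f"{r}_taxid"] = lineage.taxids[r] if lineage else "NA"
        if meta is not None:
            row.update(meta.as_row())
        else:
            row.update(
                {
                    c: "NA"
                    for c in COLLECTION_COLUMNS
                    if c not in row and c not in ("record_id", "source")
                }
            )
            row["seq_length"] = len(rec.sequence)
        rows.append(row)
    df = pd.DataFrame(rows, columns=COLLECTION_COLUMNS)
    df.to_csv(out_tsv, sep="\t", index=False)
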