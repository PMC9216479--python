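"""Harmonization of record classifications to the NCBI seven-rank backbone.

Every record is aligned to the canonical kingdom / phylum / class / order /
family / genus / species path of the NCBI taxonomy. Records with an INSDC
accession resolve through the accession2taxid mapping; BOLD-exclusive
records resolve through the lowest-rank taxon name of their own taxonomy
path that exists in the reference. Names absent from the reference are kept
verbatim with taxid "NA". Every BOLD record whose raw path differs from the
harmonized one is reported in the taxonomy-update table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .integrate import MergedRecord
from .io_formats import RANKS, TaxonomyStore

logger = logging.getLogger(__name__)

__all__ = [
    "Lineage",
    "LineageResolution",
    "lineage_from_taxid",
    "resolve_record_lineage",
    "taxonomy_update_report",
]

NA = "NA"


@dataclass
class Lineage:
    """Seven-rank classification path; unresolved slots hold "NA".

    ``names[rank]`` may be a verbatim source name while ``taxids[rank]`` is
    "NA" when the name has no match in the reference taxonomy.
    """

    names: dict[str, str] = field(default_factory=lambda: {r: NA for r in RANKS})
    taxids: dict[str, object] = field(default_factory=lambda: {r: NA for r in RANKS})

    def lowest_resolved_taxid(self):
        for rank in reversed(RANKS):
            if self.taxids[rank] != NA:
                return self.taxids[rank]
        return None


@dataclass
class LineageResolution:
    """Outcome of harmonizing one record.

    ``changes`` lists (rank, raw BOLD name, harmonized name) for every rank
    where the source classification disagrees with the reference.
    """

    lineage: Lineage
    changes: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def changed(self) -> bool:
        return bool(self.changes)


def lineage_from_taxid(taxid, store: TaxonomyStore) -> Lineage:
    """Walk parent links from ``taxid`` filling the seven canonical ranks.

    Only nodes whose rank label equals a canonical rank fill a slot (no
    promotion of e.g. subfamily); unmatched ranks stay "NA". An unknown
    taxid yields an all-NA lineage with a warning.
    """
    lineage = Lineage()
    if taxid in (None, NA) or not store.contains(int(taxid)):
        logger.warning("taxid %r absent from taxonomy; all-NA lineage", taxid)
        return lineage
    for t in store.ancestors(int(taxid)):
        rank = store.rank.get(t)
        if rank in RANKS and lineage.taxids[rank] == NA:
            lineage.names[rank] = store.name.get(t, NA)
            lineage.taxids[rank] = t
    return lineage


def _candidate_matches_raw_ranks(taxid: int, raw: dict[str, str], store: TaxonomyStore) -> bool:
    """True if the candidate's ancestry is consistent with raw higher ranks."""
    ancestor_names = {store.name.get(t, "").lower() for t in store.ancestors(taxid)}
    for rank in RANKS:
        name = raw.get(rank)
        if name and name.lower() in ancestor_names:
            return True
    return False


def _resolve_bold_names(raw: dict[str, str], store: TaxonomyStore) -> Lineage:
    """Lowest-rank name lookup with homonym disambiguation via higher ranks."""
    for rank in reversed(RANKS):
        name = raw.get(rank)
        if not name:
            continue
        candidates = store.taxid_for_name(name)
        if not candidates:
            continue
        if len(candidates) > 1:
            consistent = [
                t for t in candidates if _candidate_matches_raw_ranks(t, _above(raw, rank), store)
            ]
            if len(consistent) != 1:
                logger.warning(
                    "homonym %r (%d candidates) cannot be disambiguated; taxid NA", name, len(candidates)
                )
                continue
            candidates = consistent
        return lineage_from_taxid(candidates[0], store)
    return Lineage()


def _above(raw: dict[str, str], rank: str) -> dict[str, str]:
    idx = RANKS.index(rank)
    return {r: raw[r] for r in RANKS[:idx] if r in raw}


def resolve_record_lineage(record: MergedRecord, store: TaxonomyStore) -> LineageResolution:
    """Harmonize one merged record to the reference backbone.

    Resolution order: accession2taxid -> the flat file's own taxid
    cross-reference -> lowest-rank BOLD name lookup. Raw BOLD names at
    ranks the resolved lineage leaves empty are kept verbatim with taxid
    "NA". ``changes`` records every rank where a raw BOLD name was replaced
    by a different reference name.
    """
    raw_bold = dict(record.bold.raw_taxon_names) if record.bold is not None else {}

    taxid = None
    if record.accession is not None:
        taxid = store.acc2taxid.get(record.accession)
    if taxid is None and record.ena is not None:
        hint = record.ena.raw_taxon_names.get("taxid")
        if hint and hint.isdigit() and store.contains(int(hint)):
            taxid = int(hint)

    if taxid is not None:
        lineage = lineage_from_taxid(taxid, store)
    else:
        lineage = _resolve_bold_names({r: n for r, n in raw_bold.items() if r in RANKS}, store)

    changes: list[tuple[str, str, str]] = []
    for rank in RANKS:
        raw_name = raw_bold.get(rank)
        if lineage.taxids[rank] == NA and lineage.names[rank] == NA and raw_name:
            # no reference information at this rank: keep the source name
            lineage.names[rank] = raw_name
        elif raw_name and lineage.names[rank] != NA and raw_name.lower() != lineage.names[rank].lower():
            changes.append((rank, raw_name, lineage.names[rank]))
    return LineageResolution(lineage, changes)


def taxonomy_update_report(
    resolutions: dict[str, LineageResolution],
) -> tuple[list[tuple[str, str, str, str]], int]:
    """Rows (record_id, rank, old_name, new_name) plus distinct-record count."""
    rows: list[tuple[str, str, str, str]] = []
    changed_records = 0
    for record_id in sorted(resolutions):
        res = resolutions[record_id]
        if res.changed:
            changed_records += 1
            for rank, old, new in res.changes:
                rows.append((record_id, rank, old, new))
    return rows, changed_records
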