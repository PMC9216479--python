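"""Merging of curated ENA and BOLD record sets.

Records surviving curation in both sources are joined on their versionless
INSDC accession: a BOLD row whose GenBank accession matches an ENA entry
collapses into one record of provenance BOTH, keeping the ENA sequence and
feature table (the side the annotation check validated) while BOLD fills
in missing metadata. BOLD records without an accession are keyed by their
process ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import SequenceRecord, Source

logger = logging.getLogger(__name__)

__all__ = ["MergedRecord", "merge_sources", "PROVENANCES"]

PROVENANCES = ("BOLD_unique", "ENA_unique", "BOTH")

_SOURCE_LABEL = {"BOLD_unique": "BOLD", "ENA_unique": "ENA", "BOTH": "BOTH"}


@dataclass
class MergedRecord:
    """One dereplicated entry of the final collection."""

    record_id: str
    provenance: str  # one of PROVENANCES
    sequence: str
    contributing_ids: list[str] = field(default_factory=list)
    ena: SequenceRecord | None = None
    bold: SequenceRecord | None = None

    @property
    def source_label(self) -> str:
        """Value of the output TSV "source" column (BOLD | ENA | BOTH)."""
        return _SOURCE_LABEL[self.provenance]

    @property
    def accession(self) -> str | None:
        if self.ena is not None:
            return self.ena.accession
        return self.bold.accession if self.bold is not None else None


def _dedup(records: list[SequenceRecord], label: str) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.record_id in out:
            logger.warning("duplicate %s id %s; keeping first", label, rec.record_id)
            continue
        out[rec.record_id] = rec
    return out


def merge_sources(
    ena_kept: list[SequenceRecord], bold_kept: list[SequenceRecord]
) -> list[MergedRecord]:
    """Merge the two curated sets and assign provenance.

    Output order: ENA-side records (ENA_unique and BOTH) in ENA input
    order, then BOLD-unique records in BOLD input order. Intra-source
    duplicate ids collapse to the first occurrence with a warning. The
    counting identity |merged| = |ENA_unique| + |BOLD_unique| + |BOTH|
    holds by construction.
    """
    ena_by_acc = _dedup(ena_kept, "ENA")
    bold_by_id = _dedup(bold_kept, "BOLD")

    bold_by_acc = {
        rec.accession: rec for rec in bold_by_id.values() if rec.accession is not None
    }

    merged: list[MergedRecord] = []
    for acc, ena_rec in ena_by_acc.items():
        bold_rec = bold_by_acc.get(acc)
        if bold_rec is not None:
            contributing = [acc]
            if bold_rec.process_id:
                contributing.append(bold_rec.process_id)
            merged.append(
                MergedRecord(acc, "BOTH", ena_rec.sequence, contributing, ena_rec, bold_rec)
            )
        else:
            merged.append(MergedRecord(acc, "ENA_unique", ena_rec.sequence, [acc], ena_rec, None))

    matched_accessions = set(ena_by_acc) & set(bold_by_acc)
    for rid, bold_rec in bold_by_id.items():
        if bold_rec.accession in matched_accessions:
            continue
        contributing = [rid]
        merged.append(MergedRecord(rid, "BOLD_unique", bold_rec.sequence, contributing, None, bold_rec))
    return merged
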