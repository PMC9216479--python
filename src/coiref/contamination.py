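"""Contamination screen over an externally produced blastn result.

The nucleotide-similarity search itself is not re-run here: the stage
consumes a BLAST tabular (outfmt-6-like) file produced beforehand and
rejects records whose best hit (by bit score) falls under a rejected clade
— by default Bacteria, Archaea and Viridiplantae, i.e. non-animal matches
that indicate mislabeled or contaminant sequences. Records without a hit,
or with a hit that cannot be placed in the taxonomy, pass the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import TaxonomyStore

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "parse_blast_tab",
    "contamination_gate",
    "default_reject_clades",
    "DEFAULT_REJECT_CLADE_NAMES",
]

DEFAULT_REJECT_CLADE_NAMES = ("Bacteria", "Archaea", "Viridiplantae")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    bitscore: float
    subject_taxid: int | None = None
    pident: float | None = None
    evalue: float | None = None


def parse_blast_tab(stream, has_taxid_col: bool = True) -> dict[str, BlastHit]:
    """Best hit per query from a BLAST outfmt-6-like table.

    Expected columns are the standard 12 (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore), optionally
    followed by a subject-taxid column. Best = maximal bit score, ties kept
    by first occurrence; malformed rows are skipped with a warning.
    """
    best: dict[str, BlastHit] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        try:
            query, subject = cols[0], cols[1]
            pident = float(cols[2])
            evalue = float(cols[10])
            bitscore = float(cols[11])
            taxid = None
            if has_taxid_col:
                taxid = int(cols[12].split(";")[0])
        except (IndexError, ValueError):
            logger.warning("skipping malformed BLAST row %d: %r", lineno, line[:80])
            continue
        hit = BlastHit(query, subject, bitscore, taxid, pident, evalue)
        prev = best.get(query)
        if prev is None or hit.bitscore > prev.bitscore:
            best[query] = hit
    return best


def default_reject_clades(store: TaxonomyStore) -> set[int]:
    """Taxids of the default rejected clades present in the supplied taxonomy."""
    clades = set()
    for name in DEFAULT_REJECT_CLADE_NAMES:
        clades.update(store.taxid_for_name(name))
    return clades


def contamination_gate(
    record_id: str,
    hits: dict[str, BlastHit],
    store: TaxonomyStore,
    reject_clades: set[int],
) -> tuple[bool, str]:
    """Pass/fail for one record; returns (passed, reason).

    Fails iff the best hit's taxid has an ancestor in ``reject_clades``.
    No hit, no taxid, or a taxid absent from the taxonomy all pass (the
    screen can only reject what it can classify).
    """
    hit = hits.get(record_id)
    if hit is None:
        return True, "no similarity hit"
    if hit.subject_taxid is None:
        logger.warning("%s: best hit lacks a taxid; cannot classify", record_id)
        return True, "best hit lacks taxid"
    if not store.contains(hit.subject_taxid):
        logger.warning(
            "%s: best-hit taxid %d absent from taxonomy; cannot classify",
            record_id,
            hit.subject_taxid,
        )
        return True, f"best-hit taxid {hit.subject_taxid} not in taxonomy"
    for t in store.ancestors(hit.subject_taxid):
        if t in reject_clades:
            clade = store.name.get(t, str(t))
            return False, f"best hit under rejected clade {clade}"
    return True, "best hit outside rejected clades"
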