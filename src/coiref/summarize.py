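"""Collection-level summary statistics.

Three reports mirror what a reference-collection release note contains: a
provenance table (records unique to each source vs shared), the taxonomic
composition per phylum at the six sub-kingdom ranks, and the exact
sequence-length distribution. Percentage rounding is explicit because
published tables mix conventions: ``half_up`` (default) and ``truncate``
are both available.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from .integrate import MergedRecord
from .taxonomy import Lineage

__all__ = [
    "percentage",
    "ProvenanceSummary",
    "provenance_table",
    "provenance_summary",
    "CompositionRow",
    "composition_by_rank",
    "length_histogram",
    "LengthStats",
]

NA = "NA"

#: ranks reported in the composition table (grouped by phylum)
COMPOSITION_RANKS = ("class", "order", "family", "genus", "species")


def percentage(part: int, whole: int, decimals: int = 2, mode: str = "half_up") -> float:
    """100 * part / whole under an explicit rounding mode.

    ``half_up`` rounds 0.5 away from zero (ordinary table rounding);
    ``truncate`` drops excess digits. Division by zero yields 0.0.
    """
    if whole == 0:
        return 0.0
    rounding = {"half_up": ROUND_HALF_UP, "truncate": ROUND_DOWN}[mode]
    quantum = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(part) / Decimal(whole)).quantize(quantum, rounding=rounding)
    )


@dataclass
class ProvenanceSummary:
    counts: dict[str, int]
    total: int
    percentages: dict[str, object]


def provenance_table(
    n_bold_unique: int,
    n_ena_unique: int,
    n_both: int,
    decimals: int = 2,
    mode: str = "half_up",
) -> ProvenanceSummary:
    """Provenance counts and percentages from the three category counts."""
    counts = {"BOLD_unique": n_bold_unique, "ENA_unique": n_ena_unique, "BOTH": n_both}
    total = sum(counts.values())
    if total == 0:
        pct = {k: NA for k in counts}
    else:
        pct = {k: percentage(v, total, decimals, mode) for k, v in counts.items()}
    return ProvenanceSummary(counts, total, pct)


def provenance_summary(
    records: list[MergedRecord], decimals: int = 2, mode: str = "half_up"
) -> ProvenanceSummary:
    tally = Counter(rec.provenance for rec in records)
    return provenance_table(
        tally.get("BOLD_unique", 0), tally.get("ENA_unique", 0), tally.get("BOTH", 0),
        decimals, mode,
    )


@dataclass
class CompositionRow:
    """Per-phylum composition: sequence count plus distinct-taxa counts and
    percentages (relative to collection-wide distinct totals) per rank."""

    phylum: str
    seq_count: int
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)


def composition_by_rank(
    lineages: list[Lineage], decimals: int = 3, mode: str = "half_up"
) -> tuple[list[CompositionRow], dict[str, int]]:
    """Distinct-name composition per phylum.

    "NA" names never enter distinct counts; records with an unresolved
    phylum are grouped under phylum "NA". Returns (rows sorted by sequence
    count descending then phylum name, collection-wide distinct totals).
    """
    seq_counts: Counter[str] = Counter()
    per_phylum: dict[str, dict[str, set]] = {}
    totals: dict[str, set] = {r: set() for r in COMPOSITION_RANKS}
    for lin in lineages:
        phylum = lin.names["phylum"] if lin.names["phylum"] != NA else NA
        seq_counts[phylum] += 1
        bucket = per_phylum.setdefault(phylum, {r: set() for r in COMPOSITION_RANKS})
        for rank in COMPOSITION_RANKS:
            name = lin.names[rank]
            if name != NA:
                bucket[rank].add(name)
                totals[rank].add(name)
    total_counts = {r: len(v) for r, v in totals.items()}
    rows = []
    for phylum in sorted(seq_counts, key=lambda p: (-seq_counts[p], p)):
        counts = {r: len(per_phylum[phylum][r]) for r in COMPOSITION_RANKS}
        pct = {
            r: percentage(counts[r], total_counts[r], decimals, mode) if total_counts[r] else 0.0
            for r in COMPOSITION_RANKS
        }
        rows.append(CompositionRow(phylum, seq_counts[phylum], counts, pct))
    return rows, total_counts


@dataclass
class LengthStats:
    histogram: dict[int, int]
    min: int | None
    max: int | None
    mode: int | None


def length_histogram(lengths) -> LengthStats:
    """Exact integer length histogram; mode ties break to the smaller length."""
    counter = Counter(int(x) for x in lengths)
    if not counter:
        return LengthStats({}, None, None, None)
    mode = min(
        (length for length, n in counter.items() if n == max(counter.values()))
    )
    return LengthStats(dict(sorted(counter.items())), min(counter), max(counter), mode)
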