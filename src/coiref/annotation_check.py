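"""Annotation-consistency checks for ENA records.

ENA entries are not barcode-curated, so their own CDS annotation is
compared against the profile-HMM footprint: a record is kept only when the
best-overlapping CDS shares at least 80% of its sites with the HMM
localization. Pseudogene-tagged CDS reject the record outright. Gene and
product labels of profile-consistent features are harvested as candidate
marker-name synonyms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import CdsFeature, SequenceRecord, merge_intervals
from .profile_search import HmmHit

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "cds_profile_overlap",
    "validate_ena_record",
    "harvest_synonyms",
    "DEFAULT_OVERLAP_MIN",
]

DEFAULT_OVERLAP_MIN = 0.80


@dataclass(frozen=True)
class OverlapResult:
    """Overlap between one annotated feature and the HMM footprint.

    ``cds_sites`` is the union length of the feature's spans (the
    denominator of the fraction); ``shared_sites`` the intersection with the
    footprint.
    """

    cds_sites: int
    shared_sites: int
    fraction: float
    gene_label: str | None = None
    product_label: str | None = None


def cds_profile_overlap(cds: CdsFeature, hit: HmmHit) -> OverlapResult:
    """Fraction of CDS sites covered by the profile footprint.

    Both coordinate systems are 0-based half-open on the forward strand;
    strand is deliberately ignored (positional comparison only). A
    zero-length CDS yields fraction 0 with a warning.
    """
    spans = merge_intervals(cds.spans)
    cds_sites = sum(e - s for s, e in spans)
    shared = 0
    if hit.nt_start is not None and hit.nt_end is not None:
        for s, e in spans:
            shared += max(0, min(e, hit.nt_end) - max(s, hit.nt_start))
    if cds_sites == 0:
        logger.warning("zero-length CDS; overlap fraction treated as 0")
        fraction = 0.0
    else:
        fraction = shared / cds_sites
    return OverlapResult(
        cds_sites=cds_sites,
        shared_sites=shared,
        fraction=fraction,
        gene_label=cds.gene_label,
        product_label=cds.product_label,
    )


def validate_ena_record(
    record: SequenceRecord,
    hit: HmmHit,
    overlap_min: float = DEFAULT_OVERLAP_MIN,
    no_cds_policy: str = "keep",
) -> tuple[bool, OverlapResult | None, str]:
    """Decide whether an ENA record's annotation is consistent with the hit.

    Among CDS-key features the one with maximal overlap fraction decides
    (ties: first in feature-table order). The decision is:

    * decisive CDS pseudogene-tagged -> reject, whatever the overlap;
    * fraction >= ``overlap_min`` (inclusive) -> keep;
    * no CDS feature at all -> per ``no_cds_policy`` ("keep" accepts on HMM
      evidence alone, "reject" drops the record).

    Returns (verdict, decisive overlap or None, human-readable reason).
    """
    cds_features = [f for f in record.features if f.feature_key == "CDS"]
    if not cds_features:
        if no_cds_policy == "keep":
            return True, None, "no CDS annotation; kept on HMM evidence"
        return False, None, "no CDS annotation"
    overlaps = [cds_profile_overlap(f, hit) for f in cds_features]
    best_i = max(range(len(overlaps)), key=lambda i: overlaps[i].fraction)
    best_cds, best = cds_features[best_i], overlaps[best_i]
    if best_cds.is_pseudogene:
        return False, best, "pseudogene-tagged CDS"
    if best.fraction >= overlap_min:
        return True, best, f"CDS overlap {best.shared_sites}/{best.cds_sites}"
    return (
        False,
        best,
        f"CDS overlap {best.shared_sites}/{best.cds_sites} = {best.fraction:.4f} < {overlap_min}",
    )


def contributing_synonym_overlaps(
    record: SequenceRecord, hit: HmmHit, overlap_min: float = DEFAULT_OVERLAP_MIN
) -> list[OverlapResult]:
    """Overlaps of all features (CDS or gene) consistent with the profile.

    Every feature whose overlap fraction reaches the threshold contributes
    its labels to the synonym harvest, not just the decisive CDS.
    """
    out = []
    for feat in record.features:
        if feat.is_pseudogene:
            continue
        ov = cds_profile_overlap(feat, hit)
        if ov.fraction >= overlap_min:
            out.append(ov)
    return out


def harvest_synonyms(kept_overlaps: list[OverlapResult]) -> list[str]:
    """Unique, sorted gene/product labels from profile-consistent features.

    Labels are whitespace-trimmed but case-preserving; empty labels are
    dropped. The result is a plain sorted list suitable for a one-column
    TSV.
    """
    labels = set()
    for ov in kept_overlaps:
        for label in (ov.gene_label, ov.product_label):
            if label and label.strip():
                labels.add(label.strip())
    return sorted(labels)
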