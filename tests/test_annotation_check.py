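"""CDS/footprint overlap rule, pseudogene rejection, synonym harvest."""

import pytest

from coiref.annotation_check import (
    cds_profile_overlap,
    contributing_synonym_overlaps,
    harvest_synonyms,
    validate_ena_record,
)
from coiref.io_formats import CdsFeature, SequenceRecord, Source
from coiref.profile_search import HmmHit


def hit(nt_start, nt_end, score=100.0):
    return HmmHit(1, score, 0, (nt_end - nt_start) // 3, nt_start, nt_end)


def ena(features, seq_len=900):
    return SequenceRecord(
        "ACC00001", Source.ENA, "A" * seq_len, accession="ACC00001", features=features
    )


class TestOverlap:
    @pytest.mark.parametrize(
        "cds_span,footprint,shared,fraction",
        [
            ((0, 600), (100, 580), 480, 0.80),      # exactly at threshold
            ((0, 600), (100, 579), 479, 479 / 600),  # one site short
            ((0, 600), (0, 600), 600, 1.0),
        ],
    )
    def test_interval_arithmetic(self, cds_span, footprint, shared, fraction):
        ov = cds_profile_overlap(CdsFeature([cds_span]), hit(*footprint))
        assert ov.cds_sites == 600
        assert ov.shared_sites == shared
        assert ov.fraction == pytest.approx(fraction)

    def test_join_cds_uses_union_of_spans(self):
        ov = cds_profile_overlap(CdsFeature([(0, 30), (60, 90)]), hit(0, 90))
        assert (ov.cds_sites, ov.shared_sites, ov.fraction) == (60, 60, 1.0)

    def test_zero_length_cds_treated_as_zero_fraction(self):
        ov = cds_profile_overlap(CdsFeature([(5, 5)]), hit(0, 90))
        assert ov.fraction == 0.0

    def test_overlap_invariant_under_coordinate_translation(self):
        base = cds_profile_overlap(CdsFeature([(0, 600)]), hit(100, 580))
        for shift in (1, 37, 300):
            moved = cds_profile_overlap(
                CdsFeature([(shift, 600 + shift)]), hit(100 + shift, 580 + shift)
            )
            assert moved.fraction == base.fraction


class TestValidateRecord:
    def test_overlap_at_threshold_keeps(self):
        ok, ov, _ = validate_ena_record(ena([CdsFeature([(100, 700)])]), hit(200, 680))
        assert ok and ov.fraction == pytest.approx(0.8)

    def test_overlap_below_threshold_rejects(self):
        ok, ov, reason = validate_ena_record(ena([CdsFeature([(100, 700)])]), hit(200, 679))
        assert not ok and "overlap" in reason

    def test_pseudogene_rejects_regardless_of_overlap(self):
        feat = CdsFeature([(0, 600)], is_pseudogene=True)
        ok, _, reason = validate_ena_record(ena([feat]), hit(0, 600))
        assert not ok and "pseudogene" in reason

    def test_max_overlap_cds_decides(self):
        low = CdsFeature([(700, 880)])   # 0.0 overlap
        high = CdsFeature([(0, 600)])    # 1.0 overlap
        ok, ov, _ = validate_ena_record(ena([low, high]), hit(0, 600))
        assert ok and ov.fraction == 1.0

    def test_no_cds_policy(self):
        rec = ena([CdsFeature([(0, 90)], feature_key="gene")])
        ok, ov, _ = validate_ena_record(rec, hit(0, 90), no_cds_policy="keep")
        assert ok and ov is None
        ok, _, _ = validate_ena_record(rec, hit(0, 90), no_cds_policy="reject")
        assert not ok


class TestSynonyms:
    def test_unique_sorted_and_trimmed(self):
        recs = [
            ena([CdsFeature([(0, 600)], gene_label=" COI ", product_label="cytochrome oxidase subunit I")]),
            ena([CdsFeature([(0, 600)], gene_label="cox1")]),
            ena([CdsFeature([(0, 600)], gene_label="COI")]),
        ]
        overlaps = [
            ov for r in recs for ov in contributing_synonym_overlaps(r, hit(0, 600))
        ]
        assert harvest_synonyms(overlaps) == ["COI", "cox1", "cytochrome oxidase subunit I"]

    def test_inconsistent_features_do_not_contribute(self):
        rec = ena([CdsFeature([(700, 880)], gene_label="ND5")])  # outside footprint
        assert contributing_synonym_overlaps(rec, hit(0, 600)) == []

    def test_empty_input_yields_empty_list(self):
        assert harvest_synonyms([]) == []

    def test_output_is_subset_of_input_labels(self, pipeline_result, corpus):
        _, manifest = corpus
        allowed = set(manifest.expected_synonyms)
        assert set(pipeline_result.synonyms) <= allowed
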