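"""Seven-rank lineage resolution and the BOLD update report."""

import io

import pytest

from coiref.integrate import MergedRecord
from coiref.io_formats import RANKS, SequenceRecord, Source, read_taxdump
from coiref.taxonomy import (
    LineageResolution,
    lineage_from_taxid,
    resolve_record_lineage,
    taxonomy_update_report,
)


def bold_merged(names, pid="FIX001-21"):
    rec = SequenceRecord(pid, Source.BOLD, "ACGT" * 50, process_id=pid, raw_taxon_names=names)
    return MergedRecord(pid, "BOLD_unique", rec.sequence, [pid], None, rec)


class TestLineageFromTaxid:
    def test_species_taxid_fills_all_seven_ranks(self, store):
        lin = lineage_from_taxid(7227, store)
        assert [lin.names[r] for r in RANKS] == [
            "Metazoa", "Arthropoda", "Insecta", "Diptera",
            "Drosophilidae", "Drosophila", "Drosophila melanogaster",
        ]
        assert lin.taxids["kingdom"] == 33208 and lin.taxids["species"] == 7227

    def test_genus_level_taxid_leaves_species_na(self, store):
        lin = lineage_from_taxid(7215, store)
        assert lin.names["genus"] == "Drosophila"
        assert lin.names["species"] == "NA" and lin.taxids["species"] == "NA"

    def test_absent_taxid_gives_all_na(self, store):
        lin = lineage_from_taxid(987654, store)
        assert all(lin.names[r] == "NA" for r in RANKS)

    def test_filled_ranks_are_ancestors_of_the_query(self, store):
        lin = lineage_from_taxid(7955, store)
        ancestors = set(store.ancestors(7955))
        for rank in RANKS:
            if lin.taxids[rank] != "NA":
                assert lin.taxids[rank] in ancestors


class TestResolveRecord:
    def test_accession_resolution_via_acc2taxid(self, store, pipeline_result):
        both = next(m for m in pipeline_result.merged if m.provenance == "BOTH")
        res = pipeline_result.resolutions[both.record_id]
        assert res.lineage.taxids["species"] != "NA"

    def test_bold_only_lowest_rank_name_lookup(self, store):
        res = resolve_record_lineage(
            bold_merged({"species": "Danio rerio", "genus": "Danio"}), store
        )
        assert res.lineage.taxids["species"] == 7955
        assert res.lineage.names["phylum"] == "Chordata"
        assert not res.changed

    def test_outdated_family_name_reported_as_changed(self, store):
        res = resolve_record_lineage(
            bold_merged({"species": "Drosophila melanogaster", "family": "Oldfamilidae"}), store
        )
        assert res.changed
        assert res.changes == [("family", "Oldfamilidae", "Drosophilidae")]
        assert res.lineage.names["family"] == "Drosophilidae"

    def test_unknown_names_kept_verbatim_with_na_taxids(self, store):
        names = {"phylum": "Imaginophora", "species": "Imaginarius nonexistens"}
        res = resolve_record_lineage(bold_merged(names), store)
        assert res.lineage.names["species"] == "Imaginarius nonexistens"
        assert res.lineage.taxids["species"] == "NA"
        assert res.lineage.names["phylum"] == "Imaginophora"
        assert not res.changed

    def test_homonym_disambiguated_by_higher_ranks(self):
        nodes = io.StringIO(
            "".join(
                "\t|\t".join([str(t), str(p), r, "", "0", "1", "1", "1", "5", "1", "0", "0", ""]) + "\t|\n"
                for t, p, r in [
                    (1, 1, "no rank"), (10, 1, "kingdom"),
                    (20, 10, "phylum"), (21, 10, "phylum"),
                    (30, 20, "genus"), (31, 21, "genus"),
                ]
            )
        )
        names = io.StringIO(
            "".join(
                "\t|\t".join([str(t), n, "", "scientific name"]) + "\t|\n"
                for t, n in [
                    (1, "root"), (10, "Metazoa"), (20, "Mollusca"), (21, "Annelida"),
                    (30, "Duplex"), (31, "Duplex"),
                ]
            )
        )
        st = read_taxdump(nodes, names)
        res = resolve_record_lineage(
            bold_merged({"phylum": "Annelida", "genus": "Duplex"}), st
        )
        assert res.lineage.taxids["genus"] == 31
        # without a disambiguating higher rank the taxid stays NA
        res2 = resolve_record_lineage(bold_merged({"genus": "Duplex"}), st)
        assert res2.lineage.taxids["genus"] == "NA"
        assert res2.lineage.names["genus"] == "Duplex"


class TestUpdateReport:
    def test_counts_distinct_records_and_rows(self, store):
        resolutions = {
            "R1": LineageResolution(lineage_from_taxid(7227, store), []),
            "R2": LineageResolution(
                lineage_from_taxid(7227, store),
                [("family", "Oldfamilidae", "Drosophilidae"), ("genus", "Oldus", "Drosophila")],
            ),
            "R3": LineageResolution(
                lineage_from_taxid(7460, store), [("species", "Apis mellifica", "Apis mellifera")]
            ),
        }
        rows, n_changed = taxonomy_update_report(resolutions)
        assert n_changed == 2
        assert len(rows) == 3
        assert rows[0][0] == "R2"  # sorted by record id

    def test_no_changes_yields_empty_report(self, store):
        rows, n = taxonomy_update_report(
            {"R1": LineageResolution(lineage_from_taxid(7227, store), [])}
        )
        assert rows == [] and n == 0

    def test_corpus_update_count_matches_manifest(self, pipeline_result, corpus):
        _, manifest = corpus
        assert pipeline_result.updated_bold == manifest.expected_updated_bold
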