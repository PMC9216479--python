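"""Genetic codes and six-frame translation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coiref.io_formats import read_taxdump
from coiref.translation import (
    DEFAULT_MITO_TABLE,
    GeneticCode,
    mito_code_for,
    reverse_complement,
    six_frame_translate,
)


@pytest.mark.parametrize("code_id", [1, 2, 5])
def test_gencode_dmp_tables_match_ncbi_reference(corpus, code_id):
    """The ncbieaa strings written to gencode.dmp reproduce the NCBI tables."""
    outdir, _ = corpus
    with open(outdir / "nodes.dmp") as nodes, open(outdir / "names.dmp") as names, open(
        outdir / "gencode.dmp"
    ) as gencode:
        store = read_taxdump(nodes, names, gencode)
    assert store.gencodes[code_id].codon_to_aa == GeneticCode.from_table_id(code_id).codon_to_aa


@pytest.mark.parametrize(
    "codon,code_id,expected",
    [
        ("AGA", 1, "R"),   # arginine in the standard code
        ("AGA", 2, "*"),   # stop in vertebrate mitochondrial
        ("AGA", 5, "S"),   # serine in invertebrate mitochondrial
        ("TGA", 5, "W"),   # mitochondrial tryptophan read-through
        ("ATN", 5, "X"),   # any ambiguity symbol -> X
    ],
)
def test_single_codon_translation(codon, code_id, expected):
    assert GeneticCode.from_table_id(code_id).translate_codon(codon) == expected


class TestSixFrames:
    def test_frame_plus1_of_atggca_is_ma(self):
        frames = six_frame_translate("ATGGCA", GeneticCode.from_table_id(5))
        assert frames[0].frame == 1 and frames[0].peptide == "MA"

    def test_seven_nt_gives_expected_peptide_lengths(self):
        frames = six_frame_translate("ATGGCAT", GeneticCode.from_table_id(1))
        assert [len(f.peptide) for f in frames] == [2, 2, 1, 2, 2, 1]

    def test_too_short_sequence_gives_empty_peptides(self):
        frames = six_frame_translate("AT", GeneticCode.from_table_id(1))
        assert all(f.peptide == "" for f in frames)

    def test_translation_continues_through_stops(self):
        # TAA is a stop in every NCBI table
        frames = six_frame_translate("ATGTAAATG", GeneticCode.from_table_id(5))
        assert frames[0].peptide == "M*M"

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=3, max_size=40))
    def test_reverse_complement_symmetry(self, seq):
        """Frame -k of seq equals frame +k of revcomp(seq)."""
        code = GeneticCode.from_table_id(5)
        fwd = six_frame_translate(seq, code)
        rev = six_frame_translate(reverse_complement(seq), code)
        for k in range(3):
            assert fwd[3 + k].peptide == rev[k].peptide

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=40))
    def test_forward_frames_tile_the_sequence(self, seq):
        """Codons consumed by frames +1..+3 cover every position."""
        covered = set()
        for offset in range(3):
            usable = (len(seq) - offset) // 3 * 3
            covered.update(range(offset, offset + usable))
        assert covered == set(range(len(seq)))


class TestMitoCodeLookup:
    def test_direct_and_inherited_codes(self, store):
        assert mito_code_for(7711, store).code_id == 2    # set on the node
        assert mito_code_for(7955, store).code_id == 2    # inherited from Chordata
        assert mito_code_for(7227, store).code_id == 5    # inherited from Metazoa

    def test_unresolved_taxid_falls_back_to_default(self, store):
        assert mito_code_for("NA", store).code_id == DEFAULT_MITO_TABLE
        assert mito_code_for(None, store).code_id == DEFAULT_MITO_TABLE
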