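"""Plan7-lite Viterbi scorer, frame selection, TC gate, external backend."""

import io
import math
import random

import pytest

from _viterbi_oracle import brute_force_score, random_toy_profile
from coiref.io_formats import read_embl_flatfile
from coiref.profile_search import (
    AMINO_ALPHABET,
    HmmHit,
    best_frame_hit,
    external_backend_parse,
    map_envelope_to_nt,
    passes_tc,
    viterbi_local,
)
from coiref.translation import GeneticCode, reverse_complement, six_frame_translate


class TestViterbiOracle:
    def test_matches_exhaustive_enumeration_on_random_toys(self):
        """DP equals brute-force path enumeration on 300 random instances."""
        rng = random.Random(1)
        for _ in range(300):
            M = rng.randint(1, 3)
            L = rng.randint(1, 4)
            prof = random_toy_profile(rng, M)
            pep = "".join(rng.choice(AMINO_ALPHABET + "X") for _ in range(L))
            score, aa_start, aa_end = viterbi_local(prof, pep)
            assert score == pytest.approx(brute_force_score(prof, pep), abs=1e-9)
            assert 0 <= aa_start < aa_end <= L

    def test_empty_peptide_scores_minus_infinity(self):
        prof = random_toy_profile(random.Random(0), 2)
        score, start, end = viterbi_local(prof, "")
        assert score == -math.inf and start is None and end is None

    def test_local_alignment_is_monotone_under_concatenation(self):
        """Appending residues outside the optimal envelope never hurts."""
        rng = random.Random(2)
        prof = random_toy_profile(rng, 3)
        for _ in range(50):
            pep = "".join(rng.choice(AMINO_ALPHABET) for _ in range(rng.randint(1, 4)))
            extra = rng.choice(AMINO_ALPHABET)
            base, *_ = viterbi_local(prof, pep)
            left, *_ = viterbi_local(prof, extra + pep)
            right, *_ = viterbi_local(prof, pep + extra)
            assert left >= base - 1e-12 and right >= base - 1e-12


class TestFrameSelection:
    def test_envelope_mapping_formulas(self):
        assert map_envelope_to_nt(2, 1, 2, 4, 20) == (7, 13)
        assert map_envelope_to_nt(-1, 0, 0, 2, 20) == (14, 20)

    def test_nt_envelope_is_three_times_aa_envelope(self, profile, corpus):
        outdir, manifest = corpus
        with open(outdir / "ena.dat") as fh:
            records, _ = read_embl_flatfile(fh)
        code = GeneticCode.from_table_id(5)
        rec = records[0]
        hit = best_frame_hit(profile, six_frame_translate(rec.sequence, code), len(rec.sequence))
        assert hit.nt_end - hit.nt_start == 3 * (hit.aa_end - hit.aa_start)

    def test_equal_scores_prefer_forward_frame(self):
        """A reverse-complement palindrome ties frames +k and -k: +1 wins."""
        prof = random_toy_profile(random.Random(3), 2)
        half = "ATGGCAGTT"
        seq = half + reverse_complement(half)
        frames = six_frame_translate(seq, GeneticCode.from_table_id(5))
        assert frames[0].peptide == frames[3].peptide  # genuinely tied inputs
        hit = best_frame_hit(prof, frames, len(seq))
        assert hit.frame == 1

    def test_footprint_localizes_planted_coding_region(self, profile, corpus, store):
        """The hit envelope equals the planted coding block for clean records."""
        outdir, manifest = corpus
        with open(outdir / "ena.dat") as fh:
            records, _ = read_embl_flatfile(fh)
        by_id = {r.record_id: r for r in records}
        code = GeneticCode.from_table_id(5)
        checked = 0
        for plan in manifest.records:
            if plan.category != "clean" or "ENA" not in plan.sources:
                continue
            rec = by_id[plan.record_id]
            hit = best_frame_hit(profile, six_frame_translate(rec.sequence, code), len(rec.sequence))
            (cds,) = [f for f in rec.features if f.feature_key == "CDS"]
            assert (hit.nt_start, hit.nt_end) == (cds.start, cds.end)
            checked += 1
        assert checked >= 3


class TestTrustedCutoff:
    def test_gate_is_inclusive_at_tc(self, profile):
        at = HmmHit(1, 34.0, 0, 10)
        below = HmmHit(1, 33.99, 0, 10)
        assert passes_tc(at, profile)
        assert not passes_tc(below, profile)

    def test_raising_tc_never_accepts_a_rejected_hit(self, profile):
        hit = HmmHit(1, 40.0, 0, 10)
        accepted = [passes_tc(hit, profile, tc_override=tc) for tc in (30, 35, 40, 41, 60)]
        # once rejected, stays rejected as the threshold rises
        assert accepted == sorted(accepted, reverse=True)

    def test_missing_tc_is_an_error(self):
        prof = random_toy_profile(random.Random(0), 2)
        prof.tc = None
        with pytest.raises(ValueError, match="TC"):
            passes_tc(HmmHit(1, 50.0, 0, 2), prof)


DOMTBL = """\
#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name   accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
ACC00001/+2          -            219 COX1_toy     -            200   1e-60   40.1   0.1   1   2   1e-58   1e-55   40.1   0.1     1   200    12   210    12   210  0.98 -
ACC00001/+2          -            219 COX1_toy     -            200   1e-60   40.1   0.1   2   2   1e-10   1e-08   12.5   0.0     1    50   211   218   211   218  0.80 -
ACC00002/-1          -            219 COX1_toy     -            200   1e-20   22.0   0.0   1   1   1e-18   1e-15   22.0   0.0     1   200     5   100     5   100  0.90 -
not a valid row
"""


class TestExternalBackend:
    def test_best_domain_per_query_with_envelope_mapping(self):
        hits = external_backend_parse(io.StringIO(DOMTBL))
        assert set(hits) == {"ACC00001", "ACC00002"}
        assert hits["ACC00001"].score_bits == 40.1
        assert (hits["ACC00001"].aa_start, hits["ACC00001"].aa_end) == (11, 210)
        assert hits["ACC00001"].frame == 2
        assert hits["ACC00002"].frame == -1

    def test_comment_only_stream_yields_empty_map(self):
        assert external_backend_parse(io.StringIO("# nothing\n# here\n")) == {}


class TestPyhmmerCrossCheck:
    """The built-in scorer against HMMER (via pyhmmer) on the same profile.

    The two parameterize local entry/exit differently, so scores agree only
    approximately; the TC verdicts must agree exactly.
    """

    def _pyhmmer_domain_score(self, corpus, peptide, name=b"q"):
        pyhmmer = pytest.importorskip("pyhmmer")
        outdir, _ = corpus
        alph = pyhmmer.easel.Alphabet.amino()
        with pyhmmer.plan7.HMMFile(outdir / "profile.hmm") as hf:
            hmm = hf.read()
        seq = pyhmmer.easel.TextSequence(
            name=name, sequence=peptide.replace("*", "X")
        ).digitize(alph)
        pipe = pyhmmer.plan7.Pipeline(alph, background=pyhmmer.plan7.Background(alph))
        hits = pipe.search_hmm(hmm, pyhmmer.easel.DigitalSequenceBlock(alph, [seq]))
        return max((d.score for h in hits for d in h.domains), default=0.0), hits

    def test_scores_agree_within_band_and_gate_agrees(self, corpus, profile):
        outdir, manifest = corpus
        with open(outdir / "ena.dat") as fh:
            records, _ = read_embl_flatfile(fh)
        by_id = {r.record_id: r for r in records}
        code = GeneticCode.from_table_id(5)

        clean = next(
            p for p in manifest.records if p.category == "clean" and "ENA" in p.sources
        )
        rec = by_id[clean.record_id]
        frames = six_frame_translate(rec.sequence, code)
        hit = best_frame_hit(profile, frames, len(rec.sequence))
        pep = next(f for f in frames if f.frame == hit.frame).peptide
        ext_score, _ = self._pyhmmer_domain_score(corpus, pep)
        assert ext_score >= profile.tc and hit.score_bits >= profile.tc
        assert abs(ext_score - hit.score_bits) / hit.score_bits < 0.15

        noisy = next(p for p in manifest.records if p.category == "low_hmm")
        rec2 = by_id.get(noisy.record_id)
        if rec2 is not None:  # low_hmm may land on the BOLD side
            frames2 = six_frame_translate(rec2.sequence, code)
            hit2 = best_frame_hit(profile, frames2, len(rec2.sequence))
            best_ext = max(
                self._pyhmmer_domain_score(corpus, f.peptide)[0]
                for f in frames2 if f.peptide
            )
            assert best_ext < profile.tc and hit2.score_bits < profile.tc

    def test_domtblout_roundtrip_through_external_parser(self, corpus, profile):
        """pyhmmer's domtblout output is parseable and gates identically."""
        pyhmmer = pytest.importorskip("pyhmmer")
        outdir, manifest = corpus
        with open(outdir / "ena.dat") as fh:
            records, _ = read_embl_flatfile(fh)
        code = GeneticCode.from_table_id(5)
        rec = records[0]
        frames = six_frame_translate(rec.sequence, code)
        hit = best_frame_hit(profile, frames, len(rec.sequence))
        pep = next(f for f in frames if f.frame == hit.frame).peptide
        name = f"{rec.record_id}/{hit.frame:+d}".encode()
        _, hits = self._pyhmmer_domain_score(corpus, pep, name=name)
        buf = io.BytesIO()
        hits.write(buf, format="domains")
        parsed = external_backend_parse(io.StringIO(buf.getvalue().decode()))
        assert rec.record_id in parsed
        ext = parsed[rec.record_id]
        assert ext.frame == hit.frame
        assert passes_tc(ext, profile) == passes_tc(hit, profile)
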