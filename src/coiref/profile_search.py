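"""Profile-HMM screening of translated frames.

Candidate barcode records are accepted only if one of their six conceptual
translations matches the marker's curated profile HMM above the profile's
trusted cutoff (TC) — the bit score above which every known match is a true
positive (HMMER's ``--cut_tc`` gate).

The built-in scorer is a "plan7-lite" local Viterbi over the classic
match/insert/delete profile architecture, in bit space:

* match emissions are log-odds bits against the standard amino-acid
  background; insert emissions come from the profile file (typically equal
  to the background, i.e. 0 bits);
* internal transitions are log2 of the profile's transition probabilities;
* local entry into match state k costs ``log2(2 / (M (M+1)))`` uniformly
  (the classic uniform local-entry distribution); exit is free;
* residues outside the 20-letter alphabet ('X', '*') emit 0 bits
  (background-neutral).

No MSV/bias heuristics, no forward scores, no E-values: the gate is a plain
bit-score threshold, which is what the trusted cutoff defines. Output from
an external ``hmmsearch`` run (domtblout) can be parsed and used
interchangeably via :func:`external_backend_parse`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .translation import FramePeptide

__all__ = [
    "AMINO_ALPHABET",
    "AMINO_BACKGROUND",
    "ProfileHMM",
    "HmmHit",
    "viterbi_local",
    "best_frame_hit",
    "passes_tc",
    "external_backend_parse",
    "map_hit_to_nt",
]

#: Canonical amino-acid column order of HMMER3 profile files.
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Standard amino-acid background frequencies (Swiss-Prot derived; the null
#: model HMMER uses for protein profiles).
AMINO_BACKGROUND = {
    "A": 0.0787945, "C": 0.0151600, "D": 0.0535222, "E": 0.0668298,
    "F": 0.0397062, "G": 0.0695071, "H": 0.0229198, "I": 0.0590092,
    "K": 0.0594422, "L": 0.0963728, "M": 0.0237718, "N": 0.0414386,
    "P": 0.0482904, "Q": 0.0395639, "R": 0.0540978, "S": 0.0683364,
    "T": 0.0540687, "V": 0.0673417, "W": 0.0114135, "Y": 0.0304133,
}

# transition column order in HMMER3 files (indexed by source node)
TRANS_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")

_NEG = -1.0e30  # finite stand-in for log(0); keeps numpy arithmetic NaN-free


@dataclass
class ProfileHMM:
    """A profile HMM in bit space.

    Arrays are indexed by node 1..M (row 0 is unused padding for match
    emissions; transition row 0 holds the begin-state transitions from the
    file, which the uniform-local-entry scorer does not use).
    """

    name: str
    M: int
    match_bits: np.ndarray = field(repr=False)   # (M+1, 20)
    insert_bits: np.ndarray = field(repr=False)  # (M+1, 20)
    trans_bits: np.ndarray = field(repr=False)   # (M+1, 7), TRANS_ORDER
    tc: float | None = None
    ga: float | None = None
    nc: float | None = None
    alphabet: str = AMINO_ALPHABET

    def __post_init__(self) -> None:
        if self.match_bits.shape != (self.M + 1, 20):
            raise ValueError("match emission array has wrong shape")
        if not np.all(np.isfinite(self.match_bits[1:])):
            raise ValueError("non-finite match emission scores")

    @property
    def entry_bits(self) -> float:
        """Uniform local-entry score into any match state."""
        return math.log2(2.0 / (self.M * (self.M + 1)))


@dataclass(frozen=True)
class HmmHit:
    """Best profile match for one record.

    ``aa_start``/``aa_end`` delimit the matched peptide envelope (0-based,
    half-open); ``nt_start``/``nt_end`` are the corresponding coordinates on
    the original forward nucleotide sequence (None until mapped, e.g. for
    hits parsed from an external search).
    """

    frame: int | None
    score_bits: float
    aa_start: int
    aa_end: int
    nt_start: int | None = None
    nt_end: int | None = None


def _residue_indices(peptide: str) -> np.ndarray:
    """Map residues to alphabet columns; -1 flags background-neutral symbols."""
    idx = np.full(len(peptide), -1, dtype=np.int64)
    lookup = {a: i for i, a in enumerate(AMINO_ALPHABET)}
    for i, r in enumerate(peptide):
        idx[i] = lookup.get(r, -1)
    return idx


def viterbi_local(profile: ProfileHMM, peptide: str):
    """Optimal local alignment score of ``peptide`` against ``profile``.

    Returns ``(score_bits, aa_start, aa_end)`` with a 0-based half-open
    envelope, or ``(-inf, None, None)`` for an empty peptide. The score is
    the maximum over all begin/end positions of a plan7 path B -> Mk ...
    Ml -> E, with uniform local entry/exit (see module docstring). Ties are
    broken toward the earliest end position, then the earliest model node,
    then (within a cell) entry > match > insert > delete predecessors.
    """
    L = len(peptide)
    if L == 0:
        return (-math.inf, None, None)
    M = profile.M
    t = np.where(np.isfinite(profile.trans_bits), profile.trans_bits, _NEG)
    tmm, tmi, tmd, tim, tii, tdm, tdd = (t[:, j] for j in range(7))
    em = profile.match_bits
    ins = profile.insert_bits
    entry = profile.entry_bits
    res = _residue_indices(peptide)

    # cumulative delete-chain cost: T[k] = sum_{j<=k} t_dd[j]
    T = np.concatenate(([0.0], np.cumsum(tdd[1:])))
    nodes = np.arange(M + 1)

    vm = np.full(M + 1, _NEG)
    vi = np.full(M + 1, _NEG)
    vd = np.full(M + 1, _NEG)
    sm = np.zeros(M + 1, dtype=np.int64)
    si = np.zeros(M + 1, dtype=np.int64)
    sd = np.zeros(M + 1, dtype=np.int64)

    best = -math.inf
    best_start = 0
    best_end = 0

    for i in range(1, L + 1):
        r = res[i - 1]
        em_vec = em[1:, r] if r >= 0 else np.zeros(M)
        ins_vec = ins[1:, r] if r >= 0 else np.zeros(M)

        # --- match states: entry vs M/I/D predecessors at node k-1, row i-1
        cand = np.stack([
            np.full(M, entry),
            vm[:M] + tmm[:M],
            vi[:M] + tim[:M],
            vd[:M] + tdm[:M],
        ])
        choice = np.argmax(cand, axis=0)  # first max wins -> entry preferred
        starts = np.stack([
            np.full(M, i - 1, dtype=np.int64),
            sm[:M], si[:M], sd[:M],
        ])
        vm_new = np.full(M + 1, _NEG)
        sm_new = np.zeros(M + 1, dtype=np.int64)
        vm_new[1:] = em_vec + np.take_along_axis(cand, choice[None, :], 0)[0]
        sm_new[1:] = np.take_along_axis(starts, choice[None, :], 0)[0]

        # --- insert states (same node, previous row)
        cm = vm[1:] + tmi[1:]
        ci = vi[1:] + tii[1:]
        use_m = cm >= ci
        vi_new = np.full(M + 1, _NEG)
        si_new = np.zeros(M + 1, dtype=np.int64)
        vi_new[1:] = ins_vec + np.where(use_m, cm, ci)
        si_new[1:] = np.where(use_m, sm[1:], si[1:])

        # --- delete states, same row: D_k best over M-exit node j < k via a
        # running max on val[j] = Vm[j] + t_md[j] - T[j]
        val = vm_new + tmd - T
        run = np.maximum.accumulate(val)
        prev_run = np.concatenate(([-np.inf], run[:-1]))
        leader = np.where(val > prev_run, nodes, -1)
        jbest = np.maximum.accumulate(leader)
        vd_new = np.full(M + 1, _NEG)
        sd_new = np.zeros(M + 1, dtype=np.int64)
        vd_new[1:] = run[:M] + T[:M]
        sd_new[1:] = sm_new[np.clip(jbest[:M], 0, M)]

        vm, vi, vd = vm_new, vi_new, vd_new
        sm, si, sd = sm_new, si_new, sd_new

        k = int(np.argmax(vm[1:])) + 1
        if vm[k] > best:
            best = float(vm[k])
            best_start = int(sm[k])
            best_end = i

    return (best, best_start, best_end)


def best_frame_hit(profile: ProfileHMM, frames: list[FramePeptide], seq_len: int) -> HmmHit | None:
    """Score all six frames and return the best hit with nucleotide coordinates.

    Ties are broken by frame order (+1, +2, +3, -1, -2, -3). Returns None if
    every frame is empty (sequence shorter than one codon).
    """
    best: HmmHit | None = None
    for fp in frames:
        score, aa_start, aa_end = viterbi_local(profile, fp.peptide)
        if aa_start is None:
            continue
        if best is None or score > best.score_bits:
            nt_start, nt_end = map_envelope_to_nt(fp.frame, fp.offset, aa_start, aa_end, seq_len)
            best = HmmHit(fp.frame, score, aa_start, aa_end, nt_start, nt_end)
    return best


def map_envelope_to_nt(frame: int, offset: int, aa_start: int, aa_end: int, seq_len: int):
    """Map a peptide envelope to forward-strand nucleotide coordinates.

    Forward frames: ``[offset + 3*aa_start, offset + 3*aa_end)``. Reverse
    frames are mapped on the reverse complement and reflected back:
    ``[L - (offset + 3*aa_end), L - (offset + 3*aa_start))``.
    """
    lo = offset + 3 * aa_start
    hi = offset + 3 * aa_end
    if frame > 0:
        return lo, hi
    return seq_len - hi, seq_len - lo


def map_hit_to_nt(hit: HmmHit, seq_len: int) -> HmmHit:
    """Fill in nucleotide coordinates on a hit whose frame is known."""
    if hit.frame is None:
        return hit
    nt_start, nt_end = map_envelope_to_nt(
        hit.frame, abs(hit.frame) - 1, hit.aa_start, hit.aa_end, seq_len
    )
    return HmmHit(hit.frame, hit.score_bits, hit.aa_start, hit.aa_end, nt_start, nt_end)


def passes_tc(hit: HmmHit, profile: ProfileHMM, tc_override: float | None = None) -> bool:
    """Trusted-cutoff gate: accept iff the bit score reaches TC (inclusive)."""
    tc = tc_override if tc_override is not None else profile.tc
    if tc is None:
        raise ValueError(
            "profile has no TC cutoff; supply one (tc_override / --tc-override) "
            "or use a manual gate mode"
        )
    return hit.score_bits >= tc


_FRAME_SUFFIX = re.compile(r"^(?P<rid>.+)/(?P<frame>[+-][123])$")


def external_backend_parse(stream) -> dict[str, HmmHit]:
    """Parse hmmsearch ``--domtblout`` output into best hits per query sequence.

    Target (sequence) names of the form ``<record_id>/<frame>`` (e.g.
    ``ACC00001/+2``, the convention used when the pipeline exports frame
    peptides for an external search) have the frame recovered; other names
    yield ``frame=None``. For each record the highest-scoring domain wins;
    envelope columns (1-based inclusive) become a 0-based half-open peptide
    envelope. Malformed lines are skipped.
    """
    best: dict[str, HmmHit] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        try:
            target = cols[0]
            score = float(cols[13])
            env_from = int(cols[19])
            env_to = int(cols[20])
        except (IndexError, ValueError):
            continue
        m = _FRAME_SUFFIX.match(target)
        rid = m.group("rid") if m else target
        frame = int(m.group("frame")) if m else None
        hit = HmmHit(frame, score, env_from - 1, env_to)
        prev = best.get(rid)
        if prev is None or hit.score_bits > prev.score_bits:
            best[rid] = hit
    return best
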