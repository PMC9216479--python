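"""Independent brute-force oracle for the plan7-lite local Viterbi score.

Enumerates every legal local path (entry into any match state, exit from
any match state, M/I/D moves in between) recursively and returns the
maximum bit score. Kept deliberately separate from the DP implementation:
only the model parameterization (emissions, transitions, uniform local
entry) is shared, through the ProfileHMM container.
"""

import math
import random

import numpy as np

from coiref.profile_search import AMINO_ALPHABET, AMINO_BACKGROUND, ProfileHMM

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}


def random_toy_profile(rng: random.Random, M: int) -> ProfileHMM:
    """A random, fully finite profile with proper probability rows."""

    def simplex(n):
        xs = [rng.random() + 1e-3 for _ in range(n)]
        s = sum(xs)
        return [x / s for x in xs]

    bg = np.array([AMINO_BACKGROUND[a] for a in AMINO_ALPHABET])
    match = np.zeros((M + 1, 20))
    insert = np.zeros((M + 1, 20))
    trans = np.zeros((M + 1, 7))
    for k in range(M + 1):
        match[k] = np.log2(np.array(simplex(20)) / bg)
        insert[k] = np.log2(np.array(simplex(20)) / bg)
        mm, mi, md = simplex(3)
        im, ii = simplex(2)
        dm, dd = simplex(2)
        trans[k] = np.log2([mm, mi, md, im, ii, dm, dd])
    return ProfileHMM("toy", M, match, insert, trans, tc=0.0)


def brute_force_score(profile: ProfileHMM, peptide: str) -> float:
    """Max over all local path scores by exhaustive enumeration."""
    M, L = profile.M, len(peptide)
    if L == 0:
        return -math.inf

    def em(k, i):
        r = _AA_INDEX.get(peptide[i], -1)
        return profile.match_bits[k][r] if r >= 0 else 0.0

    def iem(k, i):
        r = _AA_INDEX.get(peptide[i], -1)
        return profile.insert_bits[k][r] if r >= 0 else 0.0

    t = profile.trans_bits
    best = -math.inf

    def expand(kind, k, i, score):
        # i is the index of the next unconsumed residue
        nonlocal best
        if kind == "M":
            best = max(best, score)  # exit to E is free from any match state
            if k < M and i < L:
                expand("M", k + 1, i + 1, score + t[k][0] + em(k + 1, i))
            if i < L:
                expand("I", k, i + 1, score + t[k][1] + iem(k, i))
            if k + 1 <= M:
                expand("D", k + 1, i, score + t[k][2])
        elif kind == "I":
            if k < M and i < L:
                expand("M", k + 1, i + 1, score + t[k][3] + em(k + 1, i))
            if i < L:
                expand("I", k, i + 1, score + t[k][4] + iem(k, i))
        else:  # D
            if k < M and i < L:
                expand("M", k + 1, i + 1, score + t[k][5] + em(k + 1, i))
            if k + 1 <= M:
                expand("D", k + 1, i, score + t[k][6])

    for k0 in range(1, M + 1):
        for i0 in range(L):
            expand("M", k0, i0 + 1, profile.entry_bits + em(k0, i0))
    return best
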