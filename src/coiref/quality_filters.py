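"""Sequence-level quality gates and the per-record audit trail.

Gates (all pure predicates; order matters only for the audit trail):

* length window 100 bp - 60 kbp (inclusive), excluding primer dimers and
  nuclear genomes/scaffolds while keeping the longest known mitogenomes;
* terminal-N trimming, then at most five internal ambiguous 'N' bases;
* no stop codon inside the profile-matched envelope of the winning frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .profile_search import HmmHit
from .translation import FramePeptide

__all__ = [
    "FilterConfig",
    "StageResult",
    "CurationDecision",
    "STAGES",
    "length_gate",
    "trim_terminal_n",
    "internal_n_gate",
    "stop_codon_gate",
]

#: Fixed stage order of the curation audit trail.
STAGES = ("length", "hmm", "tc", "annotation", "contamination", "internal_n", "stop_codon")


@dataclass
class FilterConfig:
    """Tunable thresholds of the curation workflow.

    Defaults are the published curation parameters: a 100 nt - 60 000 nt
    length window, at most five internal Ns after terminal-N trimming, an
    80% CDS/footprint overlap requirement and the profile's trusted cutoff
    as HMM gate.
    """

    min_len: int = 100
    max_len: int = 60_000
    max_internal_n: int = 5
    apply_length_to: str = "both"       # "both" | "ENA_only"
    stop_check_scope: str = "envelope"  # "envelope" | "full_frame"
    cds_overlap_min: float = 0.80
    no_cds_policy: str = "keep"         # "keep" | "reject"

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.max_internal_n < 0:
            raise ValueError("max_internal_n must be >= 0")
        if self.apply_length_to not in ("both", "ENA_only"):
            raise ValueError("apply_length_to must be 'both' or 'ENA_only'")
        if self.stop_check_scope not in ("envelope", "full_frame"):
            raise ValueError("stop_check_scope must be 'envelope' or 'full_frame'")


@dataclass(frozen=True)
class StageResult:
    stage: str
    status: str  # "pass" | "fail" | "skipped" | "n/a"
    detail: str = ""


@dataclass
class CurationDecision:
    """Per-record verdict with the ordered list of filter outcomes."""

    record_id: str
    kept: bool
    stage_results: list[StageResult] = field(default_factory=list)

    @property
    def failed_stage(self) -> str | None:
        for sr in self.stage_results:
            if sr.status == "fail":
                return sr.stage
        return None


def length_gate(sequence: str, cfg: FilterConfig) -> bool:
    """Inclusive length-window gate."""
    return cfg.min_len <= len(sequence) <= cfg.max_len


def trim_terminal_n(sequence: str) -> tuple[str, int, int]:
    """Strip maximal leading/trailing runs of 'N'; returns (trimmed, lead, trail).

    An all-N sequence trims to the empty string with the whole run counted
    as leading (left-maximal convention). Idempotent.
    """
    stripped_left = sequence.lstrip("N")
    n_leading = len(sequence) - len(stripped_left)
    trimmed = stripped_left.rstrip("N")
    n_trailing = len(stripped_left) - len(trimmed)
    return trimmed, n_leading, n_trailing


def internal_n_gate(trimmed_sequence: str, cfg: FilterConfig) -> bool:
    """Pass iff the trimmed sequence has at most ``max_internal_n`` Ns.

    Other IUPAC ambiguity codes (R, Y, ...) are not counted. An empty
    trimmed sequence fails (nothing left after trimming).
    """
    if not trimmed_sequence:
        return False
    return trimmed_sequence.count("N") <= cfg.max_internal_n


def stop_codon_gate(hit: HmmHit, frame_peptide: FramePeptide, cfg: FilterConfig) -> bool:
    """Fail iff a stop codon lies in the checked scope of the winning frame.

    Scope "envelope" (default) inspects only the profile-matched peptide
    envelope; "full_frame" inspects the entire frame translation.
    """
    if cfg.stop_check_scope == "full_frame":
        return "*" not in frame_peptide.peptide
    return "*" not in frame_peptide.peptide[hit.aa_start : hit.aa_end]
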