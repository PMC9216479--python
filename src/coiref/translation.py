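"""Six-frame conceptual translation under mitochondrial genetic codes.

Protein-coding barcode markers such as COI are screened at the amino-acid
level, so every nucleotide record is translated in all six reading frames
under the mitochondrial genetic code of its source taxon (NCBI translation
tables; e.g. table 2 for vertebrates, table 5 for invertebrates). Frames are
translated *through* stop codons — localization of the coding region is the
job of the downstream profile search, and the stop-codon filter inspects
only the matched envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "FramePeptide",
    "FRAMES",
    "reverse_complement",
    "six_frame_translate",
    "mito_code_for",
    "DEFAULT_MITO_TABLE",
]

#: NCBI translation table used when a record's taxon cannot be resolved.
#: Table 5 (invertebrate mitochondrial) — the dominant animal barcode phylum
#: is Arthropoda.
DEFAULT_MITO_TABLE = 5

#: Frame labels in canonical order (+1, +2, +3 on the forward strand,
#: -1, -2, -3 on the reverse complement).
FRAMES = (1, 2, 3, -1, -2, -3)

_BASES = "TCAG"
#: The 64 codons in NCBI ``gencode.dmp`` order (first base varies slowest).
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

_COMPLEMENT = str.maketrans(
    "ACGTRYKMBVDHSWN" + "acgtrykmbvdhswn",
    "TGCAYRMKVBHDSWN" + "tgcayrmkvbhdswn",
)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    Parameters
    ----------
    code_id : int
        NCBI translation-table identifier (1 = standard, 2 = vertebrate
        mitochondrial, 5 = invertebrate mitochondrial, ...).
    codon_to_aa : dict
        Mapping of all 64 unambiguous codons to one-letter amino acids,
        with ``'*'`` for stop codons.
    name : str
        Human-readable table name.
    """

    code_id: int
    codon_to_aa: dict[str, str] = field(repr=False)
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.code_id} has {len(self.codon_to_aa)} codons, expected 64"
            )
        if "*" not in self.codon_to_aa.values():
            raise ValueError(f"genetic code {self.code_id} has no stop codon")

    @classmethod
    def from_ncbieaa(cls, code_id: int, ncbieaa: str, name: str = "") -> "GeneticCode":
        """Build from a 64-character ``ncbieaa`` string as found in gencode.dmp."""
        ncbieaa = ncbieaa.strip()
        if len(ncbieaa) != 64:
            raise ValueError(f"ncbieaa string must be 64 characters, got {len(ncbieaa)}")
        return cls(code_id, dict(zip(CODONS, ncbieaa)), name)

    @classmethod
    def from_table_id(cls, code_id: int) -> "GeneticCode":
        """Build from the NCBI tables that ship with Biopython."""
        table = CodonTable.unambiguous_dna_by_id[code_id]
        mapping = dict(table.forward_table)
        for codon in table.stop_codons:
            mapping[codon] = "*"
        return cls(code_id, {c: mapping[c] for c in CODONS}, "; ".join(table.names))

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; any codon with a non-ACGT symbol yields 'X'."""
        return self.codon_to_aa.get(codon, "X")

    def translate(self, sequence: str) -> str:
        """Translate a nucleotide string in frame, through stop codons."""
        n = len(sequence) // 3
        get = self.codon_to_aa.get
        return "".join(get(sequence[3 * i : 3 * i + 3], "X") for i in range(n))


@dataclass(frozen=True)
class FramePeptide:
    """One conceptual translation of a record.

    ``frame`` is +1/+2/+3 for the forward strand and -1/-2/-3 for the
    reverse complement; ``offset`` = abs(frame) - 1 is the number of leading
    nucleotides skipped on the (possibly reverse-complemented) strand.
    """

    frame: int
    offset: int
    peptide: str


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def six_frame_translate(sequence: str, code: GeneticCode) -> list[FramePeptide]:
    """Translate ``sequence`` in all six frames under ``code``.

    Stop codons are rendered ``'*'`` and translation continues through them.
    Sequences shorter than three nucleotides yield six empty peptides.
    """
    rc = reverse_complement(sequence)
    out: list[FramePeptide] = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        strand_seq = sequence if frame > 0 else rc
        out.append(FramePeptide(frame, offset, code.translate(strand_seq[offset:])))
    return out


def mito_code_for(taxid, store, default_table: int = DEFAULT_MITO_TABLE) -> GeneticCode:
    """Mitochondrial genetic code for a taxon, by nearest-ancestor lookup.

    ``store`` is a :class:`coiref.io_formats.TaxonomyStore`. Nodes with an
    unspecified mitochondrial code (0) inherit from their parent; an
    unresolved ``taxid`` (None, "NA", or absent from the store) falls back to
    ``default_table``.
    """
    code_id = None
    if taxid not in (None, "NA", ""):
        code_id = store.mito_gencode_id(int(taxid))
    if not code_id:
        code_id = default_table
    code = store.gencodes.get(code_id)
    if code is None:
        code = GeneticCode.from_table_id(code_id)
    return code
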