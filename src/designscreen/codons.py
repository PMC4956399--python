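"""Genetic-code lookup tables shared across the package.

Amino acids are indexed in the fixed alphabetical order of ``AA_ALPHABET``;
nucleotides in the order A, C, G, T. Codon translation is taken from the
standard genetic code (NCBI table 1) via Biopython.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable, IUPACData

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}
STOP_CHAR = "*"

NT_ALPHABET: str = "ACGT"
NT_INDEX: dict[str, int] = {nt: i for i, nt in enumerate(NT_ALPHABET)}

#: Degenerate-base expansions (IUPAC), e.g. N -> ACGT, K -> GT.
DEGENERATE: dict[str, str] = {
    k: "".join(sorted(v)) for k, v in IUPACData.ambiguous_dna_values.items()
}

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon string -> single-letter amino acid, "*" for stop (64 entries).
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = STOP_CHAR

#: Flat lookup: index 16*b1 + 4*b2 + b3 (A=0,C=1,G=2,T=3) -> amino acid byte.
CODON_AA_FLAT: np.ndarray = np.empty(64, dtype="U1")
for _i in range(64):
    _codon = NT_ALPHABET[_i // 16] + NT_ALPHABET[(_i // 4) % 4] + NT_ALPHABET[_i % 4]
    CODON_AA_FLAT[_i] = CODON_TO_AA[_codon]

#: Fixed most-frequent-codon table (human codon-usage maxima) used for
#: deterministic reverse translation. Every entry translates back to its key.
MOST_FREQUENT_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

#: Synonymous codons per amino acid (for seeded-random reverse translation).
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != STOP_CHAR:
        SYNONYMOUS_CODONS.setdefault(_aa, []).append(_codon)


def translate(nt_seq: str) -> str:
    """Translate an in-frame nucleotide string; stops render as ``*``."""
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} is not a multiple of 3")
    return "".join(CODON_TO_AA[nt_seq[i:i + 3]] for i in range(0, len(nt_seq), 3))


def validate_protein(seq: str, *, name: str = "sequence") -> None:
    """Raise ``ValueError`` if *seq* uses letters outside the 20-aa alphabet."""
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"{name} contains invalid residue(s) {sorted(bad)}: {seq!r}")
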