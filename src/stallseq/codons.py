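"""Standard genetic code and codon-choice tables.

The codon table is hard-coded rather than delegated to an external library so
that translation behaviour (including rendering stops as ``'*'``) is fixed and
auditable.  DNA alphabet only: ``'U'`` is not accepted.
"""

from __future__ import annotations

NUCLEOTIDES = "ACGT"

#: Standard genetic code, DNA codons -> one-letter amino acid, stop = '*'.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Most frequently used human codon per amino acid, used when a designed
#: peptide has to be reverse-translated into a concrete nucleotide sequence.
MOST_FREQUENT_HUMAN_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


def translate(nt_seq: str) -> str:
    """Translate a DNA sequence in frame 0; stops are rendered as ``'*'``.

    Raises
    ------
    ValueError
        If the length is not a multiple of 3 or a codon is not ACGT-only.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} is not a multiple of 3")
    nt_seq = nt_seq.upper()
    try:
        return "".join(CODON_TABLE[nt_seq[i : i + 3]] for i in range(0, len(nt_seq), 3))
    except KeyError as exc:
        raise ValueError(f"invalid codon {exc.args[0]!r} (DNA alphabet A/C/G/T only)") from None


def reverse_translate(peptide: str) -> str:
    """Encode a peptide with the most frequent human codon per residue."""
    try:
        return "".join(MOST_FREQUENT_HUMAN_CODON[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"cannot encode non-standard residue {exc.args[0]!r}") from None
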