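"""Design of the dicodon-repeat reporter libraries and their barcodes.

The main library tiles every ordered codon pair (4096 of them) as a tandem
8× repeat, giving a 48-nt variable insert encoding a 16-residue dipeptide
repeat.  Variant libraries systematically shrink the repeat (padding with a
Ser-Gly linker), scramble its periodicity against the reversed dipeptide, or
combine two dipeptides into 4-residue units.  Barcodes are 24-nt (VNN)×8
sequences, which structurally excludes in-frame stop codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .codons import (
    NUCLEOTIDES,
    STANDARD_AMINO_ACIDS,
    reverse_translate,
    translate,
)

INSERT_LENGTH_NT = 48
REPEATS_MAIN_POOL = 8
BARCODE_LENGTH = 24
BARCODE_CODONS = 8
#: First base of each barcode codon: any nucleotide except T, so no codon can
#: start a stop (TAA/TAG/TGA all begin with T).
V_BASES = "ACG"

#: Ser-Gly linker codon unit used to pad short repeats to 48 nt.
SG_LINKER_UNIT = "AGCGGT"

#: Full reporter coding sequence length (RFP-2A-insert-2A-YFP cassette), nt.
REPORTER_CDS_LENGTH_NT = 1725


@dataclass(frozen=True)
class CodonPairInsert:
    """One dicodon-repeat reporter insert."""

    insert_id: str
    codon1: str
    codon2: str
    n_repeats: int
    nt_seq: str
    peptide: str

    @classmethod
    def from_pair(cls, codon1: str, codon2: str, n_repeats: int = REPEATS_MAIN_POOL) -> "CodonPairInsert":
        if n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        nt_seq = (codon1 + codon2) * n_repeats
        return cls(
            insert_id=f"{codon1}_{codon2}",
            codon1=codon1,
            codon2=codon2,
            n_repeats=n_repeats,
            nt_seq=nt_seq,
            peptide=translate(nt_seq),
        )

    @property
    def dipeptide(self) -> str:
        """The encoded amino-acid pair ('*' marks a stop codon)."""
        return self.peptide[:2]

    @property
    def has_stop(self) -> bool:
        return "*" in self.peptide


@dataclass(frozen=True)
class VariantInsert:
    """A designed variant insert (length series, periodicity, or combination)."""

    insert_id: str
    base_dipeptide: str
    design: str  # length_series | periodicity | combination
    design_param: int
    nt_seq: str

    def __post_init__(self) -> None:
        if len(self.nt_seq) != INSERT_LENGTH_NT:
            raise ValueError(f"variant insert must be {INSERT_LENGTH_NT} nt, got {len(self.nt_seq)}")

    @property
    def peptide(self) -> str:
        return translate(self.nt_seq)


@dataclass(frozen=True)
class Barcode:
    """A 24-nt (VNN)×8 barcode; by construction stop-free in frame 0."""

    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != BARCODE_LENGTH:
            raise ValueError("barcode must be 24 nt")
        for i in range(0, BARCODE_LENGTH, 3):
            codon = self.seq[i : i + 3]
            if codon[0] not in V_BASES or any(b not in NUCLEOTIDES for b in codon):
                raise ValueError(f"codon {codon!r} violates the VNN design")


def enumerate_codon_pairs(n_repeats: int = REPEATS_MAIN_POOL) -> list[CodonPairInsert]:
    """All 4096 ordered codon pairs as tandem-repeat inserts.

    Deterministic lexicographic order over (codon1, codon2) with alphabet
    A < C < G < T.
    """
    codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
    return [
        CodonPairInsert.from_pair(c1, c2, n_repeats)
        for c1, c2 in itertools.product(codons, repeat=2)
    ]


def frameshift_partner(pair: CodonPairInsert, shift: int) -> tuple[str, str]:
    """Codon pair whose in-frame repeat peptide equals the shifted-frame read.

    Reading the infinite (codon1+codon2) repeat with a +``shift`` nucleotide
    offset yields the same periodic peptide as reading, in frame 0, the left
    rotation of the 6-mer by ``shift`` positions re-split into two codons.
    A +3 shift therefore simply swaps the two codons.
    """
    if shift not in (0, 1, 2, 3):
        raise ValueError("shift must be in {0, 1, 2, 3}")
    hexamer = pair.codon1 + pair.codon2
    rotated = hexamer[shift:] + hexamer[:shift]
    return rotated[:3], rotated[3:]


def _check_dipeptide(dipeptide: str) -> None:
    if len(dipeptide) != 2 or any(aa not in STANDARD_AMINO_ACIDS for aa in dipeptide):
        raise ValueError(f"dipeptide must be 2 standard amino acids, got {dipeptide!r}")


def build_variant_series(
    dipeptide: str,
    design: str,
    *,
    repeat_counts: Sequence[int] = tuple(range(1, 9)),
    block_sizes: Sequence[int] = (1, 2, 4, 8),
    combination_units: Sequence[str] | None = None,
) -> list[VariantInsert]:
    """Design a variant insert series for one dipeptide.

    ``length_series``
        One insert per repeat count (default 1–8); the dipeptide block is
        padded 3′ with Ser-Gly linker units to a constant 48 nt.
    ``periodicity``
        Block size *b* lays down *b* tandem dipeptides followed by *b* copies
        of the reversed dipeptide, tiled to 16 residues; block size 8 is the
        pure repeat.  All members share the pure repeat's composition.
    ``combination``
        4× repeats of each supplied 4-residue unit (e.g. "SVKF"); the unit
        must contain the base dipeptide's residues.
    """
    _check_dipeptide(dipeptide)
    unit_nt = reverse_translate(dipeptide)
    out: list[VariantInsert] = []

    if design == "length_series":
        for n in repeat_counts:
            if not 1 <= n <= REPEATS_MAIN_POOL:
                raise ValueError("repeat count must be between 1 and 8")
            pad_units = REPEATS_MAIN_POOL - n
            nt_seq = unit_nt * n + SG_LINKER_UNIT * pad_units
            out.append(VariantInsert(f"{dipeptide}_length_series_{n}", dipeptide, design, n, nt_seq))
    elif design == "periodicity":
        for b in block_sizes:
            if b not in (1, 2, 4, 8):
                raise ValueError("block size must be 1, 2, 4, or 8")
            peptide_units = (dipeptide * b + dipeptide[::-1] * b) * (REPEATS_MAIN_POOL // (2 * b) or 1)
            peptide = peptide_units[: 2 * REPEATS_MAIN_POOL]
            nt_seq = reverse_translate(peptide)
            out.append(VariantInsert(f"{dipeptide}_periodicity_{b}", dipeptide, design, b, nt_seq))
    elif design == "combination":
        if not combination_units:
            raise ValueError("combination design requires combination_units")
        for i, unit in enumerate(combination_units, start=1):
            if len(unit) != 4:
                raise ValueError(f"combination unit must be 4 residues, got {unit!r}")
            nt_seq = reverse_translate(unit * 4)
            out.append(VariantInsert(f"{dipeptide}_combination_{i}", dipeptide, design, i, nt_seq))
    else:
        raise ValueError(f"unknown design {design!r}")
    return out


def generate_barcode(rng: np.random.Generator) -> Barcode:
    """Draw one barcode uniformly from the (VNN)×8 space (48⁸ sequences)."""
    codons = []
    v = rng.integers(0, 3, size=BARCODE_CODONS)
    nn = rng.integers(0, 4, size=(BARCODE_CODONS, 2))
    for i in range(BARCODE_CODONS):
        codons.append(V_BASES[v[i]] + NUCLEOTIDES[nn[i, 0]] + NUCLEOTIDES[nn[i, 1]])
    return Barcode("".join(codons))


def generate_distinct_barcodes(n: int, rng: np.random.Generator) -> list[Barcode]:
    """Draw ``n`` distinct barcodes (rejection sampling; space is 48⁸)."""
    seen: set[str] = set()
    out: list[Barcode] = []
    while len(out) < n:
        bc = generate_barcode(rng)
        if bc.seq not in seen:
            seen.add(bc.seq)
            out.append(bc)
    return out


def write_library_fasta(inserts: Iterable[CodonPairInsert | VariantInsert], path: str | Path) -> None:
    """Export insert sequences as FASTA (record id = insert_id)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(ins.nt_seq), id=ins.insert_id, description="") for ins in inserts]
    seqio_write(records, str(path), "fasta")


def library_manifest(inserts: Sequence[CodonPairInsert | VariantInsert]):
    """TSV-ready manifest of the library design."""
    import pandas as pd

    rows = []
    for ins in inserts:
        row = {"insert_id": ins.insert_id, "nt_seq": ins.nt_seq, "peptide": ins.peptide}
        if isinstance(ins, CodonPairInsert):
            row.update(codon1=ins.codon1, codon2=ins.codon2, n_repeats=ins.n_repeats,
                       design="dicodon_pool", design_param=ins.n_repeats)
        else:
            row.update(codon1="", codon2="", n_repeats=np.nan,
                       design=ins.design, design_param=ins.design_param)
        rows.append(row)
    return pd.DataFrame(rows)
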