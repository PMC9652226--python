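"""Destabilizing-dipeptide scoring and proteome-wide motif scanning.

A *destabilizing dipeptide* is an adjacent residue pair combining a
positively charged residue (K or R) with a bulky one (L, V, I, Y, or F), in
either order; each such pair scores 1, and each pair of overlapping
destabilizing dipeptides (sharing a residue) adds a bonus of 1.  Under this
default "per-pair" bonus a run of L consecutive destabilizing dipeptides
contributes L + (L−1); an alternative "per-cluster" mode awards a flat +1
per overlapping run.  Scanning a coding sequence takes, per protein, the
16-residue window with the maximum score (leftmost on ties); windows scoring
above 9 are classified as destabilizing motifs, below 3 as controls.

The reordering mutant design disrupts destabilizing dipeptides without
changing composition: all codons encoding K/R move to the 5' end of the
motif and all codons encoding L/V/I/Y/F move to the 3' end, each block
preserving its internal order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .codons import STANDARD_AMINO_ACIDS, translate

#: Positively charged partners of the destabilizing dipeptide.
CHARGED = frozenset("KR")
#: Bulky partners of the destabilizing dipeptide (scan definition).
BULKY = frozenset("LVIYF")

WINDOW_LENGTH = 16
DESTABILIZING_THRESHOLD = 9  # score > 9
CONTROL_THRESHOLD = 3  # score < 3

_STANDARD = frozenset(STANDARD_AMINO_ACIDS)


def _is_destabilizing_pair(a: str, b: str) -> bool:
    return (a in CHARGED and b in BULKY) or (a in BULKY and b in CHARGED)


def peptide_score(window: str, overlap_mode: str = "per_pair") -> int:
    """Destabilizing-dipeptide score of a peptide.

    Score = D + O where D counts adjacent positions forming a charged-bulky
    pair and O counts overlap bonuses (per overlapping pair of dipeptides by
    default, per overlapping cluster with ``overlap_mode="per_cluster"``).

    Raises on non-standard residues; callers scanning real proteomes should
    skip such windows.
    """
    bad = set(window) - _STANDARD
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in window")
    if overlap_mode not in ("per_pair", "per_cluster"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    hits = [_is_destabilizing_pair(window[i], window[i + 1]) for i in range(len(window) - 1)]
    D = sum(hits)
    if overlap_mode == "per_pair":
        O = sum(1 for i in range(len(hits) - 1) if hits[i] and hits[i + 1])
    else:
        O = 0
        run = 0
        for h in hits + [False]:
            if h:
                run += 1
            else:
                if run >= 2:
                    O += 1
                run = 0
    return D + O


@dataclass(frozen=True)
class PeptideMotif:
    """The maximum-scoring window of one coding sequence."""

    gene_id: str
    window_start: int  # 1-based residue index, inclusive
    window_seq: str
    score: int

    @property
    def motif_class(self) -> str:
        if self.score > DESTABILIZING_THRESHOLD:
            return "destabilizing"
        if self.score < CONTROL_THRESHOLD:
            return "control"
        return "neither"


def max_scoring_window(
    protein: str,
    window: int = WINDOW_LENGTH,
    overlap_mode: str = "per_pair",
) -> tuple[int, str, int] | None:
    """Leftmost maximum-scoring window of one protein (1-based start).

    Windows containing non-standard residues are not scored; returns None
    when the protein is shorter than the window or no window is scorable.
    """
    protein = protein.rstrip("*")
    n = len(protein)
    if n < window:
        return None
    best: tuple[int, str, int] | None = None
    for start in range(n - window + 1):
        seq = protein[start : start + window]
        if set(seq) - _STANDARD:
            continue
        s = peptide_score(seq, overlap_mode)
        if best is None or s > best[2]:
            best = (start + 1, seq, s)
    return best


def scan_proteome(
    proteins: Iterable[tuple[str, str]] | str | Path,
    *,
    window: int = WINDOW_LENGTH,
    overlap_mode: str = "per_pair",
    is_cds: bool = False,
) -> tuple[list[PeptideMotif], int]:
    """Max-window scan over a proteome.

    ``proteins`` is an iterable of (gene_id, sequence) or a FASTA path.
    Sequences may be protein (default) or nucleotide CDS (``is_cds=True``,
    translated with the standard code; length must be divisible by 3).
    Terminal stop symbols are stripped.  Returns the motif list and the
    number of sequences skipped as shorter than the window.
    """
    if isinstance(proteins, (str, Path)):
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(proteins), "fasta")]
    else:
        records = list(proteins)
    if not records:
        raise ValueError("no sequences to scan")
    motifs: list[PeptideMotif] = []
    skipped = 0
    for gene_id, seq in records:
        if is_cds:
            seq = translate(seq)
        hit = max_scoring_window(seq, window=window, overlap_mode=overlap_mode)
        if hit is None:
            skipped += 1
            continue
        start, win_seq, score = hit
        motifs.append(PeptideMotif(gene_id, start, win_seq, score))
    return motifs, skipped


def motifs_to_frame(motifs: Sequence[PeptideMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.gene_id, m.window_start, m.window_seq, m.score, m.motif_class)
            for m in motifs
        ],
        columns=["gene_id", "window_start", "window_seq", "score", "class"],
    )


@dataclass(frozen=True)
class ReorderedMutant:
    """Composition-preserving reordering that disrupts destabilizing pairs."""

    wt_codons: tuple[str, ...]
    mut_codons: tuple[str, ...]

    @property
    def peptide_wt(self) -> str:
        return translate("".join(self.wt_codons))

    @property
    def peptide_mut(self) -> str:
        return translate("".join(self.mut_codons))


def design_reordered_mutant(wt_codons: Sequence[str]) -> ReorderedMutant:
    """Move K/R codons to the 5' end and L/V/I/Y/F codons to the 3' end.

    The three blocks (charged, other, bulky) each preserve the relative
    order of their member codons, so the codon multiset is unchanged.
    """
    charged, other, bulky = [], [], []
    for codon in wt_codons:
        aa = translate(codon)
        if aa == "*":
            raise ValueError(f"stop codon {codon!r} in motif")
        if aa in CHARGED:
            charged.append(codon)
        elif aa in BULKY:
            bulky.append(codon)
        else:
            other.append(codon)
    return ReorderedMutant(tuple(wt_codons), tuple(charged + other + bulky))


def mutants_to_frame(pairs: Sequence[tuple[str, ReorderedMutant]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (gid, " ".join(m.wt_codons), " ".join(m.mut_codons), m.peptide_wt, m.peptide_mut)
            for gid, m in pairs
        ],
        columns=["gene_id", "wt_codons", "mut_codons", "wt_peptide", "mut_peptide"],
    )
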