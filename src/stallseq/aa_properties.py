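"""Amino-acid physicochemical scales and secondary-structure classification.

Scales shipped with the package (``data/aa_scales.tsv``):

* ``pI`` — isoelectric point of the free amino acid (pH units); high values
  mark positively charged residues (Zimmerman scale).
* ``bulkiness`` — ratio of side-chain volume to length in Å² (Zimmerman
  scale); residues above 18 Å² are called *bulky*.
* ``cf_helix`` / ``cf_strand`` — Chou–Fasman α-helix / β-strand propensities
  (dimensionless, empirical occurrence ratios).

Per-residue secondary-structure probability profiles (the output format of a
neural-network predictor such as S4PRED) are consumed from TSV and classified
by a strict >0.5 mean-probability rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import STANDARD_AMINO_ACIDS

BULKY_THRESHOLD = 18.0  # Å²; side-chain volume/length above this is "bulky"

_SCALE_NAMES = ("pI", "bulkiness", "cf_helix", "cf_strand")


def _load_scales() -> pd.DataFrame:
    with resources.files("stallseq.data").joinpath("aa_scales.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("aa")
    if set(df.index) != set(STANDARD_AMINO_ACIDS):
        raise RuntimeError("aa_scales.tsv does not cover exactly the 20 standard amino acids")
    return df


SCALES: pd.DataFrame = _load_scales()

#: Residues whose Zimmerman bulkiness exceeds 18 Å² (I, L, F, W, Y, V).
BULKY_AMINO_ACIDS = frozenset(SCALES.index[SCALES["bulkiness"] > BULKY_THRESHOLD])

#: Positively charged residues (lysine, arginine).
POSITIVELY_CHARGED = frozenset("KR")


def scale_value(aa: str, scale: str) -> float:
    """Look up one residue in one scale; rejects non-standard residues."""
    if scale not in _SCALE_NAMES:
        raise ValueError(f"unknown scale {scale!r}; choose from {_SCALE_NAMES}")
    if aa not in SCALES.index:
        raise ValueError(f"non-standard residue {aa!r}")
    return float(SCALES.at[aa, scale])


def mean_scale(peptide: str, scale: str) -> float:
    """Arithmetic mean of a physicochemical scale over a peptide.

    Parameters
    ----------
    peptide:
        Non-empty string of standard one-letter amino acids.
    scale:
        One of ``pI``, ``bulkiness``, ``cf_helix``, ``cf_strand``.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    return float(np.mean([scale_value(aa, scale) for aa in peptide]))


@dataclass(frozen=True)
class StructureProfile:
    """Per-residue 3-state secondary-structure probabilities for a peptide."""

    peptide: str
    p_helix: np.ndarray
    p_strand: np.ndarray
    p_coil: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.peptide)
        for name in ("p_helix", "p_strand", "p_coil"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (n,):
                raise ValueError(f"{name} has length {v.shape}, expected ({n},)")
        total = self.p_helix + self.p_strand + self.p_coil
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("per-residue probabilities must sum to 1 (tolerance 1e-6)")

    @classmethod
    def from_two_state(cls, peptide: str, p_helix, p_strand) -> "StructureProfile":
        """Build from a 2-state predictor; the remainder is assigned to coil."""
        p_helix = np.asarray(p_helix, dtype=float)
        p_strand = np.asarray(p_strand, dtype=float)
        return cls(peptide, p_helix, p_strand, 1.0 - p_helix - p_strand)


def classify_structure(profile: StructureProfile) -> str:
    """Call a peptide *helix*, *strand*, or *other*.

    A peptide is classified as helix (strand) when its mean per-residue helix
    (strand) probability is strictly greater than 0.5; the normalisation
    constraint makes the two calls mutually exclusive.  Everything else is
    *other*.
    """
    if float(np.mean(profile.p_helix)) > 0.5:
        return "helix"
    if float(np.mean(profile.p_strand)) > 0.5:
        return "strand"
    return "other"


def read_structure_profiles(path: str | Path) -> dict[str, StructureProfile]:
    """Read per-residue structure probabilities from TSV.

    Expected columns: ``peptide_id, position, residue, p_helix, p_strand,
    p_coil`` (``p_coil`` optional; the remainder of 1 is used when absent).
    Positions are 1-based and must be contiguous per peptide.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "position", "residue", "p_helix", "p_strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"structure profile TSV missing columns: {sorted(missing)}")
    profiles: dict[str, StructureProfile] = {}
    for pid, grp in df.groupby("peptide_id", sort=False):
        grp = grp.sort_values("position")
        if list(grp["position"]) != list(range(1, len(grp) + 1)):
            raise ValueError(f"positions for {pid!r} are not contiguous from 1")
        peptide = "".join(grp["residue"])
        p_h = grp["p_helix"].to_numpy(float)
        p_s = grp["p_strand"].to_numpy(float)
        if "p_coil" in grp.columns:
            profiles[pid] = StructureProfile(peptide, p_h, p_s, grp["p_coil"].to_numpy(float))
        else:
            profiles[pid] = StructureProfile.from_two_state(peptide, p_h, p_s)
    return profiles
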