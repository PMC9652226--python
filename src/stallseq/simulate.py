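"""Synthetic sequencing data for the reporter assay.

Every input the analysis pipeline consumes can be generated here under a
stated generative model, with ground-truth sidecar tables, so the whole
pipeline is testable end to end without any external sequencing data.

Generative model
----------------
Each insert's true log2 mRNA level is a linear function of the mean
isoelectric point, bulkiness, their interaction, and the mean Chou–Fasman
β-strand propensity of its encoded dipeptide, plus a fixed log2 penalty for
stop-containing inserts (premature termination channels into
nonsense-mediated decay) and Gaussian insert-level noise::

    level = b_pI·pI̅ + b_bulk·bulk̅ + b_int·pI̅·bulk̅ + b_strand·strand̅
            + stop_penalty·1[stop] + N(0, noise_sd)

Counts are drawn with Dirichlet-multinomial overdispersion around equal
genomic representation; mRNA abundance multiplies the genomic proportion of
each barcode by 2^level of its insert, so the log2 mRNA/gDNA ratio is the
estimand.  Sorted (low-reporter-fluorescence) samples weight barcodes by the
insert's premature-termination probability; transcription-shutoff timecourse
samples decay each insert exponentially by its half-life against a
constant-abundance spike-in barcode set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aa_properties import mean_scale
from .codons import NUCLEOTIDES
from .reporter_library import (
    BARCODE_LENGTH,
    CodonPairInsert,
    VariantInsert,
    generate_distinct_barcodes,
)

# Fixed flanking context of linkage reads: 5' flank + 48-nt insert + spacer +
# 24-nt barcode + 3' flank.  Offsets are part of the declared read layout.
LINKAGE_FLANK5 = "GGCC"
LINKAGE_SPACER = "TCTAGA"
LINKAGE_FLANK3 = "AAGG"
LINKAGE_INSERT_OFFSET = len(LINKAGE_FLANK5)
LINKAGE_BARCODE_OFFSET = LINKAGE_INSERT_OFFSET + 48 + len(LINKAGE_SPACER)

#: Transcription-shutoff sampling times (hours).
DEFAULT_TIMEPOINTS_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)

_PHRED = "I"  # constant quality; quality modelling is out of scope

_BASE_TO_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass
class GenerativeModel:
    """Simulation truth for insert-level mRNA effects.

    Default coefficients are the physicochemical model used throughout the
    package (log2 scale, raw Zimmerman / Chou–Fasman feature units).
    """

    beta_pI: float = 0.31
    beta_bulk: float = 0.20
    beta_inter: float = -0.03
    beta_strand: float = -0.52
    noise_sd: float = 0.5
    stop_penalty: float = -2.0
    term_prob_map: dict[str, float] = field(default_factory=dict)
    halflife_map: dict[str, float] = field(default_factory=dict)
    #: termination probability for inserts absent from term_prob_map
    default_term_prob: float = 0.05
    #: half-life (hours) for inserts absent from halflife_map
    default_halflife_h: float = 4.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(not 0 <= p <= 1 for p in self.term_prob_map.values()):
            raise ValueError("termination probabilities must lie in [0, 1]")
        if any(h <= 0 for h in self.halflife_map.values()):
            raise ValueError("half-lives must be positive")

    def term_prob(self, insert_id: str) -> float:
        return self.term_prob_map.get(insert_id, self.default_term_prob)

    def halflife(self, insert_id: str) -> float:
        return self.halflife_map.get(insert_id, self.default_halflife_h)


@dataclass
class ReadSet:
    """A simulated sample: fixed-layout reads plus its identity."""

    sample_id: str
    layout: str  # "linkage" | "barcode_only"
    sequences: list[str]

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences):
                fh.write(f"@{self.sample_id}_{i}\n{seq}\n+\n{_PHRED * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path: str | Path, sample_id: str, layout: str = "barcode_only") -> "ReadSet":
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        with open(path) as fh:
            seqs = [seq for _, seq, _ in FastqGeneralIterator(fh)]
        return cls(sample_id, layout, seqs)


def _seqs_to_matrix(seqs: Sequence[str]) -> np.ndarray:
    joined = "".join(seqs).encode()
    n = len(seqs)
    return np.frombuffer(joined, dtype=np.uint8).reshape(n, -1).copy()


def _matrix_to_seqs(mat: np.ndarray) -> list[str]:
    width = mat.shape[1]
    raw = mat.tobytes().decode()
    return [raw[i : i + width] for i in range(0, len(raw), width)]


def _apply_substitution_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform per-base substitutions; errors never silently reproduce the base."""
    if error_rate <= 0:
        return mat
    idx_of = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_TO_IDX.items():
        idx_of[ord(b)] = i
    codes = idx_of[mat]
    mask = rng.random(mat.shape) < error_rate
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    new_codes = (codes[mask] + shifts) % 4
    lut = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
    out = mat.copy()
    out[mask] = lut[new_codes]
    return out


def _insert_features(insert: CodonPairInsert | VariantInsert) -> tuple[float, float, float, bool]:
    """(mean pI, mean bulkiness, mean strand propensity, has stop) of the dipeptide."""
    peptide = insert.peptide
    dipeptide = peptide[:2]
    has_stop = "*" in peptide
    standard = dipeptide.replace("*", "")
    if not standard:
        return 0.0, 0.0, 0.0, has_stop
    return (
        mean_scale(standard, "pI"),
        mean_scale(standard, "bulkiness"),
        mean_scale(standard, "cf_strand"),
        has_stop,
    )


def simulate_true_levels(
    inserts: Sequence[CodonPairInsert | VariantInsert],
    model: GenerativeModel,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw each insert's true log2 mRNA level under the generative model.

    Physicochemical features are mean scale values over the insert's
    dipeptide; for stop-containing dipeptides they are computed over the
    standard residues only (zero when both positions are stops), with the
    stop penalty carrying the termination effect.
    """
    levels: dict[str, float] = {}
    noise = rng.normal(0.0, model.noise_sd, size=len(inserts)) if model.noise_sd > 0 else np.zeros(len(inserts))
    for i, ins in enumerate(inserts):
        pI, bulk, strand, has_stop = _insert_features(ins)
        level = (
            model.beta_pI * pI
            + model.beta_bulk * bulk
            + model.beta_inter * pI * bulk
            + model.beta_strand * strand
            + (model.stop_penalty if has_stop else 0.0)
            + noise[i]
        )
        levels[ins.insert_id] = float(level)
    return levels


def draw_barcodes_per_insert(
    n_inserts: int,
    rng: np.random.Generator,
    median: int = 15,
    minimum: int = 1,
) -> np.ndarray:
    """Truncated-geometric barcode counts with the configured median.

    Geometric on {1, 2, ...} with P(X <= k) = 1 - q^k; q is set so the CDF
    crosses 0.5 strictly between median−1 and median (half-step correction,
    q = 0.5^(1/(median−0.5))), making ``median`` the unambiguous population
    median.  Counts below ``minimum`` are impossible by construction of the
    support.
    """
    if median < 2:
        return np.full(n_inserts, max(1, minimum), dtype=int)
    q = 0.5 ** (1.0 / (median - 0.5))
    u = rng.random(n_inserts)
    counts = minimum + np.floor(np.log(u) / np.log(q)).astype(int)
    return counts


def simulate_linkage_reads(
    inserts: Sequence[CodonPairInsert | VariantInsert],
    rng: np.random.Generator,
    *,
    barcodes_per_insert: int | None = None,
    median_barcodes: int = 15,
    reads_per_barcode: float = 10.0,
    read_count_model: str = "poisson",
    error_rate: float = 0.001,
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate insert-barcode linkage sequencing.

    Each insert receives a number of distinct barcodes (fixed when
    ``barcodes_per_insert`` is given, otherwise truncated-geometric with
    median 15); each (insert, barcode) pair emits Poisson or fixed read
    counts; reads carry uniform substitution errors.

    Returns the read set and the ground-truth table
    (insert_id, barcode, true_reads).
    """
    n = len(inserts)
    if barcodes_per_insert is not None:
        bc_counts = np.full(n, int(barcodes_per_insert))
    else:
        bc_counts = draw_barcodes_per_insert(n, rng, median=median_barcodes)
    all_barcodes = generate_distinct_barcodes(int(bc_counts.sum()), rng)

    rows = []
    pos = 0
    for ins, k in zip(inserts, bc_counts):
        for bc in all_barcodes[pos : pos + k]:
            rows.append((ins.insert_id, bc.seq, ins.nt_seq))
        pos += k
    truth = pd.DataFrame(rows, columns=["insert_id", "barcode", "nt_seq"])

    if read_count_model == "poisson":
        read_counts = rng.poisson(reads_per_barcode, size=len(truth))
    elif read_count_model == "fixed":
        read_counts = np.full(len(truth), int(round(reads_per_barcode)))
    else:
        raise ValueError(f"unknown read_count_model {read_count_model!r}")
    truth = truth.assign(true_reads=read_counts)

    templates = [
        LINKAGE_FLANK5 + nt + LINKAGE_SPACER + bc + LINKAGE_FLANK3
        for nt, bc in zip(truth["nt_seq"], truth["barcode"])
    ]
    if templates:
        mat = _seqs_to_matrix(templates)
        mat = np.repeat(mat, read_counts, axis=0)
        mat = _apply_substitution_errors(mat, error_rate, rng)
        seqs = _matrix_to_seqs(mat)
    else:
        seqs = []
    truth = truth.drop(columns="nt_seq")
    return ReadSet("linkage", "linkage", seqs), truth


def _base_proportions(n: int, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Barcode representation around equality; Dirichlet with conc. 1/dispersion."""
    if dispersion <= 0:
        return np.full(n, 1.0 / n)
    return rng.dirichlet(np.full(n, 1.0 / dispersion))


def _reads_from_counts(
    barcodes: Sequence[str],
    counts: np.ndarray,
    sample_id: str,
    error_rate: float,
    rng: np.random.Generator,
) -> ReadSet:
    if counts.sum() == 0:
        return ReadSet(sample_id, "barcode_only", [])
    mat = _seqs_to_matrix(list(barcodes))
    mat = np.repeat(mat, counts, axis=0)
    mat = _apply_substitution_errors(mat, error_rate, rng)
    return ReadSet(sample_id, "barcode_only", _matrix_to_seqs(mat))


def simulate_count_reads(
    truth_levels: Mapping[str, float],
    barcode_map: pd.DataFrame,
    rng: np.random.Generator,
    *,
    gdna_depth: int = 2_000_000,
    mrna_depth: int = 2_000_000,
    dispersion: float = 0.2,
    error_rate: float = 0.001,
) -> tuple[ReadSet, ReadSet, pd.DataFrame]:
    """Simulate barcode-only gDNA and mRNA samples.

    Genomic barcode abundances are drawn overdispersed around equal
    representation; mRNA abundance of each barcode is its genomic proportion
    times 2^(true level) of its insert, so the log2 mRNA/gDNA count ratio
    recovers the true levels (up to the library median shift).

    Returns (gdna_reads, mrna_reads, truth table with per-barcode counts).
    """
    barcodes = barcode_map["barcode"].tolist()
    insert_ids = barcode_map["insert_id"].tolist()
    n = len(barcodes)
    if n == 0:
        raise ValueError("barcode map is empty")
    p = _base_proportions(n, dispersion, rng)
    levels = np.array([truth_levels[i] for i in insert_ids])
    w = p * np.exp2(levels)
    w /= w.sum()

    gdna_counts = rng.multinomial(int(gdna_depth), p)
    mrna_counts = rng.multinomial(int(mrna_depth), w) if mrna_depth > 0 else np.zeros(n, dtype=int)

    sidecar = pd.DataFrame(
        {
            "barcode": barcodes,
            "insert_id": insert_ids,
            "gdna_true_count": gdna_counts,
            "mrna_true_count": mrna_counts,
        }
    )
    gdna = _reads_from_counts(barcodes, gdna_counts, "gdna", error_rate, rng)
    mrna = _reads_from_counts(barcodes, mrna_counts, "mrna", error_rate, rng)
    return gdna, mrna, sidecar


def simulate_sorted_reads(
    model: GenerativeModel,
    barcode_map: pd.DataFrame,
    rng: np.random.Generator,
    *,
    depth: int = 1_000_000,
    dispersion: float = 0.2,
    error_rate: float = 0.001,
) -> tuple[ReadSet, ReadSet, pd.DataFrame]:
    """Simulate low-fluorescence sorted and unsorted gDNA barcode samples.

    Sorted-sample weights multiply each barcode's genomic proportion by its
    insert's premature-termination probability, so terminating inserts enrich
    in the sorted gate.
    """
    barcodes = barcode_map["barcode"].tolist()
    insert_ids = barcode_map["insert_id"].tolist()
    n = len(barcodes)
    p = _base_proportions(n, dispersion, rng)
    term = np.array([model.term_prob(i) for i in insert_ids])
    w = p * term
    if w.sum() == 0:
        raise ValueError("all termination probabilities are zero")
    w /= w.sum()
    unsorted_counts = rng.multinomial(int(depth), p)
    sorted_counts = rng.multinomial(int(depth), w)
    sidecar = pd.DataFrame(
        {
            "barcode": barcodes,
            "insert_id": insert_ids,
            "unsorted_true_count": unsorted_counts,
            "sorted_true_count": sorted_counts,
            "term_prob": term,
        }
    )
    unsorted = _reads_from_counts(barcodes, unsorted_counts, "unsorted", error_rate, rng)
    low_yfp = _reads_from_counts(barcodes, sorted_counts, "low_yfp", error_rate, rng)
    return low_yfp, unsorted, sidecar


def simulate_timecourse_reads(
    model: GenerativeModel,
    barcode_map: pd.DataFrame,
    rng: np.random.Generator,
    *,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
    depth_per_timepoint: int = 1_000_000,
    spikein_size: int = 200,
    dispersion: float = 0.2,
    error_rate: float = 0.001,
) -> tuple[dict[float, ReadSet], pd.DataFrame, list[str]]:
    """Simulate a transcription-shutoff decay timecourse with spike-ins.

    Library barcode abundance decays as 0.5^(t/half-life) of its insert; a
    set of external spike-in barcodes keeps constant absolute abundance and
    anchors cross-timepoint normalization.

    Returns ({timepoint: reads}, truth table, spike-in barcode list).
    """
    if not timepoints_h or timepoints_h[0] != 0:
        raise ValueError("timepoints must start at 0")
    barcodes = barcode_map["barcode"].tolist()
    insert_ids = barcode_map["insert_id"].tolist()
    n = len(barcodes)
    p = _base_proportions(n, dispersion, rng)
    spike = [b.seq for b in generate_distinct_barcodes(spikein_size, rng)]
    spike = [b for b in spike if b not in set(barcodes)]
    spike_abund = np.full(len(spike), p.mean())

    halflife = np.array([model.halflife(i) for i in insert_ids])
    readsets: dict[float, ReadSet] = {}
    rows = []
    all_bc = barcodes + spike
    for t in timepoints_h:
        abund = np.concatenate([p * 0.5 ** (t / halflife), spike_abund])
        counts = rng.multinomial(int(depth_per_timepoint), abund / abund.sum())
        readsets[float(t)] = _reads_from_counts(all_bc, counts, f"t{t}", error_rate, rng)
        for bc, ins, c in zip(all_bc, insert_ids + ["spikein"] * len(spike), counts):
            rows.append((float(t), bc, ins, int(c)))
    truth = pd.DataFrame(rows, columns=["timepoint_h", "barcode", "insert_id", "true_count"])
    return readsets, truth, spike


def simulate_luminescence(
    transit_time_s: float,
    rate: float,
    noise_sd: float,
    t_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a continuous in vitro translation luminescence trace.

    Signal is zero until ribosomes complete their first transit, then rises
    linearly: ``max(0, rate·(t − transit_time)) + N(0, noise_sd)``.  Default
    grid: one reading every 10 s over 25 min.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 25 * 60 + 1, 10.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    signal = np.maximum(0.0, rate * (t_grid - transit_time_s))
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        signal = signal + rng.normal(0.0, noise_sd, size=t_grid.shape)
    return pd.DataFrame({"time_s": t_grid, "signal": signal})
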