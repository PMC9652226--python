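"""Barcode counting and per-insert mRNA quantification.

The estimand is the per-insert mRNA level: the log2 ratio of summed mRNA
barcode counts to summed genomic-DNA barcode counts, median-normalized over
inserts that pass coverage thresholds (a minimum of 200 reads and 6 barcodes
summed across the mRNA and gDNA samples; inserts below either threshold, or
with zero gDNA counts, are reported as missing, never smoothed).  Barcode-
level uncertainty is a bootstrap over barcodes, resampling each barcode with
its paired (mRNA, gDNA) counts jointly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import BarcodeMap
from .reporter_library import BARCODE_LENGTH
from .simulate import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 200
DEFAULT_MIN_BARCODES = 6


@dataclass
class CountTable:
    """Per-barcode read counts for one sample."""

    sample_id: str
    counts: dict[str, int]
    unmatched: int

    def total(self) -> int:
        return sum(self.counts.values())


def _one_mismatch_variants(seq: str) -> Iterable[str]:
    for i, orig in enumerate(seq):
        for b in "ACGT":
            if b != orig:
                yield seq[:i] + b + seq[i + 1 :]


def count_barcodes(
    reads: ReadSet | Iterable[str],
    barcode_map: BarcodeMap,
    *,
    rescue_one_mismatch: bool = True,
) -> CountTable:
    """Tally reads against the kept barcodes of a map.

    Exact matches count directly; with ``rescue_one_mismatch`` a read one
    substitution away from exactly one kept barcode is rescued, while reads
    within one mismatch of two kept barcodes stay unmatched.
    """
    kept = set(barcode_map.entries["barcode"])
    if not kept:
        raise ValueError("barcode map has no kept barcodes")
    sample_id = reads.sample_id if isinstance(reads, ReadSet) else "sample"
    seqs = reads.sequences if isinstance(reads, ReadSet) else reads

    raw = Counter(seqs)
    counts: dict[str, int] = {bc: 0 for bc in kept}
    unmatched = 0
    for seq, n in raw.items():
        if seq in kept:
            counts[seq] += n
            continue
        if rescue_one_mismatch and len(seq) == BARCODE_LENGTH:
            hits = [v for v in _one_mismatch_variants(seq) if v in kept]
            if len(hits) == 1:
                counts[hits[0]] += n
                continue
        unmatched += n
    return CountTable(sample_id, counts, unmatched)


@dataclass
class InsertQuant:
    """Per-insert quantification with pass/fail status."""

    insert_id: str
    mrna_sum: int
    gdna_sum: int
    n_barcodes: int
    level: float  # log2, median-normalized; NaN when missing
    sem: float
    status: str  # "ok" | "missing"


def _insert_sums(table: CountTable, barcode_map: BarcodeMap) -> pd.Series:
    df = barcode_map.entries.assign(
        n=[table.counts.get(bc, 0) for bc in barcode_map.entries["barcode"]]
    )
    return df.groupby("insert_id")["n"].sum()


def insert_levels(
    mrna: CountTable,
    gdna: CountTable,
    barcode_map: BarcodeMap,
    *,
    min_reads: int = DEFAULT_MIN_READS,
    min_barcodes: int = DEFAULT_MIN_BARCODES,
) -> pd.DataFrame:
    """Per-insert summed counts and median-normalized log2 mRNA levels.

    An insert is *missing* when its combined mRNA+gDNA read total falls below
    ``min_reads``, it has fewer than ``min_barcodes`` barcodes with any
    counts, or its gDNA sum is zero.  Levels of ok inserts are
    log2(mRNA/gDNA) minus the library median over ok inserts.
    """
    entries = barcode_map.entries
    mrna_sums = _insert_sums(mrna, barcode_map)
    gdna_sums = _insert_sums(gdna, barcode_map)
    n_bc = entries.assign(
        nonzero=[
            (mrna.counts.get(bc, 0) + gdna.counts.get(bc, 0)) > 0
            for bc in entries["barcode"]
        ]
    ).groupby("insert_id")["nonzero"].sum()

    df = pd.DataFrame({"mrna_sum": mrna_sums, "gdna_sum": gdna_sums, "n_barcodes": n_bc})
    df = df.fillna(0).astype(int)
    ok = (
        ((df["mrna_sum"] + df["gdna_sum"]) >= min_reads)
        & (df["n_barcodes"] >= min_barcodes)
        & (df["gdna_sum"] > 0)
    )
    n_zero_gdna = int(((df["gdna_sum"] == 0) & (df["mrna_sum"] > 0)).sum())
    if n_zero_gdna:
        logger.info("%d inserts with mRNA counts but zero gDNA counts set missing", n_zero_gdna)
    if not ok.any():
        raise ValueError("no insert passes the coverage thresholds")

    raw = np.log2(df.loc[ok, "mrna_sum"] / df.loc[ok, "gdna_sum"])
    med = float(raw.median())
    df["level"] = np.nan
    df.loc[ok, "level"] = raw - med
    df["status"] = np.where(ok, "ok", "missing")
    df.index.name = "insert_id"
    return df.reset_index()


def bootstrap_sem(
    barcode_counts: Sequence[tuple[int, int]],
    B: int,
    rng: np.random.Generator,
) -> float:
    """Bootstrap SEM of an insert's log2 mRNA/gDNA level over its barcodes.

    Each resample draws barcodes with replacement, carrying each barcode's
    paired (mRNA, gDNA) counts jointly, and recomputes the summed log2 ratio;
    the SEM is the standard deviation over replicates.  Replicates whose
    resampled gDNA (or mRNA) sum is zero are dropped and counted in the log.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not barcode_counts:
        raise ValueError("insert has no barcodes")
    arr = np.asarray(barcode_counts, dtype=float)  # columns: mRNA, gDNA
    n = arr.shape[0]
    idx = rng.integers(0, n, size=(B, n))
    sums = arr[idx].sum(axis=1)  # (B, 2)
    valid = (sums > 0).all(axis=1)
    dropped = int(B - valid.sum())
    if dropped:
        logger.info("bootstrap: dropped %d/%d replicates with zero resampled sums", dropped, B)
    if valid.sum() < 2:
        return float("nan")
    ratios = np.log2(sums[valid, 0] / sums[valid, 1])
    return float(np.std(ratios, ddof=1))


def quantify_with_sem(
    mrna: CountTable,
    gdna: CountTable,
    barcode_map: BarcodeMap,
    rng: np.random.Generator,
    *,
    B: int | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    min_barcodes: int = DEFAULT_MIN_BARCODES,
) -> pd.DataFrame:
    """Insert levels plus bootstrap SEM per ok insert.

    Default replicate count follows library size: 100 replicates for
    libraries over 1000 inserts, 1000 otherwise.
    """
    df = insert_levels(mrna, gdna, barcode_map, min_reads=min_reads, min_barcodes=min_barcodes)
    if B is None:
        B = 100 if len(df) > 1000 else 1000
    by_insert = dict(iter(barcode_map.entries.groupby("insert_id")["barcode"]))
    sems = []
    for insert_id, status in zip(df["insert_id"], df["status"]):
        if status != "ok":
            sems.append(float("nan"))
            continue
        pairs = [
            (mrna.counts.get(bc, 0), gdna.counts.get(bc, 0))
            for bc in by_insert[insert_id]
        ]
        sems.append(bootstrap_sem(pairs, B, rng))
    return df.assign(sem=sems)


def decay_normalize(
    timecourse: Mapping[float, CountTable],
    spikein_barcodes: Sequence[str],
    barcode_map: BarcodeMap,
) -> pd.DataFrame:
    """Spike-in- and time-0-normalized decay curves per insert.

    norm_level(t) = [insert_sum(t) / spikein_total(t)] ÷ the same quantity at
    t = 0, so every curve starts at 1.  Spike-in totals are tallied from the
    raw counts of the external barcode set in each sample.
    """
    times = sorted(timecourse)
    if not times or times[0] != 0:
        raise ValueError("timecourse must include a t=0 sample")
    spike = set(spikein_barcodes)

    per_time: dict[float, pd.Series] = {}
    spike_total: dict[float, int] = {}
    for t in times:
        table = timecourse[t]
        spike_total[t] = sum(n for bc, n in table.counts.items() if bc in spike)
        if spike_total[t] <= 0:
            raise ValueError(f"zero spike-in counts at t={t}")
        per_time[t] = _insert_sums(table, barcode_map)

    inserts = per_time[0].index
    rows = []
    for insert_id in inserts:
        base = per_time[0][insert_id] / spike_total[0]
        if base <= 0:
            continue
        for t in times:
            val = per_time[t].get(insert_id, 0) / spike_total[t]
            rows.append((insert_id, t, val / base))
    return pd.DataFrame(rows, columns=["insert_id", "timepoint_h", "norm_level"])


def fit_halflife(curve: pd.DataFrame) -> float:
    """Least-squares half-life (hours) from one insert's decay curve.

    Fits log2(norm_level) = −t/h through the origin; points with
    non-positive normalized level are dropped.
    """
    d = curve[curve["norm_level"] > 0]
    t = d["timepoint_h"].to_numpy(float)
    y = np.log2(d["norm_level"].to_numpy(float))
    denom = float((t * t).sum())
    if denom == 0:
        return float("nan")
    slope = float((t * y).sum() / denom)
    if slope >= 0:
        return float("inf")
    return -1.0 / slope


def facs_enrichment(
    sorted_table: CountTable,
    unsorted_table: CountTable,
    barcode_map: BarcodeMap,
) -> pd.DataFrame:
    """Per-insert log2 enrichment in the sorted low-fluorescence population.

    log2(summed sorted counts / summed unsorted counts); inserts with a zero
    sum in either sample are flagged and excluded from the enrichment value.
    """
    s = _insert_sums(sorted_table, barcode_map)
    u = _insert_sums(unsorted_table, barcode_map)
    df = pd.DataFrame({"sorted_sum": s, "unsorted_sum": u}).fillna(0).astype(int)
    ok = (df["sorted_sum"] > 0) & (df["unsorted_sum"] > 0)
    df["enrichment"] = np.nan
    df.loc[ok, "enrichment"] = np.log2(df.loc[ok, "sorted_sum"] / df.loc[ok, "unsorted_sum"])
    df["status"] = np.where(ok, "ok", "zero_count")
    df.index.name = "insert_id"
    return df.reset_index()
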