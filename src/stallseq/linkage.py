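"""Barcode-to-insert assignment from linkage reads.

Replaces an aligner-based workflow with an explicit matching contract: a read
insert region is assigned to the unique library insert within a bounded
number of substitutions (ties are discarded, standing in for a mapping-
quality filter).  Tallied (barcode, insert) pairs then pass three filters:

1. minimum observation count (default 4);
2. removal of barcodes linked to more than one distinct insert;
3. collapse of same-insert barcodes within a small Hamming distance onto the
   higher-count member (deterministic lexicographic tie-break).

All steps are substitution-only (fixed-length synthesized regions) and
order-independent.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reporter_library import BARCODE_LENGTH, CodonPairInsert, VariantInsert
from .simulate import LINKAGE_BARCODE_OFFSET, LINKAGE_INSERT_OFFSET, ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 4
DEFAULT_COLLISION_DISTANCE = 2
DEFAULT_MAX_MISMATCHES = 2

#: Barcode dispositions recorded in the filter log.
DISPOSITIONS = ("kept", "below_min_count", "multi_insert", "duplicate_collapsed")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class LibraryIndex:
    """Insert lookup by exact sequence with a vectorised mismatch fallback."""

    insert_ids: list[str]
    _exact: dict[str, str] = field(init=False, repr=False)
    _matrix: np.ndarray = field(init=False, repr=False)
    insert_length: int = field(init=False)

    def __init__(self, inserts: Sequence[CodonPairInsert | VariantInsert]):
        self.insert_ids = [ins.insert_id for ins in inserts]
        seqs = [ins.nt_seq for ins in inserts]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("library inserts must share one length")
        self.insert_length = lengths.pop()
        self._exact = {}
        for ins_id, s in zip(self.insert_ids, seqs):
            if s in self._exact:
                raise ValueError(f"duplicate insert sequence for {ins_id}")
            self._exact[s] = ins_id
        self._matrix = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
            len(seqs), self.insert_length
        )

    def match(self, region: str, max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> str | None:
        """Unique insert within ``max_mismatches`` substitutions, else None.

        A read equidistant from two inserts at the minimum distance is left
        unassigned (uniqueness contract).
        """
        if len(region) != self.insert_length:
            return None
        hit = self._exact.get(region)
        if hit is not None:
            return hit
        if max_mismatches < 1:
            return None
        query = np.frombuffer(region.encode(), dtype=np.uint8)
        dists = (self._matrix != query).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatches:
            return None
        idx = np.flatnonzero(dists == best)
        if len(idx) != 1:
            return None
        return self.insert_ids[int(idx[0])]


def match_insert(
    read_insert_region: str,
    index: LibraryIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> str | None:
    """Assign one read insert region to a library insert (None = unassigned)."""
    return index.match(read_insert_region, max_mismatches)


@dataclass
class BarcodeMap:
    """Validated barcode→insert assignments after filtering."""

    entries: pd.DataFrame  # columns: barcode, insert_id, count
    filter_log: pd.DataFrame  # columns: barcode, insert_id, count, disposition

    @property
    def kept(self) -> pd.DataFrame:
        return self.entries

    def barcodes_for(self, insert_id: str) -> list[str]:
        return self.entries.loc[self.entries["insert_id"] == insert_id, "barcode"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        """Write the full disposition table as (gzip) TSV."""
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            self.filter_log.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            log = pd.read_csv(fh, sep="\t")
        kept = log[log["disposition"] == "kept"].drop(columns="disposition").reset_index(drop=True)
        return cls(kept, log)


def _extract_regions(reads: ReadSet) -> Iterable[tuple[str, str]]:
    """Yield (insert_region, barcode) from linkage reads at the fixed layout."""
    i0, i1 = LINKAGE_INSERT_OFFSET, LINKAGE_INSERT_OFFSET + 48
    b0, b1 = LINKAGE_BARCODE_OFFSET, LINKAGE_BARCODE_OFFSET + BARCODE_LENGTH
    for seq in reads.sequences:
        if len(seq) < b1:
            continue
        yield seq[i0:i1], seq[b0:b1]


def tally_linkage_reads(
    reads: ReadSet | Iterable[tuple[str, str]],
    index: LibraryIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> Counter:
    """Count (barcode, insert_id) pairs over assignable linkage reads.

    Accepts either a linkage ReadSet (regions cut at the fixed offsets) or an
    iterable of pre-split (insert_region, barcode) tuples.
    """
    pairs = _extract_regions(reads) if isinstance(reads, ReadSet) else reads
    tally: Counter = Counter()
    region_cache: dict[str, str | None] = {}
    for region, barcode in pairs:
        hit = region_cache.get(region, "__miss__")
        if hit == "__miss__":
            hit = index.match(region, max_mismatches)
            region_cache[region] = hit
        if hit is not None:
            tally[(barcode, hit)] += 1
    return tally


def build_barcode_map(
    reads: ReadSet | Iterable[tuple[str, str]],
    index: LibraryIndex,
    *,
    min_count: int = DEFAULT_MIN_COUNT,
    collision_distance: int = DEFAULT_COLLISION_DISTANCE,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> BarcodeMap:
    """Tally linkage reads and apply the count/collision/duplicate filters.

    Filters, in order: drop barcodes seen fewer than ``min_count`` times in
    total; drop barcodes linked to two or more distinct inserts; among
    same-insert barcode pairs within Hamming distance ``collision_distance``,
    discard the lower-count member (lexicographically greater on count ties).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if collision_distance < 0:
        raise ValueError("collision_distance must be >= 0")
    tally = tally_linkage_reads(reads, index, max_mismatches)
    if not tally:
        logger.warning("no assignable linkage reads; barcode map is empty")
        cols = ["barcode", "insert_id", "count"]
        empty = pd.DataFrame(columns=cols)
        return BarcodeMap(empty, empty.assign(disposition=pd.Series(dtype=str)))

    by_barcode: dict[str, dict[str, int]] = defaultdict(dict)
    for (barcode, insert_id), n in tally.items():
        by_barcode[barcode][insert_id] = by_barcode[barcode].get(insert_id, 0) + n

    rows = []  # (barcode, insert_id, count, disposition)
    surviving: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for barcode in sorted(by_barcode):
        per_insert = by_barcode[barcode]
        total = sum(per_insert.values())
        top_insert = max(per_insert, key=lambda k: (per_insert[k], k))
        if len(per_insert) > 1:
            rows.append((barcode, top_insert, total, "multi_insert"))
        elif total < min_count:
            rows.append((barcode, top_insert, total, "below_min_count"))
        else:
            surviving[top_insert].append((barcode, total))

    for insert_id in sorted(surviving):
        group = surviving[insert_id]
        # process high-count first; lexicographically smaller wins count ties
        group.sort(key=lambda bc: (-bc[1], bc[0]))
        kept_here: list[tuple[str, int]] = []
        for barcode, count in group:
            clash = collision_distance > 0 and any(
                hamming(barcode, kb) <= collision_distance for kb, _ in kept_here
            )
            if clash:
                rows.append((barcode, insert_id, count, "duplicate_collapsed"))
            else:
                kept_here.append((barcode, count))
                rows.append((barcode, insert_id, count, "kept"))

    log = pd.DataFrame(rows, columns=["barcode", "insert_id", "count", "disposition"])
    log = log.sort_values(["insert_id", "barcode"]).reset_index(drop=True)
    kept = log[log["disposition"] == "kept"].drop(columns="disposition").reset_index(drop=True)
    return BarcodeMap(kept, log)
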