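"""Counting, level computation, bootstrap SEM, decay and sort-seq metrics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stallseq.linkage import BarcodeMap
from stallseq.quantify import (
    CountTable,
    bootstrap_sem,
    count_barcodes,
    decay_normalize,
    facs_enrichment,
    fit_halflife,
    insert_levels,
)


def make_map(entries):
    """entries: list of (barcode, insert_id, count)."""
    df = pd.DataFrame(entries, columns=["barcode", "insert_id", "count"])
    return BarcodeMap(df, df.assign(disposition="kept"))


BC = ["A" * 24, "C" * 24, "G" * 24, "AC" * 12, "AG" * 12, "CG" * 12, "GA" * 12]


class TestCountBarcodes:
    def test_each_kept_barcode_once(self):
        bm = make_map([(BC[0], "i1", 5), (BC[1], "i1", 5), (BC[2], "i2", 5)])
        table = count_barcodes(BC[:3], bm)
        assert all(table.counts[bc] == 1 for bc in BC[:3])
        assert table.unmatched == 0

    def test_one_mismatch_rescued_to_unique_barcode(self):
        bm = make_map([(BC[0], "i1", 5), (BC[1], "i2", 5)])
        read = "T" + "A" * 23  # Hamming 1 from BC[0], far from BC[1]
        # brute-force nearest-barcode check
        dists = {bc: sum(a != b for a, b in zip(read, bc)) for bc in (BC[0], BC[1])}
        assert dists[BC[0]] == 1 and dists[BC[1]] > 1
        table = count_barcodes([read], bm)
        assert table.counts[BC[0]] == 1

    def test_ambiguous_rescue_stays_unmatched(self):
        near1 = "A" * 24
        near2 = "A" * 23 + "G"
        bm = make_map([(near1, "i1", 5), (near2, "i2", 5)])
        read = "A" * 23 + "C"  # Hamming 1 from both
        table = count_barcodes([read], bm)
        assert table.unmatched == 1

    def test_rescue_off_leaves_unmatched(self):
        bm = make_map([(BC[0], "i1", 5)])
        table = count_barcodes(["T" + "A" * 23], bm, rescue_one_mismatch=False)
        assert table.unmatched == 1


class TestInsertLevels:
    def test_single_insert_balanced_counts_give_zero(self):
        bm = make_map([(bc, "i1", 5) for bc in BC[:6]])
        mrna = CountTable("m", {bc: 67 for bc in BC[:6]}, 0)
        gdna = CountTable("g", {bc: 67 for bc in BC[:6]}, 0)
        df = insert_levels(mrna, gdna, bm)
        assert df.loc[0, "level"] == pytest.approx(0.0)
        assert df.loc[0, "status"] == "ok"

    def test_five_barcodes_is_missing(self):
        extra = [("CA" * 12), ("GC" * 12), ("TG" * 12), ("AT" * 12), ("CT" * 12), ("TC" * 12)]
        bm = make_map(
            [(bc, "i1", 5) for bc in BC[:5]] + [(bc, "i2", 5) for bc in extra]
        )
        all_bc = BC[:5] + extra
        mrna = CountTable("m", {bc: 100 for bc in all_bc}, 0)
        gdna = CountTable("g", {bc: 100 for bc in all_bc}, 0)
        df = insert_levels(mrna, gdna, bm, min_barcodes=6, min_reads=200).set_index("insert_id")
        assert df.at["i1", "status"] == "missing"  # 5 barcodes despite 1000 reads
        assert math.isnan(df.at["i1", "level"])
        assert df.at["i2", "status"] == "ok"

    def test_below_200_reads_is_missing(self):
        bm = make_map([(bc, "i1", 5) for bc in BC[:6]] + [(BC[6], "i2", 5)])
        counts_m = {bc: 16 for bc in BC[:6]}  # 96+96 = 192 < 200
        counts_m[BC[6]] = 500
        counts_g = dict(counts_m)
        df = insert_levels(CountTable("m", counts_m, 0), CountTable("g", counts_g, 0),
                           bm, min_barcodes=1).set_index("insert_id")
        assert df.at["i1", "status"] == "missing"
        assert df.at["i2", "status"] == "ok"

    def test_median_subtraction(self):
        entries = []
        mrna, gdna = {}, {}
        for i, ratio in enumerate([2.0, 4.0, 32.0]):
            for j in range(6):
                bc = ("ACGT"[i] + "ACGT"[j % 4] + "AC"[j // 4]) * 8
                entries.append((bc, f"i{i}", 5))
                gdna[bc] = 100
                mrna[bc] = int(100 * ratio)
        bm = make_map(entries)
        df = insert_levels(CountTable("m", mrna, 0), CountTable("g", gdna, 0), bm)
        levels = df.set_index("insert_id")["level"]
        assert levels["i0"] == pytest.approx(-1.0)
        assert levels["i1"] == pytest.approx(0.0)
        assert levels["i2"] == pytest.approx(3.0)

    def test_normalization_idempotent(self):
        entries = []
        mrna, gdna = {}, {}
        rng = np.random.default_rng(0)
        for i in range(9):
            for j in range(6):
                bc = "".join(rng.choice(list("ACGT"), 24))
                entries.append((bc, f"i{i}", 5))
                gdna[bc] = 100
                mrna[bc] = int(rng.integers(50, 400))
        bm = make_map(entries)
        df = insert_levels(CountTable("m", mrna, 0), CountTable("g", gdna, 0), bm)
        ok = df[df["status"] == "ok"]
        assert float(ok["level"].median()) == pytest.approx(0.0, abs=1e-12)
        # subtracting the (zero) median again changes nothing
        assert np.allclose(ok["level"] - ok["level"].median(), ok["level"])

    def test_zero_gdna_with_mrna_is_missing(self):
        bm = make_map([(bc, "i1", 5) for bc in BC[:6]] + [(BC[6], "i2", 5)])
        mrna = {bc: 100 for bc in BC}
        gdna = {bc: 100 for bc in BC[:6]}
        gdna[BC[6]] = 0
        df = insert_levels(CountTable("m", mrna, 0), CountTable("g", gdna, 0),
                           bm, min_barcodes=1, min_reads=10).set_index("insert_id")
        assert df.at["i2", "status"] == "missing"

    def test_no_ok_insert_raises(self):
        bm = make_map([(BC[0], "i1", 5)])
        with pytest.raises(ValueError):
            insert_levels(CountTable("m", {BC[0]: 1}, 0), CountTable("g", {BC[0]: 1}, 0), bm)


class TestBootstrapSem:
    def test_identical_barcodes_give_zero(self, rng):
        assert bootstrap_sem([(100, 100)] * 4, 200, rng) == pytest.approx(0.0)

    def test_single_barcode_gives_zero(self, rng):
        assert bootstrap_sem([(123, 77)], 100, rng) == pytest.approx(0.0)

    def test_two_barcode_case_matches_exact_enumeration(self):
        pairs = [(100, 100), (400, 100)]
        # exact enumeration over resample multisets {11},{12},{22} w/ 1/4,1/2,1/4
        vals, weights = [], []
        for combo, w in [((0, 0), 0.25), ((0, 1), 0.5), ((1, 1), 0.25)]:
            m = sum(pairs[i][0] for i in combo)
            g = sum(pairs[i][1] for i in combo)
            vals.append(math.log2(m / g))
            weights.append(w)
        mean = sum(w * v for w, v in zip(weights, vals))
        exact_sd = math.sqrt(sum(w * (v - mean) ** 2 for w, v in zip(weights, vals)))
        rng = np.random.default_rng(11)
        est = bootstrap_sem(pairs, 100_000, rng)
        assert est == pytest.approx(exact_sd, rel=0.02)

    def test_sem_shrinks_with_depth(self):
        rng = np.random.default_rng(12)
        base = [(int(x), int(y)) for x, y in rng.integers(20, 200, size=(8, 2))]
        scaled = [(m * 100, g * 100) for m, g in base]
        s_base = bootstrap_sem(base, 2000, np.random.default_rng(1))
        s_scaled = bootstrap_sem(scaled, 2000, np.random.default_rng(1))
        # ratio noise is multiplicative: scaling all counts by a constant
        # leaves the barcode-level log-ratios unchanged
        assert s_scaled == pytest.approx(s_base, rel=1e-9)

    def test_label_permutation_invariance(self):
        pairs = [(100, 100), (400, 100), (50, 200)]
        a = bootstrap_sem(pairs, 5000, np.random.default_rng(3))
        b = bootstrap_sem(list(reversed(pairs)), 5000, np.random.default_rng(3))
        assert a == pytest.approx(b, rel=0.05)


class TestDecayAndEnrichment:
    def _map(self):
        return make_map([(BC[0], "i1", 5), (BC[1], "i1", 5)])

    def test_constant_counts_give_flat_curve(self):
        bm = self._map()
        spike = ["T" + "A" * 23]
        tables = {
            t: CountTable(f"t{t}", {BC[0]: 100, BC[1]: 100, spike[0]: 50}, 0)
            for t in [0.0, 1.0, 2.0]
        }
        curves = decay_normalize(tables, spike, bm)
        assert np.allclose(curves["norm_level"], 1.0)

    def test_ratio_invariance_when_both_double(self):
        bm = self._map()
        spike = ["T" + "A" * 23]
        tables = {
            0.0: CountTable("t0", {BC[0]: 100, BC[1]: 100, spike[0]: 50}, 0),
            1.0: CountTable("t1", {BC[0]: 200, BC[1]: 200, spike[0]: 100}, 0),
        }
        curves = decay_normalize(tables, spike, bm)
        assert np.allclose(curves["norm_level"], 1.0)

    def test_missing_time_zero_raises(self):
        bm = self._map()
        with pytest.raises(ValueError):
            decay_normalize({1.0: CountTable("t1", {BC[0]: 1}, 0)}, ["T" * 24], bm)

    def test_zero_spikein_raises(self):
        bm = self._map()
        tables = {0.0: CountTable("t0", {BC[0]: 100}, 0)}
        with pytest.raises(ValueError):
            decay_normalize(tables, ["T" + "A" * 23], bm)

    def test_halflife_fit_recovers_exact_decay(self):
        curve = pd.DataFrame({
            "insert_id": "i1",
            "timepoint_h": [0.0, 1.0, 2.0, 4.0],
            "norm_level": [1.0, 0.5, 0.25, 0.0625],
        })
        assert fit_halflife(curve) == pytest.approx(1.0)

    def test_enrichment_values(self):
        bm = make_map([(BC[0], "i1", 5), (BC[1], "i2", 5), (BC[2], "i3", 5)])
        sorted_t = CountTable("s", {BC[0]: 100, BC[1]: 400, BC[2]: 0}, 0)
        unsorted_t = CountTable("u", {BC[0]: 100, BC[1]: 100, BC[2]: 100}, 0)
        df = facs_enrichment(sorted_t, unsorted_t, bm).set_index("insert_id")
        assert df.at["i1", "enrichment"] == pytest.approx(0.0)
        assert df.at["i2", "enrichment"] == pytest.approx(2.0)
        assert df.at["i3", "status"] == "zero_count"
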