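"""Positional averaging, linear models, frame and propensity correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stallseq.aa_properties import mean_scale
from stallseq.analysis_models import (
    fit_physicochemical_model,
    frame_correlations,
    group_compare,
    positional_effects,
    propensity_correlation,
)
from stallseq.codons import CODON_TABLE, NUCLEOTIDES

CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
STOPS = {"TAA", "TAG", "TGA"}


def all_pair_levels(fn):
    return {(c1, c2): fn(c1, c2) for c1 in CODONS for c2 in CODONS}


class TestPositionalEffects:
    def test_constant_levels_give_constant_effects(self):
        eff = positional_effects(all_pair_levels(lambda a, b: 1.5))
        assert np.allclose(eff["mean_level"], 1.5)
        codons = eff[eff["unit_type"] == "codon"]
        assert len(codons) == 64 * 2  # every codon at both positions

    def test_stop_effect_below_all_amino_acids(self):
        levels = all_pair_levels(lambda a, b: -1.0 if (a in STOPS or b in STOPS) else 0.0)
        eff = positional_effects(levels)
        aa = eff[eff["unit_type"] == "amino_acid"].set_index(["unit", "position"])
        for pos in (1, 2):
            stop_mean = aa.at[("*", pos), "mean_level"]
            others = aa.loc[[(u, pos) for u in set(aa.index.get_level_values(0)) - {"*"}]]
            assert (others["mean_level"] > stop_mean).all()

    def test_elevating_one_codon_shifts_its_effect_only(self):
        delta = 2.0
        levels = all_pair_levels(lambda a, b: delta * ((a == "GTG") + (b == "GTG")))
        eff = positional_effects(levels).set_index(["unit_type", "unit", "position"])
        base = eff.at[("codon", "AAA", 1), "mean_level"]
        assert eff.at[("codon", "GTG", 1), "mean_level"] == pytest.approx(base + delta)
        assert eff.at[("codon", "GTG", 2), "mean_level"] == pytest.approx(base + delta)

    def test_means_match_groupby_oracle(self):
        rng = np.random.default_rng(8)
        levels = {(c1, c2): float(rng.normal()) for c1 in CODONS[:8] for c2 in CODONS[:8]}
        eff = positional_effects(levels).set_index(["unit_type", "unit", "position"])
        df = pd.DataFrame(
            [(c1, c2, v) for (c1, c2), v in levels.items()], columns=["c1", "c2", "level"]
        )
        for codon in CODONS[:8]:
            oracle1 = df.loc[df["c1"] == codon, "level"].mean()
            assert eff.at[("codon", codon, 1), "mean_level"] == pytest.approx(oracle1)


class TestPhysicochemicalModel:
    def test_noiseless_recovery_of_generative_betas(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        levels = {}
        for a, b in itertools.product(aas, repeat=2):
            dp = a + b
            pI = mean_scale(dp, "pI")
            bulk = mean_scale(dp, "bulkiness")
            levels[dp] = 0.31 * pI + 0.20 * bulk - 0.03 * pI * bulk
        fit = fit_physicochemical_model(levels)
        assert fit.coefficient("pI") == pytest.approx(0.31, rel=1e-6)
        assert fit.coefficient("bulkiness") == pytest.approx(0.20, rel=1e-6)
        assert fit.coefficient("pI_x_bulkiness") == pytest.approx(-0.03, rel=1e-6)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        retained_names = {t[0] for t in fit.retained}
        assert {"pI", "bulkiness", "pI_x_bulkiness"} <= retained_names

    def test_constant_response_gives_zero_slopes(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        levels = {a + b: 3.0 for a, b in itertools.product(aas, repeat=2)}
        fit = fit_physicochemical_model(levels)
        for name in ("pI", "bulkiness", "pI_x_bulkiness"):
            assert fit.coefficient(name) == pytest.approx(0.0, abs=1e-10)
        assert fit.adjusted_r2 <= 0

    def test_null_retention_rate_near_alpha(self):
        # pure-noise responses: each slope should clear p<0.05 about 5% of runs
        aas = "ACDEFGHIKLMNPQRSTVWY"
        dipeptides = [a + b for a, b in itertools.product(aas, repeat=2)]
        n_terms = 0
        n_retained = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            levels = {dp: float(rng.normal()) for dp in dipeptides}
            fit = fit_physicochemical_model(levels)
            slopes = [t for t in fit.terms if t[0] != "const"]
            n_terms += len(slopes)
            n_retained += sum(1 for t in slopes if t[2] < 0.05)
        rate = n_retained / n_terms
        assert 0.02 <= rate <= 0.10

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_physicochemical_model({"VK": 1.0, "KV": 2.0, "AA": 0.0})


class TestFrameCorrelations:
    def test_identical_partner_levels_give_r_one(self):
        levels = {}
        rng = np.random.default_rng(2)
        class_level = {}
        for c1, c2 in itertools.product(CODONS, repeat=2):
            a1, a2 = CODON_TABLE[c1], CODON_TABLE[c2]
            key = frozenset((a1, a2))
            if key not in class_level:
                class_level[key] = float(rng.normal())
            levels[(c1, c2)] = class_level[key]
        # levels depend only on the unordered amino-acid class, so any
        # stop-free partner in any frame carries a correlated signal; the
        # codon-matched +3 frame is exactly the swapped pair -> r == 1
        res = frame_correlations(levels).set_index("shift")
        assert res.at[3, "r"] == pytest.approx(1.0)
        assert res.at[3, "n_classes"] == 190

    def test_peptide_determined_truth_ranks_shift3_highest(self):
        # truth driven by amino-acid composition (reversal-symmetric, as the
        # physicochemical features are) plus small orientation-level noise:
        # the codon-matched +3 frame encodes the near-identical reversed
        # peptide, the +1/+2 frames encode unrelated peptides
        rng = np.random.default_rng(3)
        class_level: dict = {}
        orientation_jitter: dict = {}
        levels = {}
        for c1, c2 in itertools.product(CODONS, repeat=2):
            dp = CODON_TABLE[c1] + CODON_TABLE[c2]
            key = frozenset(dp)
            if key not in class_level:
                class_level[key] = float(rng.normal())
            if dp not in orientation_jitter:
                orientation_jitter[dp] = float(rng.normal(0, 0.2))
            levels[(c1, c2)] = class_level[key] + orientation_jitter[dp]
        res = frame_correlations(levels).set_index("shift")
        assert res.at[3, "r"] > 0.9
        assert res.at[3, "r"] > res.at[1, "r"]
        assert res.at[3, "r"] > res.at[2, "r"]

    def test_independent_partner_levels_give_small_r(self):
        # levels independent across codon pairs: class aggregation of
        # unrelated partners should show little correlation
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            levels = {
                (c1, c2): float(rng.normal())
                for c1, c2 in itertools.product(CODONS, repeat=2)
            }
            res = frame_correlations(levels, shifts=(1,)).set_index("shift")
            if abs(res.at[1, "r"]) < 0.2:
                hits += 1
        assert hits >= 9

    def test_too_few_classes_flagged_nan(self):
        levels = {("GTG", "AAG"): 1.0, ("AAG", "GTG"): 1.0}
        res = frame_correlations(levels, shifts=(1,))
        assert np.isnan(res.loc[0, "r"])


class TestPropensityCorrelation:
    def test_monotone_decreasing_gives_rho_minus_one(self):
        aas = ["A", "V", "I", "L", "F"]
        levels = {aa: -mean_scale(aa, "cf_strand") for aa in aas}
        rho, p = propensity_correlation(levels, "cf_strand")
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_null_p_values_roughly_uniform(self):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            levels = {aa: float(rng.normal()) for aa in aas}
            _, p = propensity_correlation(levels, "cf_strand")
            ps.append(p)
        ps = np.array(ps)
        # crude uniformity: quartile occupancy within binomial tolerance
        assert 0.05 < (ps < 0.25).mean() < 0.5
        assert 0.05 < (ps > 0.75).mean() < 0.5

    def test_exact_small_n_p_value(self):
        # n=4 strictly monotone: |rho|=1 in 2 of 24 permutations -> p = 1/12
        # cf_strand order: D (0.54) < A (0.83) < I (1.60) < V (1.70)
        levels = {"D": 0.5, "A": 1.0, "I": 2.0, "V": 3.0}
        rho, p = propensity_correlation(levels, "cf_strand")
        assert p == pytest.approx(2 / 24)

    def test_constant_propensity_rejected(self):
        levels = {"I": 1.0, "L": 2.0}  # same cf value would be fine but n<4 rejected
        with pytest.raises(ValueError):
            propensity_correlation(levels, "cf_strand")


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        res = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_enumeration_p(self):
        res = group_compare({"a": [1.0, 2.0, 3.0], "b": [10.0, 11.0, 12.0]})
        assert res.loc[0, "p_value"] == pytest.approx(0.1)

    def test_all_pairwise_comparisons_reported(self):
        res = group_compare({"a": [1.0], "b": [2.0], "c": [3.0]})
        assert len(res) == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0], "b": []})

    def test_separated_groups_significant_at_scale(self):
        rng = np.random.default_rng(5)
        low = rng.normal(-1.0, 0.5, size=60)
        high = rng.normal(0.0, 0.5, size=120)
        res = group_compare({"strand": low, "helix": high})
        assert res.loc[0, "p_value"] < 0.001
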