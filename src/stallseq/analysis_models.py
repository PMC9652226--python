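"""Statistical analyses over quantified insert levels.

Covers positional codon/amino-acid averaging, the physicochemical linear
model of dipeptide effects, reading-frame correlations, secondary-structure
propensity correlations, and pairwise group comparisons.  P values are
reported raw (no multiple-testing correction), and linear-model coefficients
are retained at p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aa_properties import SCALES, mean_scale
from .codons import CODON_TABLE
from .reporter_library import CodonPairInsert, frameshift_partner

P_RETAIN = 0.05


@dataclass
class LinearModelResult:
    """OLS fit summary: all terms plus the p < 0.05 retained subset."""

    terms: list[tuple[str, float, float]]  # (name, coefficient, p_value)
    adjusted_r2: float

    @property
    def retained(self) -> list[tuple[str, float, float]]:
        return [t for t in self.terms if t[2] < P_RETAIN]

    def coefficient(self, name: str) -> float:
        for term, coef, _ in self.terms:
            if term == name:
                return coef
        raise KeyError(name)


def positional_effects(levels: Mapping[tuple[str, str], float]) -> pd.DataFrame:
    """Mean level per codon (and per amino acid) at each repeat position.

    For each codon and position (1 or 2), averages the level over all partner
    codons at the other position; amino-acid effects aggregate synonymous
    codons, with stop codons as a 21st class ('*').  Returns one row per
    (unit_type, unit, position) with mean_level and sem.
    """
    rows = []
    for (c1, c2), level in levels.items():
        rows.append((c1, 1, level))
        rows.append((c2, 2, level))
    df = pd.DataFrame(rows, columns=["codon", "position", "level"]).dropna()
    codon_eff = (
        df.groupby(["codon", "position"])["level"]
        .agg(mean_level="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0)
        .reset_index()
        .assign(unit_type="codon")
        .rename(columns={"codon": "unit"})
    )
    df["aa"] = df["codon"].map(CODON_TABLE)
    aa_eff = (
        df.groupby(["aa", "position"])["level"]
        .agg(mean_level="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0)
        .reset_index()
        .assign(unit_type="amino_acid")
        .rename(columns={"aa": "unit"})
    )
    out = pd.concat([codon_eff, aa_eff], ignore_index=True)
    return out[["unit_type", "unit", "position", "mean_level", "sem"]]


def dipeptide_features(dipeptides: Sequence[str], include_strand: bool = False) -> pd.DataFrame:
    """Design matrix of physicochemical features for a set of dipeptides."""
    rows = []
    for dp in dipeptides:
        pI = mean_scale(dp, "pI")
        bulk = mean_scale(dp, "bulkiness")
        row = {"dipeptide": dp, "pI": pI, "bulkiness": bulk, "pI_x_bulkiness": pI * bulk}
        if include_strand:
            row["strand_propensity"] = mean_scale(dp, "cf_strand")
        rows.append(row)
    return pd.DataFrame(rows).set_index("dipeptide")


def fit_physicochemical_model(
    levels: Mapping[str, float],
    *,
    include_strand: bool = False,
) -> LinearModelResult:
    """OLS fit of dipeptide levels on mean pI, bulkiness, their interaction,
    and optionally mean β-strand propensity; intercept always included.

    Raises on a rank-deficient feature matrix, naming the offending terms.
    """
    dipeptides = list(levels)
    X = dipeptide_features(dipeptides, include_strand=include_strand)
    y = np.array([levels[dp] for dp in dipeptides], dtype=float)
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} features, got {n}")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(f"collinear feature matrix among terms {list(X.columns)}")
    fit = sm.OLS(y, Xc).fit()
    terms = [
        (name, float(fit.params[name]), float(fit.pvalues[name]))
        for name in Xc.columns
        if name != "const"
    ]
    terms.insert(0, ("const", float(fit.params["const"]), float(fit.pvalues["const"])))
    return LinearModelResult(terms=terms, adjusted_r2=float(fit.rsquared_adj))


def frame_correlations(
    levels: Mapping[tuple[str, str], float],
    shifts: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Pearson correlation between in-frame and frameshifted levels.

    For each codon pair, the +shift partner pair is the left rotation of the
    hexamer; the frame-0 axis aggregates heterodipeptide classes in canonical
    orientation only (first amino acid alphabetically before the second, so
    reversed repeats are excluded; 190 classes when complete), while the
    partner axis carries the shifted partners' own levels — for the
    codon-matched +3 shift those are the physically distinct reversed-repeat
    inserts.  Pairs whose own or partner peptide contains a stop codon are
    dropped.  Returns (shift, r, n_classes).
    """
    results = []
    for shift in shifts:
        frame0: dict[tuple[str, str], list[float]] = {}
        shifted: dict[tuple[str, str], list[float]] = {}
        for (c1, c2), level in levels.items():
            if level is None or (isinstance(level, float) and math.isnan(level)):
                continue
            aa1, aa2 = CODON_TABLE[c1], CODON_TABLE[c2]
            if "*" in (aa1, aa2) or not aa1 < aa2:
                continue
            p1, p2 = frameshift_partner(CodonPairInsert.from_pair(c1, c2), shift)
            pa1, pa2 = CODON_TABLE[p1], CODON_TABLE[p2]
            if "*" in (pa1, pa2):
                continue
            partner_level = levels.get((p1, p2))
            if partner_level is None or (isinstance(partner_level, float) and math.isnan(partner_level)):
                continue
            key = (aa1, aa2)
            frame0.setdefault(key, []).append(level)
            shifted.setdefault(key, []).append(partner_level)
        keys = sorted(frame0)
        x = np.array([np.mean(frame0[k]) for k in keys])
        y = np.array([np.mean(shifted[k]) for k in keys])
        if len(keys) < 3:
            results.append((shift, float("nan"), len(keys)))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        results.append((shift, r, len(keys)))
    return pd.DataFrame(results, columns=["shift", "r", "n_classes"])


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float((rx_c[list(perm)] * ry_c).sum() / denom)
        if abs(rho) >= thresh:
            count += 1
        total += 1
    return count / total


def propensity_correlation(
    levels: Mapping[str, float],
    scale: str = "cf_strand",
) -> tuple[float, float]:
    """Spearman correlation of insert levels against a partner-residue scale.

    ``levels`` maps the varying residue (e.g. the X of Lys-X) to the measured
    level; the scale value (β-strand or α-helix Chou–Fasman propensity) of
    that residue is the second axis.  Two-sided p-value: exact permutation
    for n ≤ 10, t-approximation otherwise.
    """
    residues = list(levels)
    if len(residues) < 4:
        raise ValueError("need at least 4 points")
    y = np.array([levels[aa] for aa in residues], dtype=float)
    x = np.array([SCALES.at[aa, scale] for aa in residues], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant propensity vector; correlation undefined")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(residues) <= 10:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def group_compare(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests across groups.

    Uses the exact null distribution when the combined sample is small
    (n ≤ 20) and tie-free, the tie-corrected normal approximation otherwise.
    Returns (group_a, group_b, n_a, n_b, U, p_value).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for a, b in itertools.combinations(names, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        combined = np.concatenate([xa, xb])
        small = len(combined) <= 20
        no_ties = len(np.unique(combined)) == len(combined)
        method = "exact" if (small and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append((a, b, len(xa), len(xb), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p_value"])
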