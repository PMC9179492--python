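"""Locus informativeness statistics.

Implements the Cochran–Armitage trend test (binary carrier form and
genotype-score form), Botstein's polymorphic information content and
expected heterozygosity, the spurious sex-linkage probability model
P_i = 0.5^n, and the Kruskal–Wallis comparison of heterozygosity
across classification tiers.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "catt", "catt_trend", "pic", "spurious_probability", "expected_spurious",
    "kruskal_tiers",
]


def catt_trend(counts_by_genotype_by_sex: np.ndarray,
               scores: Sequence[float] = (0, 1, 2)) -> tuple[float, float]:
    """Cochran–Armitage trend test on a 2 × k table.

    Parameters
    ----------
    counts_by_genotype_by_sex:
        2 × k array; row 0 counts one sex, row 1 the other, columns are
        ordered genotype categories.
    scores:
        Numeric scores for the k categories (default additive 0, 1, 2).

    Returns
    -------
    (chi2, p):
        The trend chi-square (1 df, no continuity correction) and its
        two-sided asymptotic p-value.  ``(nan, nan)`` when a margin is
        degenerate (a sex absent, or no variation across categories).
    """
    table = np.asarray(counts_by_genotype_by_sex, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 × k count table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != table.shape[1]:
        raise ValueError("scores length must match the number of categories")

    n_cat = table.sum(axis=0)          # per-category totals
    R = table[0].sum()                 # row-0 total
    N = table.sum()
    if N == 0 or R == 0 or R == N:
        return (float("nan"), float("nan"))
    # variance of the score-weighted case count under the null
    mean_s = (s * n_cat).sum() / N
    var_term = (s**2 * n_cat).sum() - N * mean_s**2
    if var_term <= 0:                  # all weight on one score value
        return (float("nan"), float("nan"))
    num = (s * table[0]).sum() - R * mean_s
    chi2 = num**2 * N**2 / (R * (N - R) * var_term)
    p = float(sps.chi2.sf(chi2, df=1))
    return (float(chi2), p)


def catt(carriers_male: int, noncarriers_male: int,
         carriers_female: int, noncarriers_female: int) -> tuple[float, float]:
    """Binary Cochran–Armitage trend test of carrier state against sex.

    Equals the standard 2 × 2 trend statistic N(ad − bc)² / (R₁R₂C₁C₂)
    with a = male carriers, b = male non-carriers, c = female carriers,
    d = female non-carriers.
    """
    table = np.array([[carriers_male, noncarriers_male],
                      [carriers_female, noncarriers_female]], dtype=float)
    return catt_trend(table, scores=(0, 1))


def pic(allele_frequencies: Sequence[float], *, tol: float = 1e-9
        ) -> tuple[float, float]:
    """Botstein PIC and expected heterozygosity from allele frequencies.

    PIC = 1 − Σpᵢ² − Σᵢ Σ_{j>i} 2 pᵢ² pⱼ²  (bounded by 0.375 for a
    biallelic locus); Hₑ = 1 − Σpᵢ² (bounded by 0.5).
    """
    p = np.asarray(allele_frequencies, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("allele_frequencies must be a non-empty 1-D sequence")
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    sum_p2 = float((p**2).sum())
    he = 1.0 - sum_p2
    sum_p4 = float((p**4).sum())
    cross = (sum_p2**2 - sum_p4)  # Σᵢ Σ_{j≠i} pᵢ²pⱼ² ; halves cancel the 2·
    pic_value = 1.0 - sum_p2 - cross
    return (pic_value, he)


def spurious_probability(n: int) -> float:
    """P_i = 0.5^n — chance of a perfect sex pattern at one null locus.

    ``n`` is the number of individuals sequenced at the locus.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    return 0.5 ** n


def expected_spurious(L: int, n: int, *, two_sided: bool = False) -> float:
    """Expected count of spuriously sex-patterned loci among L tested."""
    if L < 0:
        raise ValueError("L must be non-negative")
    e = L * spurious_probability(n)
    return 2.0 * e if two_sided else e


def kruskal_tiers(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) across tier groups.

    Degenerate input where every value is identical across groups
    returns ``(0.0, 1.0)`` rather than raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return (0.0, 1.0)
    h, p = sps.kruskal(*groups)
    return (float(h), float(p))
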