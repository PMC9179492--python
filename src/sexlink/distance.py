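"""Pairwise genotype Hamming distances and their sex-stratified summary.

The distance between two individuals is the proportion of mutually
called loci at which their calls differ; pairs with no mutually called
locus are undefined (NaN).  On loci that pass the 0:100 sex-specific
filter, the between-sex mean is exactly 1 and the heterogametic-sex
within mean exactly 0 — the structure reported for the study cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, SampleSheet

__all__ = ["hamming_distance", "pairwise_distances", "distance_summary",
           "DistanceSummary"]


def hamming_distance(calls_a, calls_b) -> float:
    """Proportion of mutually-called positions where two vectors differ.

    NaN when no position is called in both vectors.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("call vectors must be 1-D and of equal length")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((a[both] != b[both]).sum() / n)


def pairwise_distances(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric sample × sample Hamming distance matrix.

    Vectorized over loci; undefined pairs (zero mutually called loci)
    are NaN, and the diagonal is 0 where a sample has any call.
    """
    calls = matrix.calls          # loci × samples
    called = calls != MISSING
    n = matrix.n_samples
    # counts of mutually-called loci and of disagreements, per pair
    both = called.astype(np.int64).T @ called.astype(np.int64)
    dist = np.full((n, n), np.nan)
    for j in range(n):
        cj = calls[:, j][:, None]
        mask = called[:, j][:, None] & called
        diff = ((calls != cj) & mask).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(both[j] > 0, diff / np.maximum(both[j], 1), np.nan)
        dist[j, :] = row
    return pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class DistanceSummary:
    """Mean ± sd Hamming distance per sex stratum."""

    mean_between_sexes: float
    sd_between_sexes: float
    mean_within_males: float
    sd_within_males: float
    mean_within_females: float
    sd_within_females: float
    n_loci_used: int
    n_pairs: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "between_sexes": {"mean": self.mean_between_sexes,
                              "sd": self.sd_between_sexes,
                              "n_pairs": self.n_pairs["between_sexes"]},
            "within_males": {"mean": self.mean_within_males,
                             "sd": self.sd_within_males,
                             "n_pairs": self.n_pairs["within_males"]},
            "within_females": {"mean": self.mean_within_females,
                               "sd": self.sd_within_females,
                               "n_pairs": self.n_pairs["within_females"]},
            "n_loci_used": self.n_loci_used,
        }


def _stratum(values: np.ndarray) -> tuple[float, float, int]:
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return (float("nan"), float("nan"), 0)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return (float(values.mean()), sd, len(values))


def distance_summary(dist: pd.DataFrame, sheet: SampleSheet,
                     n_loci_used: int | None = None) -> DistanceSummary:
    """Summarize a distance matrix over male–female / male–male /
    female–female unordered pairs (no self-pairs).

    Strata with fewer than two samples are reported as NaN/undefined.
    """
    samples = [s for s in dist.index if s in set(sheet.sample_ids)]
    sex = dict(zip(sheet.sample_ids, sheet.sex_array()))
    males = [s for s in samples if sex[s] == "male"]
    females = [s for s in samples if sex[s] == "female"]

    d = dist.to_numpy()
    pos = {s: i for i, s in enumerate(dist.index)}

    def collect(group_a, group_b, within: bool) -> np.ndarray:
        vals = []
        if within:
            for i, a in enumerate(group_a):
                for b in group_a[i + 1:]:
                    vals.append(d[pos[a], pos[b]])
        else:
            for a in group_a:
                for b in group_b:
                    vals.append(d[pos[a], pos[b]])
        return np.asarray(vals, dtype=float)

    mb, sb, nb = _stratum(collect(males, females, within=False))
    mm, sm, nm = _stratum(collect(males, None, within=True))
    mf, sf, nf = _stratum(collect(females, None, within=True))
    return DistanceSummary(
        mean_between_sexes=mb, sd_between_sexes=sb,
        mean_within_males=mm, sd_within_males=sm,
        mean_within_females=mf, sd_within_females=sf,
        n_loci_used=-1 if n_loci_used is None else int(n_loci_used),
        n_pairs={"between_sexes": nb, "within_males": nm, "within_females": nf},
    )
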