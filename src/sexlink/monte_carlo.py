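"""Monte Carlo subsampling reproducibility of the sex scan.

Each replicate draws a fraction (default 10%) of the cohort —
stratified by sex, rounding up per sex — reruns the tier
classification on carrier frequencies within the subsample, and
accumulates how often every locus classifies sex-specific and how
often it reaches any sex-linked tier.  High detection frequencies mark
loci whose sex pattern is robust to sampling; the procedure is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import MISSING, GenotypeMatrix, SampleSheet
from .scan import ScanConfig, carrier_mask

__all__ = ["McConfig", "SubsampleReport", "subsample_reproducibility",
           "SubsampleReproducibility"]


@dataclass
class McConfig:
    """Replicate count, subsample size and stratification policy."""

    reps: int = 100_000
    subsample_fraction: float = 0.10
    stratified_by_sex: bool = True
    with_replacement: bool = False
    min_per_sex: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.min_per_sex < 1:
            raise ValueError("min_per_sex must be at least 1")


@dataclass
class SubsampleReport:
    """Per-locus detection frequencies over the replicates."""

    table: pd.DataFrame
    mc_config: McConfig
    scan_config: ScanConfig
    system: str
    n_males_drawn: int
    n_females_drawn: int

    def summary(self) -> dict:
        return {
            "system": self.system,
            "reps": self.mc_config.reps,
            "seed": self.mc_config.seed,
            "subsample": {"males": self.n_males_drawn,
                          "females": self.n_females_drawn},
            "mc_config": asdict(self.mc_config),
            "mean_detection_specific":
                float(self.table["detection_frequency_specific"].mean()),
            "mean_detection_linked":
                float(self.table["detection_frequency_linked"].mean()),
        }


def subsample_reproducibility(matrix: GenotypeMatrix, sheet: SampleSheet,
                              scan_config: ScanConfig | None = None,
                              mc_config: McConfig | None = None,
                              system: str = "XY") -> SubsampleReport:
    """Detection frequency of each locus's classification under subsampling.

    For every replicate the per-sex carrier fractions are recomputed on
    the subsample and classified with ``scan_config``'s thresholds (the
    per-sex called-fraction gate applies relative to the subsample).
    ``detection_frequency_specific`` is the fraction of replicates in
    which a locus classifies at tier specific;
    ``detection_frequency_linked`` counts any tier ≥ the lowest linked
    threshold (specific included).
    """
    scan_config = scan_config or ScanConfig()
    mc_config = mc_config or McConfig()
    matrix = matrix.subset_samples(sheet.sample_ids)
    sheet.require_both_sexes()

    sex = sheet.sex_array(matrix.sample_ids)
    male_idx = np.flatnonzero(sex == "male")
    female_idx = np.flatnonzero(sex == "female")
    frac = mc_config.subsample_fraction
    if mc_config.stratified_by_sex:
        k_m = math.ceil(frac * len(male_idx))
        k_f = math.ceil(frac * len(female_idx))
    else:
        k_total = math.ceil(frac * matrix.n_samples)
        k_m = k_f = -1  # decided per replicate
        exp_m = round(k_total * len(male_idx) / matrix.n_samples)
        exp_f = k_total - exp_m
        if min(exp_m, exp_f) < mc_config.min_per_sex:
            raise ValueError(
                f"subsample of {k_total} cannot guarantee min_per_sex="
                f"{mc_config.min_per_sex}")
    if mc_config.stratified_by_sex and min(k_m, k_f) < mc_config.min_per_sex:
        raise ValueError(
            f"stratified subsample ({k_m} males, {k_f} females) below "
            f"min_per_sex={mc_config.min_per_sex}; raise the fraction")

    carriers = carrier_mask(matrix, scan_config.presence_rule_snp)
    called = matrix.called
    t_low = scan_config.tier_thresholds[0]
    gate_frac = scan_config.min_called_fraction_per_sex

    n_specific = np.zeros(matrix.n_loci, dtype=np.int64)
    n_linked = np.zeros(matrix.n_loci, dtype=np.int64)
    rng = np.random.default_rng(mc_config.seed)

    for _ in range(mc_config.reps):
        if mc_config.stratified_by_sex:
            sub_m = rng.choice(male_idx, size=k_m,
                               replace=mc_config.with_replacement)
            sub_f = rng.choice(female_idx, size=k_f,
                               replace=mc_config.with_replacement)
        else:
            pool = rng.choice(matrix.n_samples, size=k_total,
                              replace=mc_config.with_replacement)
            sub_m = pool[np.isin(pool, male_idx)]
            sub_f = pool[np.isin(pool, female_idx)]
            if min(len(sub_m), len(sub_f)) < mc_config.min_per_sex:
                continue
        nc_m = called[:, sub_m].sum(axis=1)
        nc_f = called[:, sub_f].sum(axis=1)
        ca_m = carriers[:, sub_m].sum(axis=1)
        ca_f = carriers[:, sub_f].sum(axis=1)
        ok = ((nc_m >= gate_frac * len(sub_m))
              & (nc_f >= gate_frac * len(sub_f))
              & (nc_m > 0) & (nc_f > 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            f_m = ca_m / np.maximum(nc_m, 1)
            f_f = ca_f / np.maximum(nc_f, 1)
        hi, lo = (f_m, f_f) if system == "XY" else (f_f, f_m)
        eps = 1e-9
        n_specific += ok & (hi == 1.0) & (lo == 0.0)
        n_linked += ok & (hi >= t_low - eps) & (lo <= 1.0 - t_low + eps)

    table = pd.DataFrame({
        "locus_id": matrix.locus_ids,
        "detection_frequency_specific": n_specific / mc_config.reps,
        "detection_frequency_linked": n_linked / mc_config.reps,
    })
    return SubsampleReport(
        table=table, mc_config=mc_config, scan_config=scan_config,
        system=system,
        n_males_drawn=k_m if mc_config.stratified_by_sex else exp_m,
        n_females_drawn=k_f if mc_config.stratified_by_sex else exp_f,
    )


class SubsampleReproducibility(BaseEstimator):
    """Estimator wrapper: fit(X, y) runs the subsampling test.

    ``X`` is samples × loci (NaN or −1 missing), ``y`` the sex labels.
    After fitting, ``detection_frequencies_`` holds the per-locus table.
    """

    def __init__(self, reps: int = 1000, subsample_fraction: float = 0.10,
                 stratified_by_sex: bool = True, min_per_sex: int = 2,
                 seed: int = 0, system: str = "XY", marker_type: str = "PA",
                 tiers: tuple = (0.70, 0.80, 0.90, 1.00)):
        self.reps = reps
        self.subsample_fraction = subsample_fraction
        self.stratified_by_sex = stratified_by_sex
        self.min_per_sex = min_per_sex
        self.seed = seed
        self.system = system
        self.marker_type = marker_type
        self.tiers = tiers

    def fit(self, X, y):
        from .scan import SexLinkageScanner
        X = np.asarray(X, dtype=float)
        y = SexLinkageScanner._normalize_y(y)
        calls = np.where(np.isnan(X), MISSING, X).astype(np.int8).T
        sample_ids = [f"S{i}" for i in range(X.shape[0])]
        matrix = GenotypeMatrix(calls, [f"L{j}" for j in range(X.shape[1])],
                                sample_ids, self.marker_type)
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": sample_ids, "sex": y, "population_id": "all"}))
        report = subsample_reproducibility(
            matrix, sheet,
            ScanConfig(system=self.system, tier_thresholds=tuple(self.tiers),
                       scope="pooled"),
            McConfig(reps=self.reps, subsample_fraction=self.subsample_fraction,
                     stratified_by_sex=self.stratified_by_sex,
                     min_per_sex=self.min_per_sex, seed=self.seed),
            system=self.system)
        self.n_features_in_ = X.shape[1]
        self.report_ = report
        self.detection_frequencies_ = report.table
        return self
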