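"""XY/ZW sex-linkage scan: tier classification and per-locus statistics.

A locus is screened by the fraction of called individuals in each sex
that carry its marker state (fragment presence for PA loci; alternate
allele presence for SNP loci, where a Y- or W-linked allele shows up
heterozygous in the heterogametic sex).  Under the XY hypothesis a
locus passes threshold t when the male carrier fraction is ≥ t and the
female fraction ≤ 1 − t; the tiers 0.70 / 0.80 / 0.90 mark sex-LINKED
loci (partial recombination with the sex locus) and the exact 0:100
pattern marks sex-SPECIFIC loci.  The ZW hypothesis mirrors the rule
with the sexes swapped.  Each classified locus also gets a
Cochran–Armitage trend test against sex, PIC / expected
heterozygosity, and (for SNPs) observed heterozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .distance import DistanceSummary, distance_summary, pairwise_distances
from .matrix import MISSING, GenotypeMatrix, SampleSheet
from .stats import kruskal_tiers

log = logging.getLogger(__name__)

PRESENCE_RULES = ("alt_allele_present", "het_only", "alt_hom_only")
TIER_NONE = "none"


@dataclass
class ScanConfig:
    """Scan hypotheses, tier thresholds and missing-data gates."""

    system: str = "both"                       # XY, ZW or both
    tier_thresholds: tuple = (0.70, 0.80, 0.90, 1.00)
    presence_rule_snp: str = "alt_allele_present"
    min_called_fraction_per_sex: float = 0.8
    scope: str = "both"                        # per_population, pooled or both

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW", "both"):
            raise ValueError(f"unknown system {self.system!r}")
        t = tuple(float(x) for x in self.tier_thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("tier thresholds must be strictly increasing")
        if not all(0.5 < x <= 1.0 for x in t):
            raise ValueError("tier thresholds must lie in (0.5, 1.0]")
        if t[-1] != 1.0:
            raise ValueError("last tier threshold must be 1.00 (sex-specific)")
        self.tier_thresholds = t
        if self.presence_rule_snp not in PRESENCE_RULES:
            raise ValueError(f"unknown presence rule {self.presence_rule_snp!r}")
        if not 0.0 <= self.min_called_fraction_per_sex <= 1.0:
            raise ValueError("min_called_fraction_per_sex outside [0, 1]")
        if self.scope not in ("per_population", "pooled", "both"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def systems(self) -> tuple[str, ...]:
        return ("XY", "ZW") if self.system == "both" else (self.system,)

    @property
    def tier_names(self) -> tuple[str, ...]:
        """Ordered low → high, e.g. ('linked_70', ..., 'specific')."""
        names = []
        for t in self.tier_thresholds:
            names.append("specific" if t == 1.0 else f"linked_{round(t * 100):d}")
        return tuple(names)


def carrier_mask(matrix: GenotypeMatrix,
                 presence_rule_snp: str = "alt_allele_present") -> np.ndarray:
    """Boolean loci × samples mask of marker-state carriers (missing = False)."""
    calls = matrix.calls
    if matrix.marker_type == "PA":
        return calls == 1
    if presence_rule_snp == "alt_allele_present":
        return (calls == 1) | (calls == 2)
    if presence_rule_snp == "het_only":
        return calls == 1
    return calls == 2


def carrier_frequencies(matrix: GenotypeMatrix, sheet: SampleSheet,
                        config: ScanConfig | None = None) -> pd.DataFrame:
    """Per-locus carrier fraction and called count per sex (pooled scope).

    Frequencies are over called individuals only; loci with zero called
    individuals in either sex are flagged uninformative (NaN frequency).
    """
    config = config or ScanConfig()
    sheet.require_both_sexes()
    sub = matrix.subset_samples([s for s in sheet.sample_ids
                                 if s in set(matrix.sample_ids)])
    if sub.n_samples != sheet.n_samples:
        missing = set(sheet.sample_ids) - set(matrix.sample_ids)
        raise KeyError(f"sheet samples absent from matrix: {sorted(missing)}")
    return _freq_table(sub, sheet, config)


def _freq_table(matrix: GenotypeMatrix, sheet: SampleSheet,
                config: ScanConfig) -> pd.DataFrame:
    carriers = carrier_mask(matrix, config.presence_rule_snp)
    called = matrix.called
    sex = sheet.sex_array(matrix.sample_ids)
    out = {"locus_id": matrix.locus_ids}
    for label, key in (("male", "m"), ("female", "f")):
        cols = sex == label
        n_called = called[:, cols].sum(axis=1)
        n_carrier = carriers[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_called > 0, n_carrier / np.maximum(n_called, 1), np.nan)
        out[f"f_carrier_{label}"] = freq
        out[f"n_called_{label}"] = n_called
        out[f"n_carrier_{label}"] = n_carrier
        out[f"n_{label}"] = int(cols.sum())
    df = pd.DataFrame(out)
    df["informative"] = (df["n_called_male"] > 0) & (df["n_called_female"] > 0)
    return df


def classify_locus(f_m: float, f_f: float, config: ScanConfig | None = None,
                   system: str = "XY") -> str:
    """Tier of a single locus from its per-sex carrier fractions.

    Returns the highest passed tier name, or ``"none"``.  ``specific``
    (threshold 1.00) demands the exact 1.0 / 0.0 pattern.
    """
    config = config or ScanConfig()
    if not (0.0 <= f_m <= 1.0 and 0.0 <= f_f <= 1.0):
        raise ValueError("carrier fractions must lie in [0, 1]")
    tiers = classify_array(np.array([f_m]), np.array([f_f]), config, system)
    return str(tiers[0])


def classify_array(f_m: np.ndarray, f_f: np.ndarray, config: ScanConfig,
                   system: str, eligible: np.ndarray | None = None) -> np.ndarray:
    """Vectorized tier classification; highest passed tier wins."""
    hi, lo = (f_m, f_f) if system == "XY" else (f_f, f_m)
    tiers = np.full(f_m.shape, TIER_NONE, dtype=object)
    ok = np.isfinite(f_m) & np.isfinite(f_f)
    if eligible is not None:
        ok &= eligible
    eps = 1e-9  # guards against float error in 1 − t; fractions are k/n
    for t, name in zip(config.tier_thresholds, config.tier_names):
        passed = ok & (hi >= t - eps) & (lo <= 1.0 - t + eps)
        tiers[passed] = name
    return tiers


def _catt_2x2(a, b, c, d):
    """Vectorized binary trend chi-square N(ad−bc)²/(R₁R₂C₁C₂) + p."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    N = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, N * (a * d - b * c) ** 2 / np.maximum(denom, 1), np.nan)
    from scipy.stats import chi2 as chi2_dist
    p = np.where(np.isfinite(chi2), chi2_dist.sf(chi2, df=1), np.nan)
    return chi2, p


def _biallelic_pic(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q = 1.0 - p
    he = 1.0 - p**2 - q**2
    pic = he - 2.0 * p**2 * q**2
    return pic, he


def locus_stats(matrix: GenotypeMatrix, sheet: SampleSheet,
                config: ScanConfig) -> pd.DataFrame:
    """Full per-locus statistics table for one sample scope."""
    df = _freq_table(matrix, sheet, config)
    if len(df) == 0:
        for system in config.systems:
            df[f"tier_{system}"] = pd.Series(dtype=object)
        for col in ("catt_chi2", "catt_p", "pic_botstein",
                    "expected_heterozygosity"):
            df[col] = pd.Series(dtype=float)
        return df
    n_m, n_f = df["n_male"].iloc[0], df["n_female"].iloc[0]
    gate = (
        (df["n_called_male"] >= config.min_called_fraction_per_sex * n_m)
        & (df["n_called_female"] >= config.min_called_fraction_per_sex * n_f)
    ).to_numpy()

    f_m = df["f_carrier_male"].to_numpy()
    f_f = df["f_carrier_female"].to_numpy()
    for system in config.systems:
        df[f"tier_{system}"] = classify_array(f_m, f_f, config, system, eligible=gate)

    chi2, p = _catt_2x2(
        df["n_carrier_male"], df["n_called_male"] - df["n_carrier_male"],
        df["n_carrier_female"], df["n_called_female"] - df["n_carrier_female"],
    )
    df["catt_chi2"] = chi2
    df["catt_p"] = p

    calls = matrix.calls
    called = matrix.called
    n_called = called.sum(axis=1)
    if matrix.marker_type == "SNP":
        n_het = (calls == 1).sum(axis=1)
        n_alt_hom = (calls == 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_called > 0,
                             (n_het + 2 * n_alt_hom) / np.maximum(2 * n_called, 1),
                             np.nan)
            df["observed_heterozygosity"] = np.where(
                n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        sex = sheet.sex_array(matrix.sample_ids)
        for label in ("male", "female"):
            cols = sex == label
            nc = called[:, cols].sum(axis=1)
            nh = (calls[:, cols] == 1).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                df[f"observed_heterozygosity_{label}"] = np.where(
                    nc > 0, nh / np.maximum(nc, 1), np.nan)
        freq = p_alt
    else:
        # dominant marker: use the presence/absence state frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_called > 0,
                            (calls == 1).sum(axis=1) / np.maximum(n_called, 1),
                            np.nan)
    pic_v, he = _biallelic_pic(freq)
    df["pic_botstein"] = pic_v
    df["expected_heterozygosity"] = he
    return df


def tier_comparison(per_locus: pd.DataFrame, system: str = "XY",
                    value: str = "observed_heterozygosity_male") -> tuple[float, float]:
    """Kruskal–Wallis H and p for a statistic across the tier groups."""
    col = f"tier_{system}"
    if col not in per_locus.columns:
        raise KeyError(f"no column {col!r} in scan table")
    groups = []
    for tier, grp in per_locus.groupby(col):
        if tier == TIER_NONE:
            continue
        vals = grp[value].dropna().to_numpy()
        if len(vals):
            groups.append(vals)
    return kruskal_tiers(groups)


@dataclass
class ScanResult:
    """Per-locus scan table plus tier-level summaries.

    ``per_locus`` is a long table with one row per locus per scope
    (``population`` is a population id or ``"pooled"``).
    """

    per_locus: pd.DataFrame
    config: ScanConfig
    marker_type: str
    distances: dict = field(default_factory=dict)  # (population, system, tier) → DistanceSummary
    skipped_populations: list = field(default_factory=list)

    def tier_counts(self) -> pd.DataFrame:
        """Counts of loci per population × system × tier (Table-1 layout)."""
        rows = []
        for system in self.config.systems:
            col = f"tier_{system}"
            g = (self.per_locus.groupby(["population", col], observed=True)
                 .size().reset_index(name="n_loci"))
            g = g[g[col] != TIER_NONE]
            for _, r in g.iterrows():
                rows.append({"population": r["population"], "system": system,
                             "tier": r[col], "n_loci": int(r["n_loci"]),
                             "marker_type": self.marker_type})
        return pd.DataFrame(rows, columns=["population", "system", "tier",
                                           "n_loci", "marker_type"])

    def loci_at(self, tier: str, system: str = "XY",
                population: str = "pooled") -> list[str]:
        t = self.per_locus
        sel = (t["population"] == population) & (t[f"tier_{system}"] == tier)
        return t.loc[sel, "locus_id"].tolist()

    def union_specific(self, system: str = "XY") -> list[str]:
        """Union of per-population sex-specific loci (excludes pooled)."""
        t = self.per_locus
        sel = (t["population"] != "pooled") & (t[f"tier_{system}"] == "specific")
        return sorted(t.loc[sel, "locus_id"].unique().tolist())

    def summary(self) -> dict:
        return {
            "marker_type": self.marker_type,
            "config": asdict(self.config),
            "tier_counts": self.tier_counts().to_dict(orient="records"),
            "union_specific": {s: self.union_specific(s)
                               for s in self.config.systems},
            "distances": {f"{pop}|{system}|{tier}": ds.to_dict()
                          for (pop, system, tier), ds in self.distances.items()},
            "skipped_populations": list(self.skipped_populations),
        }


def run_scan(matrix: GenotypeMatrix, sheet: SampleSheet,
             config: ScanConfig | None = None) -> ScanResult:
    """Scan a QC-passed matrix per population and/or pooled.

    Populations containing a single sex are skipped with a warning.
    Hamming-distance summaries are attached for every non-empty tier
    locus set in every scope and system.
    """
    config = config or ScanConfig()
    matrix = matrix.subset_samples(sheet.sample_ids)

    scopes: list[tuple[str, SampleSheet]] = []
    if config.scope in ("pooled", "both"):
        scopes.append(("pooled", sheet))
    if config.scope in ("per_population", "both"):
        for pop in sheet.populations:
            ids = sheet.table.loc[sheet.table["population_id"] == pop,
                                  "sample_id"].tolist()
            scopes.append((pop, sheet.subset(ids)))

    tables = []
    distances: dict = {}
    skipped: list[str] = []
    for label, sub_sheet in scopes:
        if not sub_sheet.males or not sub_sheet.females:
            log.warning("population %s has a single sex; skipped", label)
            skipped.append(label)
            continue
        sub = matrix.subset_samples(sub_sheet.sample_ids)
        stats = locus_stats(sub, sub_sheet, config)
        stats.insert(0, "population", label)
        tables.append(stats)
        for system in config.systems:
            for tier in config.tier_names:
                loci = stats.loc[stats[f"tier_{system}"] == tier,
                                 "locus_id"].tolist()
                if not loci:
                    continue
                dsub = sub.loc(loci)
                dist = pairwise_distances(dsub)
                distances[(label, system, tier)] = distance_summary(
                    dist, sub_sheet, n_loci_used=len(loci))

    per_locus = (pd.concat(tables, ignore_index=True) if tables
                 else pd.DataFrame())
    return ScanResult(per_locus=per_locus, config=config,
                      marker_type=matrix.marker_type, distances=distances,
                      skipped_populations=skipped)


class SexLinkageScanner(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector keeping sex-linked loci.

    ``X`` is samples × loci (NaN or −1 for missing); ``y`` holds sex
    labels (``"male"``/``"female"``, ``"M"``/``"F"``, or 1/0).  After
    :meth:`fit`, ``stats_`` holds the per-locus scan table and
    :meth:`transform` keeps the loci whose tier is in ``select``.
    """

    def __init__(self, system: str = "XY", tiers: tuple = (0.70, 0.80, 0.90, 1.00),
                 marker_type: str = "PA",
                 presence_rule_snp: str = "alt_allele_present",
                 min_called_fraction_per_sex: float = 0.8,
                 select: tuple = ("specific",)):
        self.system = system
        self.tiers = tiers
        self.marker_type = marker_type
        self.presence_rule_snp = presence_rule_snp
        self.min_called_fraction_per_sex = min_called_fraction_per_sex
        self.select = select

    def _scan_config(self) -> ScanConfig:
        system = self.system if self.system in ("XY", "ZW") else "both"
        return ScanConfig(system=system, tier_thresholds=tuple(self.tiers),
                          presence_rule_snp=self.presence_rule_snp,
                          min_called_fraction_per_sex=self.min_called_fraction_per_sex,
                          scope="pooled")

    @staticmethod
    def _normalize_y(y) -> np.ndarray:
        y = np.asarray(y)
        mapping = {"male": "male", "female": "female", "M": "male", "F": "female",
                   1: "male", 0: "female", True: "male", False: "female"}
        try:
            out = np.array([mapping[v] for v in y.tolist()], dtype=object)
        except KeyError as e:
            raise ValueError(f"unrecognized sex label {e.args[0]!r}") from e
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples × loci)")
        y = self._normalize_y(y)
        if len(y) != X.shape[0]:
            raise ValueError("y length must match the number of samples")
        calls = np.where(np.isnan(X), MISSING, X).astype(np.int8).T
        sample_ids = [f"S{i}" for i in range(X.shape[0])]
        matrix = GenotypeMatrix(calls, [f"L{j}" for j in range(X.shape[1])],
                                sample_ids, self.marker_type)
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": sample_ids, "sex": y, "population_id": "all"}))
        config = self._scan_config()
        stats = locus_stats(matrix, sheet, config)
        self.n_features_in_ = X.shape[1]
        self.stats_ = stats
        system = config.systems[0]
        self.tiers_ = stats[f"tier_{system}"].to_numpy()
        self.support_ = np.isin(self.tiers_, np.asarray(self.select, dtype=object))
        return self

    def _get_support_mask(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise AttributeError("SexLinkageScanner is not fitted")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.target_tags.required = True
        return tags
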