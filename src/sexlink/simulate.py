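"""Synthetic cohorts with planted sex-linked structure.

The generator emulates the study design this package analyses: a
five-population cohort of 40 males and 35 females genotyped at SNP and
dominant presence/absence (PA) loci, with a set of fully sex-linked
("specific") loci and partially linked loci planted inside a
sex-determining-region (SDR) interval on one chromosome.

Generative model
----------------
* specific loci: carrier state = heterogametic-sex indicator (males
  under XY, females under ZW);
* linked loci at recombination fraction r: carrier with probability
  1 − r in the heterogametic sex and r in the other;
* autosomal loci: allele frequency drawn from a uniform distribution;
  SNP genotypes are Hardy–Weinberg draws, PA presence is the dominant
  band probability 1 − (1 − p)²;
* then symmetric genotyping error (PA: state flip; SNP: move to an
  adjacent genotype code) and missingness, independently per cell.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream per call, so outputs are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, SampleSheet
from .mapping import SdrInterval

#: the five commercial populations of the study cohort
DEFAULT_POPULATIONS = (
    ("POP_BSPG", 0.2), ("POP_BSPGIA", 0.2), ("POP_BSPGL", 0.2),
    ("POP_BSPO", 0.2), ("POP_BSPW", 0.2),
)

N_CHROMOSOMES = 21
AUTOSOME_LENGTH = 25_000_000


@dataclass
class SimConfig:
    """Cohort layout, planted-locus design and noise levels."""

    seed: int
    n_males: int = 40
    n_females: int = 35
    populations: tuple = DEFAULT_POPULATIONS
    n_snp: int = 2000
    n_pa: int = 2000
    sd_system: str = "XY"                      # XY, ZW or PSD
    n_specific: int = 73
    linked_spec: tuple = ((50, 0.05), (50, 0.15), (50, 0.25))
    sdr_chromosome: str = "chr9"
    sdr_interval: tuple = (26_285_178, 31_930_103)
    missing_rate: float = 0.05
    genotype_error_rate: float = 0.01
    allele_freq_range: tuple = (0.05, 0.5)
    psd_switch_weights: tuple = (1.0, 0.6, 0.4)

    def __post_init__(self) -> None:
        if self.sd_system not in ("XY", "ZW", "PSD"):
            raise ValueError(f"unknown sd_system {self.sd_system!r}")
        for name in ("missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for n, r in self.linked_spec:
            if not 0.0 <= r <= 0.5:
                raise ValueError("recombination fraction must lie in [0, 0.5]")
            if n < 0:
                raise ValueError("linked locus counts must be non-negative")
        if self.n_specific < 0 or self.n_snp < 0 or self.n_pa < 0:
            raise ValueError("locus counts must be non-negative")
        lo, hi = self.sdr_interval
        n_planted = self.n_specific + sum(n for n, _ in self.linked_spec)
        if n_planted > hi - lo + 1:
            raise ValueError("more SDR loci than positions in the interval")
        if n_planted > self.n_snp + self.n_pa:
            raise ValueError("more planted loci than loci simulated")

    @property
    def n_samples(self) -> int:
        return self.n_males + self.n_females

    @property
    def heterogametic_sex(self) -> str:
        return "female" if self.sd_system == "ZW" else "male"


@dataclass
class SimTruth:
    """Planted labels and pre-noise carrier states for every locus."""

    table: pd.DataFrame          # locus_id, marker_type, label, r, chromosome, position
    carrier: dict = field(default_factory=dict)  # marker_type → bool (loci × samples)
    sample_ids: list = field(default_factory=list)

    def loci(self, label: str, marker_type: str | None = None) -> list[str]:
        t = self.table
        sel = t["label"] == label
        if marker_type is not None:
            sel &= t["marker_type"] == marker_type
        return t.loc[sel, "locus_id"].tolist()

    @property
    def planted_interval(self) -> SdrInterval:
        t = self.table[self.table["label"].isin(["specific", "linked"])]
        if len(t) == 0:
            raise ValueError("no planted SDR loci in truth")
        chrom = t["chromosome"].iloc[0]
        pos = t["position"]
        return SdrInterval(chromosome=chrom, start=int(pos.min()),
                           end=int(pos.max()), n_loci=len(t))


def _make_sheet(config: SimConfig, rng: np.random.Generator,
                sex: np.ndarray | None = None) -> SampleSheet:
    if sex is None:
        sex = np.array(["male"] * config.n_males + ["female"] * config.n_females)
    sample_ids = [f"BSP{i + 1:03d}" for i in range(config.n_samples)]
    # interleave the sexes before chunking so every population gets both
    order = np.argsort(rng.random(config.n_samples))
    shares = np.array([s for _, s in config.populations], dtype=float)
    shares = shares / shares.sum()
    bounds = np.floor(np.cumsum(shares) * config.n_samples).astype(int)
    pop_of = np.empty(config.n_samples, dtype=object)
    start = 0
    for (pop, _), stop in zip(config.populations, bounds):
        pop_of[order[start:stop]] = pop
        start = stop
    pop_of[order[start:]] = config.populations[-1][0]
    return SampleSheet(pd.DataFrame({
        "sample_id": sample_ids, "sex": sex, "population_id": pop_of}))


def _apply_noise(calls: np.ndarray, marker_type: str, config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    calls = calls.copy()
    e = config.genotype_error_rate
    if e > 0:
        flip = rng.random(calls.shape) < e
        if marker_type == "PA":
            calls[flip] = 1 - calls[flip]
        else:
            up = rng.random(calls.shape) < 0.5
            out = calls.copy()
            out[flip & (calls == 0)] = 1
            out[flip & (calls == 2)] = 1
            out[flip & (calls == 1) & up] = 2
            out[flip & (calls == 1) & ~up] = 0
            calls = out
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    return calls


def _meta_frame(locus_ids, marker_type: str, calls: np.ndarray,
                rng: np.random.Generator) -> pd.DataFrame:
    n = len(locus_ids)
    meta = pd.DataFrame(index=pd.Index(locus_ids, name="locus_id"))
    meta["reproducibility"] = rng.uniform(0.96, 1.0, n)
    meta["mean_depth"] = rng.uniform(10.0, 40.0, n)
    meta["allele_balance"] = (rng.uniform(0.92, 1.0, n)
                              if marker_type == "SNP" else np.nan)
    meta["call_rate"] = (calls != MISSING).mean(axis=1)
    return meta


def simulate_dataset(config: SimConfig
                     ) -> tuple[GenotypeMatrix, GenotypeMatrix, SampleSheet, SimTruth]:
    """Simulate (SNP matrix, PA matrix, sample sheet, ground truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # -- sex assignment -------------------------------------------------
    psd_switch_geno = None
    if config.sd_system == "PSD":
        k = len(config.psd_switch_weights)
        psd_switch_geno = rng.binomial(2, 0.5, size=(k, n))
        w = np.asarray(config.psd_switch_weights, dtype=float)
        liability = w @ psd_switch_geno + rng.normal(0.0, 0.5, size=n)
        male_rank = np.argsort(-liability, kind="stable")[: config.n_males]
        sex = np.full(n, "female", dtype=object)
        sex[male_rank] = "male"
    else:
        sex = np.array(["male"] * config.n_males + ["female"] * config.n_females,
                       dtype=object)
    sheet = _make_sheet(config, rng, sex)
    het = sheet.sex_array() == config.heterogametic_sex

    # -- planted design, split across marker types ---------------------
    plant: list[tuple[str, float]] = []
    if config.sd_system != "PSD":
        plant += [("specific", 0.0)] * config.n_specific
        for cnt, r in config.linked_spec:
            plant += [("linked", r)] * cnt
    n_total = config.n_snp + config.n_pa
    share_snp = config.n_snp / n_total if n_total else 0.0
    n_plant_snp = min(config.n_snp, int(round(len(plant) * share_snp)))
    plant_order = rng.permutation(len(plant))
    plant_snp = [plant[i] for i in plant_order[:n_plant_snp]]
    plant_pa = [plant[i] for i in plant_order[n_plant_snp:]]

    lo, hi = config.sdr_interval
    positions = rng.choice(hi - lo + 1, size=len(plant), replace=False) + lo

    truth_rows: list[dict] = []
    carrier_truth: dict[str, np.ndarray] = {}
    matrices: dict[str, GenotypeMatrix] = {}
    pos_cursor = 0

    for marker_type, n_loci, planted in (("SNP", config.n_snp, plant_snp),
                                         ("PA", config.n_pa, plant_pa)):
        prefix = "SNP" if marker_type == "SNP" else "PA"
        locus_ids = [f"{prefix}{i + 1:06d}" for i in range(n_loci)]
        calls = np.zeros((n_loci, n), dtype=np.int8)
        carrier = np.zeros((n_loci, n), dtype=bool)

        n_planted = len(planted)
        for i, (label, r) in enumerate(planted):
            if label == "specific":
                is_carrier = het.copy()
            else:
                p_carry = np.where(het, 1.0 - r, r)
                is_carrier = rng.random(n) < p_carry
            carrier[i] = is_carrier
            pos = int(positions[pos_cursor])
            pos_cursor += 1
            truth_rows.append({"locus_id": locus_ids[i], "marker_type": marker_type,
                               "label": label, "r": r if label == "linked" else np.nan,
                               "chromosome": config.sdr_chromosome, "position": pos})

        n_auto = n_loci - n_planted
        f_lo, f_hi = config.allele_freq_range
        p = rng.uniform(f_lo, f_hi, size=n_auto)
        auto_chrom = rng.integers(1, N_CHROMOSOMES + 1, size=n_auto)
        # keep autosomal loci off the SDR chromosome so chromosome counts
        # reconstruct the planted design exactly
        sdr_num = int(config.sdr_chromosome.lstrip("chr") or 9)
        auto_chrom[auto_chrom == sdr_num] = (sdr_num % N_CHROMOSOMES) + 1
        auto_pos = rng.integers(1, AUTOSOME_LENGTH + 1, size=n_auto)
        if marker_type == "SNP":
            geno = rng.binomial(2, p[:, None], size=(n_auto, n)).astype(np.int8)
            calls[n_planted:] = geno
            carrier[n_planted:] = geno > 0
        else:
            band = 1.0 - (1.0 - p[:, None]) ** 2
            present = rng.random((n_auto, n)) < band
            calls[n_planted:] = present.astype(np.int8)
            carrier[n_planted:] = present
        for j in range(n_auto):
            truth_rows.append({"locus_id": locus_ids[n_planted + j],
                               "marker_type": marker_type, "label": "autosomal",
                               "r": np.nan, "chromosome": f"chr{auto_chrom[j]}",
                               "position": int(auto_pos[j])})

        if marker_type == "SNP":
            calls[:n_planted][carrier[:n_planted]] = 1     # linked allele is het
            calls[:n_planted][~carrier[:n_planted]] = 0
            if psd_switch_geno is not None and n_loci >= len(psd_switch_geno):
                # overwrite the first loci with the liability switch loci
                for k_i in range(len(psd_switch_geno)):
                    calls[k_i] = psd_switch_geno[k_i]
                    carrier[k_i] = psd_switch_geno[k_i] > 0
                    truth_rows[-n_loci + k_i]["label"] = "switch"
        else:
            calls[:n_planted] = carrier[:n_planted].astype(np.int8)

        noisy = _apply_noise(calls, marker_type, config, rng)
        meta = _meta_frame(locus_ids, marker_type, noisy, rng)
        matrices[marker_type] = GenotypeMatrix(noisy, locus_ids,
                                               sheet.sample_ids, marker_type, meta)
        carrier_truth[marker_type] = carrier

    truth = SimTruth(table=pd.DataFrame(truth_rows), carrier=carrier_truth,
                     sample_ids=sheet.sample_ids)
    return matrices["SNP"], matrices["PA"], sheet, truth


def simulate_null_matrix(n_samples: int, n_loci: int, carrier_prob: float = 0.5,
                         seed: int = 0) -> GenotypeMatrix:
    """Independent fair-coin (or given-probability) PA carrier states.

    This is the null model behind the spurious-linkage probability
    P_i = 0.5ⁿ: every individual carries the fragment with probability
    ``carrier_prob`` independently of sex.
    """
    if n_samples < 1 or n_loci < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    calls = (rng.random((n_loci, n_samples)) < carrier_prob).astype(np.int8)
    return GenotypeMatrix(calls, [f"N{i + 1:07d}" for i in range(n_loci)],
                          [f"S{j + 1:03d}" for j in range(n_samples)], "PA")


def simulate_alignment_hits(truth: SimTruth,
                            noise: tuple[float, float] = (0.0, 0.0),
                            seed: int = 0, alignment_length: int = 69
                            ) -> pd.DataFrame:
    """Fabricate BLAST-tabular hits: one true hit per locus at its true
    position plus optional decoys.

    ``noise = (off_target_rate, identity_jitter)``.  With probability
    ``off_target_rate`` a locus gains two decoy hits: one below the
    identity filter (but with an inflated bit score, to exercise the
    filter) and one passing the filters with a lower bit score (to
    exercise the best-hit rule).  True-hit identity is 99 ± jitter.
    """
    off_rate, jitter = noise
    rng = np.random.default_rng(seed)
    half = alignment_length // 2
    rows = []
    for _, rec in truth.table.iterrows():
        pos = int(rec["position"])
        ident = min(100.0, 99.0 + rng.normal(0.0, jitter)) if jitter else 99.0
        minus = rng.random() < 0.5
        s1, s2 = pos - half, pos + half
        if minus:
            s1, s2 = s2, s1
        rows.append((rec["locus_id"], rec["chromosome"], round(ident, 2),
                     alignment_length, 1, 0, 1, alignment_length, s1, s2,
                     1e-30, 130.0))
        if off_rate and rng.random() < off_rate:
            decoy_chrom = f"chr{rng.integers(1, N_CHROMOSOMES + 1)}"
            decoy_pos = int(rng.integers(1, AUTOSOME_LENGTH))
            rows.append((rec["locus_id"], decoy_chrom, 94.0, 200, 10, 2,
                         1, alignment_length, decoy_pos, decoy_pos + 199,
                         1e-40, 250.0))
            rows.append((rec["locus_id"], decoy_chrom, 97.0, alignment_length,
                         2, 0, 1, alignment_length, decoy_pos,
                         decoy_pos + alignment_length - 1, 1e-10, 80.0))
    from .mapping import BLAST6_COLUMNS
    hits = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    minus = hits["s_start"] > hits["s_end"]
    hits["strand"] = np.where(minus, "-", "+")
    hits["s_lo"] = hits[["s_start", "s_end"]].min(axis=1)
    hits["s_hi"] = hits[["s_start", "s_end"]].max(axis=1)
    return hits


def write_blast_tab(hits: pd.DataFrame, path) -> None:
    """Write hits back to 12-column BLAST tabular text."""
    from .mapping import BLAST6_COLUMNS
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def simulate_repeat_annotation(composition: dict[str, int],
                               interval: SdrInterval, seed: int = 0
                               ) -> pd.DataFrame:
    """Place the requested number of fragments of each repeat label
    uniformly in the interval (by midpoint), so ``region_composition``
    on the full interval returns the input composition exactly."""
    from .repeats import classify_label
    rng = np.random.default_rng(seed)
    rows = []
    for label, count in composition.items():
        if count < 0:
            raise ValueError("fragment counts must be non-negative")
        cls, sub = classify_label(label)
        mids = rng.integers(interval.start, interval.end + 1, size=count)
        widths = rng.integers(50, 501, size=count)
        for mid, w in zip(mids, widths):
            start = max(1, int(mid) - int(w))
            end = 2 * int(mid) - start          # midpoint stays exactly mid
            rows.append({"chromosome": interval.chromosome, "start": start,
                         "end": end, "repeat_class": cls, "repeat_subclass": sub})
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                     "repeat_class", "repeat_subclass"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                     ).reset_index(drop=True)
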