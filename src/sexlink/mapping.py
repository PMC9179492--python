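"""Chromosome assignment of candidate loci from alignment hits.

Consumes precomputed BLAST tabular hits (outfmt 6), applies the
strict identity/length filters, assigns each locus to its best-scoring
hit, and derives the sex-determining-region (SDR) interval spanned by
the placed loci together with per-chromosome tier counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FormatError

log = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]

_NUMERIC = {
    "percent_identity": float, "alignment_length": int, "mismatches": int,
    "gap_opens": int, "q_start": int, "q_end": int, "s_start": int,
    "s_end": int, "e_value": float, "bit_score": float,
}


def read_blast_tab(path) -> pd.DataFrame:
    """Parse 12-column BLAST tabular hits.

    Minus-strand hits (s_start > s_end) get ``strand="-"`` and ordered
    ``s_lo``/``s_hi`` coordinates (1-based inclusive).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"line {lineno}: expected ≥12 tab-separated columns, "
                    f"got {len(parts)}")
            rec = dict(zip(BLAST6_COLUMNS, parts[:12]))
            try:
                for k, conv in _NUMERIC.items():
                    rec[k] = conv(rec[k])
            except ValueError as e:
                raise FormatError(f"line {lineno}: {e}") from e
            rows.append(rec)
    hits = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    if len(hits) == 0:
        hits["strand"] = pd.Series(dtype=str)
        hits["s_lo"] = pd.Series(dtype=int)
        hits["s_hi"] = pd.Series(dtype=int)
        return hits
    if (hits["percent_identity"].lt(0) | hits["percent_identity"].gt(100)).any():
        raise FormatError("percent identity outside [0, 100]")
    minus = hits["s_start"] > hits["s_end"]
    hits["strand"] = np.where(minus, "-", "+")
    hits["s_lo"] = hits[["s_start", "s_end"]].min(axis=1)
    hits["s_hi"] = hits[["s_start", "s_end"]].max(axis=1)
    return hits


@dataclass
class ChromosomeAssignment:
    """Best-hit placement per locus plus the loci left unplaced."""

    placed: pd.DataFrame     # index locus_id; chromosome, position, strand, stats
    unplaced: list[str]

    @property
    def n_placed(self) -> int:
        return len(self.placed)

    def on(self, chromosome: str) -> pd.DataFrame:
        return self.placed[self.placed["chromosome"] == chromosome]


def filter_and_assign(hits: pd.DataFrame, min_identity: float = 95.0,
                      min_length: int = 65) -> ChromosomeAssignment:
    """Keep hits with identity > min_identity and length > min_length
    (strict), then pick one best hit per locus.

    Ties on bit score break by lower e-value, then longer alignment,
    then lexicographic subject id.  The locus position is the midpoint
    of the subject interval (strand-independent).
    """
    all_loci = hits["query_id"].unique().tolist() if len(hits) else []
    ok = hits[(hits["percent_identity"] > min_identity)
              & (hits["alignment_length"] > min_length)].copy()
    if len(ok) == 0:
        placed = pd.DataFrame(columns=["chromosome", "position", "strand",
                                       "percent_identity", "alignment_length",
                                       "bit_score", "e_value"])
        placed.index.name = "locus_id"
        return ChromosomeAssignment(placed=placed, unplaced=sorted(all_loci))
    ok = ok.sort_values(
        by=["bit_score", "e_value", "alignment_length", "subject_id"],
        ascending=[False, True, False, True], kind="mergesort")
    best = ok.drop_duplicates(subset="query_id", keep="first").copy()
    best["position"] = ((best["s_lo"] + best["s_hi"]) // 2).astype(int)
    placed = (best.rename(columns={"subject_id": "chromosome"})
              .set_index("query_id")[["chromosome", "position", "strand",
                                      "percent_identity", "alignment_length",
                                      "bit_score", "e_value"]])
    placed.index.name = "locus_id"
    unplaced = sorted(set(all_loci) - set(placed.index))
    if unplaced:
        log.info("%d loci had no hit surviving the filters", len(unplaced))
    return ChromosomeAssignment(placed=placed, unplaced=unplaced)


def chromosome_counts(assignment: ChromosomeAssignment,
                      classifications: pd.Series) -> pd.DataFrame:
    """Chromosome × tier contingency counts with per-chromosome percentages.

    ``classifications`` maps locus_id → tier label; classified loci with
    no placement are counted in an ``"unplaced"`` row.
    """
    placed = assignment.placed
    rows = []
    for locus, tier in classifications.items():
        if locus in placed.index:
            rows.append({"chromosome": placed.loc[locus, "chromosome"],
                         "tier": tier})
        else:
            rows.append({"chromosome": "unplaced", "tier": tier})
    if not rows:
        return pd.DataFrame(columns=["chromosome", "tier", "n_loci", "percent"])
    df = pd.DataFrame(rows)
    counts = (df.groupby(["chromosome", "tier"], observed=True)
              .size().reset_index(name="n_loci"))
    total = counts["n_loci"].sum()
    counts["percent"] = (100.0 * counts["n_loci"] / total).round(3)
    return counts.sort_values(["chromosome", "tier"]).reset_index(drop=True)


@dataclass
class SdrInterval:
    """Minimal genomic interval spanned by a set of placed loci."""

    chromosome: str
    start: int            # 1-based inclusive
    end: int
    n_loci: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must not exceed end")
        if self.start < 1:
            raise ValueError("coordinates are 1-based and positive")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def span_mb(self) -> str:
        """Human-readable megabase rendering, one decimal (e.g. "5.6 Mb")."""
        return f"{self.span_bp / 1e6:.1f} Mb"

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def to_dict(self) -> dict:
        return {"chromosome": self.chromosome, "start": self.start,
                "end": self.end, "span_bp": self.span_bp,
                "span_mb": self.span_mb, "n_loci": self.n_loci}


def sdr_interval(assignment: ChromosomeAssignment, chromosome: str,
                 loci: list[str] | None = None) -> SdrInterval:
    """Minimal interval covering the placed loci on one chromosome."""
    placed = assignment.on(chromosome)
    if loci is not None:
        placed = placed[placed.index.isin(loci)]
    if len(placed) == 0:
        raise ValueError(f"no placed loci on {chromosome}")
    pos = placed["position"]
    return SdrInterval(chromosome=chromosome, start=int(pos.min()),
                       end=int(pos.max()), n_loci=len(placed))


def loci_in_region(assignment: ChromosomeAssignment,
                   interval: SdrInterval) -> tuple[int, float]:
    """Count and fraction of the chromosome's placed loci inside the interval."""
    on_chrom = assignment.on(interval.chromosome)
    if len(on_chrom) == 0:
        return (0, float("nan"))
    inside = on_chrom["position"].between(interval.start, interval.end)
    return (int(inside.sum()), float(inside.sum() / len(on_chrom)))


def region_percent(count: int, total: int) -> float:
    """Percentage to three decimals, as reported for region occupancy."""
    return round(100.0 * count / total, 3)


def write_karyotype_bed(assignment: ChromosomeAssignment, path) -> None:
    """Write placements as BED6 (0-based half-open); unplaced loci omitted."""
    placed = assignment.placed
    with open(path, "w") as fh:
        for locus, row in placed.iterrows():
            fh.write("\t".join([
                str(row["chromosome"]), str(int(row["position"]) - 1),
                str(int(row["position"])), str(locus),
                str(int(round(row["bit_score"]))), str(row["strand"]),
            ]) + "\n")
    if assignment.unplaced:
        log.info("omitted %d unplaced loci from BED", len(assignment.unplaced))


def read_karyotype_bed(path) -> pd.DataFrame:
    """Read back a karyotype BED; positions restored to 1-based."""
    rows = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            rows.append({"locus_id": name, "chromosome": chrom,
                         "position": int(start) + 1, "strand": strand})
    return pd.DataFrame(rows).set_index("locus_id")
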