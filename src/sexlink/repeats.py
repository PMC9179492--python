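"""Repeat-class composition of a genomic region.

Consumes an existing repeat annotation (RepeatMasker ``.out`` dialect
or a simple 4/5-column TSV), rolls subfamilies up to a fixed
class/subclass hierarchy (LTR retrotransposons → Ty3/Gypsy, Ty1/Copia;
non-LTR → LINE; DNA transposons → Helitron, Polinton, TIR; everything
unrecognized → unclassified), and tabulates fragment counts and
percentages for the fragments whose midpoint falls in the region.
Percentages use the grand total of top-level class fragments as the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import FormatError
from .mapping import SdrInterval

CLASS_HIERARCHY: dict[str, tuple[str, ...]] = {
    "LTR retrotransposon": ("Ty3/Gypsy", "Ty1/Copia"),
    "Non-LTR retrotransposon": ("LINE",),
    "DNA transposon": ("Helitron", "Polinton", "TIR"),
    "Repeat region (unclassified)": ("unclassified",),
}

#: RepeatMasker class/family label → (class, subclass)
_RM_LABELS = {
    "LTR/Gypsy": ("LTR retrotransposon", "Ty3/Gypsy"),
    "LTR/Ty3": ("LTR retrotransposon", "Ty3/Gypsy"),
    "LTR/Copia": ("LTR retrotransposon", "Ty1/Copia"),
    "LTR/Ty1": ("LTR retrotransposon", "Ty1/Copia"),
    "RC/Helitron": ("DNA transposon", "Helitron"),
    "DNA/Helitron": ("DNA transposon", "Helitron"),
    "DNA/Maverick": ("DNA transposon", "Polinton"),
    "DNA/Polinton": ("DNA transposon", "Polinton"),
}


def classify_label(label: str) -> tuple[str, str]:
    """Map a raw repeat label to the (class, subclass) hierarchy."""
    label = label.strip()
    if label in _RM_LABELS:
        return _RM_LABELS[label]
    if label in CLASS_HIERARCHY:
        return (label, CLASS_HIERARCHY[label][0])
    for cls, subs in CLASS_HIERARCHY.items():
        for sub in subs:
            if label == sub:
                return (cls, sub)
    head = label.split("/")[0]
    if head == "LINE":
        return ("Non-LTR retrotransposon", "LINE")
    if head == "DNA":
        # remaining DNA superfamilies (hAT, TcMar, ...) are TIR transposons
        return ("DNA transposon", "TIR")
    return ("Repeat region (unclassified)", "unclassified")


def read_repeat_table(path, dialect: str = "simple_tsv") -> pd.DataFrame:
    """Read a repeat annotation into (chromosome, start, end, class, subclass).

    ``repeatmasker_out`` expects the native whitespace layout with its
    three header lines; ``simple_tsv`` expects columns chromosome,
    start, end, repeat_label (tab-separated, with or without header).
    """
    rows = []
    if dialect == "repeatmasker_out":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith(("SW", "score", "*")):
                    continue
                parts = s.split()
                if len(parts) < 11:
                    raise FormatError(
                        f"line {lineno}: RepeatMasker rows need ≥11 fields")
                try:
                    chrom, start, end = parts[4], int(parts[5]), int(parts[6])
                except ValueError as e:
                    raise FormatError(f"line {lineno}: {e}") from e
                label = parts[10]
                rows.append((chrom, start, end, label))
    elif dialect == "simple_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.rstrip("\n")
                if not s:
                    continue
                parts = s.split("\t")
                if parts[0] in ("chromosome", "chrom"):
                    continue
                if len(parts) < 4:
                    raise FormatError(f"line {lineno}: expected ≥4 columns")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
                except ValueError as e:
                    raise FormatError(f"line {lineno}: {e}") from e
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    records = []
    for chrom, start, end, label in rows:
        if start > end:
            raise FormatError(f"repeat fragment with start > end on {chrom}")
        cls, sub = classify_label(label)
        records.append({"chromosome": chrom, "start": start, "end": end,
                        "repeat_class": cls, "repeat_subclass": sub})
    return pd.DataFrame(records, columns=["chromosome", "start", "end",
                                          "repeat_class", "repeat_subclass"])


def write_repeat_table(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out["label"] = out["repeat_subclass"]
    out[["chromosome", "start", "end", "label"]].to_csv(
        path, sep="\t", index=False, header=False)


@dataclass
class CompositionTable:
    """Fragment counts and percentages per repeat class and subclass."""

    table: pd.DataFrame   # columns: class, subclass (None for class rows), fragments, percent
    total: int

    @property
    def empty(self) -> bool:
        return self.total == 0

    def percent_of(self, name: str) -> float:
        t = self.table
        row = t[(t["subclass"] == name) | ((t["subclass"].isna()) & (t["class"] == name))]
        if len(row) == 0:
            raise KeyError(name)
        return float(row["percent"].iloc[0])

    def fragments_of(self, name: str) -> int:
        t = self.table
        row = t[(t["subclass"] == name) | ((t["subclass"].isna()) & (t["class"] == name))]
        if len(row) == 0:
            raise KeyError(name)
        return int(row["fragments"].iloc[0])

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def composition_from_counts(counts: dict[str, int]) -> CompositionTable:
    """Composition table from subclass (or class) fragment counts.

    The percentage denominator is the grand total over top-level
    classes, the only rule consistent with class rows summing to 100%.
    """
    by_sub: dict[str, int] = {}
    for label, n in counts.items():
        if n < 0:
            raise ValueError("fragment counts must be non-negative")
        _, sub = classify_label(label)
        by_sub[sub] = by_sub.get(sub, 0) + int(n)
    by_class = {
        cls: sum(by_sub.get(sub, 0) for sub in subs)
        for cls, subs in CLASS_HIERARCHY.items()
    }
    total = sum(by_class.values())
    rows = []
    for cls, subs in CLASS_HIERARCHY.items():
        if by_class[cls] == 0 and total > 0:
            continue
        pct = round(100.0 * by_class[cls] / total, 2) if total else 0.0
        rows.append({"class": cls, "subclass": None,
                     "fragments": by_class[cls], "percent": pct})
        for sub in subs:
            n = by_sub.get(sub, 0)
            if n == 0:
                continue
            pct = round(100.0 * n / total, 2) if total else 0.0
            rows.append({"class": cls, "subclass": sub,
                         "fragments": n, "percent": pct})
    table = pd.DataFrame(rows, columns=["class", "subclass", "fragments", "percent"])
    return CompositionTable(table=table, total=total)


def region_composition(annotation: pd.DataFrame,
                       interval: SdrInterval) -> CompositionTable:
    """Composition of the fragments whose midpoint lies in the interval."""
    a = annotation[annotation["chromosome"] == interval.chromosome]
    if len(a) == 0:
        return composition_from_counts({})
    mid = (a["start"] + a["end"]) // 2
    inside = a[mid.between(interval.start, interval.end)]
    counts = inside.groupby("repeat_subclass").size().to_dict()
    return composition_from_counts(counts)
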