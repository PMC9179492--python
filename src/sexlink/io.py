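"""Readers and writers for DArT-style genotype tables and sample sheets.

All formats are plain comma-separated text (gzip-transparent on read via
pandas).  Two genotype dialects are supported:

``two_row``
    SNP export with two consecutive rows per locus sharing a ``locus_id``:
    the first row scores the reference allele, the second the alternate.
    Per sample, (ref, alt) presence scores map to genotype codes
    ``(1,0) → 0``, ``(1,1) → 1``, ``(0,1) → 2``; a pair with a missing
    member — or the contradictory ``(0,0)`` — is recorded as missing.

``one_row``
    One row per locus; SNP cells are 0/1/2, PA cells are 0/1.

Columns whose header matches a metadata name (``reproducibility``,
``mean_depth``, ``allele_balance``, ``call_rate``, remappable through
``column_map``) are captured as locus metadata; every other non-id column
is a sample.
"""

from __future__ import annotations

import csv
import gzip
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import META_COLUMNS, MISSING, FormatError, GenotypeMatrix, SampleSheet

DEFAULT_MISSING_TOKENS = ("-", "", "NA")
WRITE_MISSING_TOKEN = "-"

DEFAULT_SEX_TOKENS: Mapping[str, str] = {
    "M": "male", "F": "female", "male": "male", "female": "female",
    "m": "male", "f": "female", "U": "unknown", "unknown": "unknown",
}


def _read_table(path, missing_tokens: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.replace({tok: None for tok in missing_tokens})


def _split_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None):
    """Partition columns into (id column, meta columns, sample columns)."""
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    if "locus_id" not in df.columns:
        raise FormatError("genotype table needs a 'locus_id' column "
                          "(or a column_map entry for it)")
    meta_cols = [c for c in df.columns if c in META_COLUMNS]
    sample_cols = [c for c in df.columns if c != "locus_id" and c not in meta_cols]
    if not sample_cols:
        raise FormatError("genotype table has no sample columns")
    return df, meta_cols, sample_cols


def _parse_calls(df: pd.DataFrame, sample_cols, legal: dict[str, int], kind: str) -> np.ndarray:
    calls = np.full((len(df), len(sample_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col].tolist()):
            if cell is None:
                continue
            cell = cell.strip()
            if cell not in legal:
                raise FormatError(
                    f"illegal {kind} call {cell!r} at row {i + 2}, column {col!r}"
                )
            calls[i, j] = legal[cell]
    return calls


def _collect_meta(df: pd.DataFrame, meta_cols, locus_ids) -> pd.DataFrame:
    meta = pd.DataFrame(np.nan, index=pd.Index(locus_ids, name="locus_id"),
                        columns=list(META_COLUMNS))
    for c in meta_cols:
        meta[c] = pd.to_numeric(df[c].to_numpy(), errors="coerce")
    return meta


def read_dart_pa(path, *, missing_tokens=DEFAULT_MISSING_TOKENS,
                 column_map: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read a SilicoDArT-style presence/absence table (one row per locus)."""
    df, meta_cols, sample_cols = _split_columns(
        _read_table(path, missing_tokens), column_map)
    locus_ids = df["locus_id"].tolist()
    if len(set(locus_ids)) != len(locus_ids):
        dup = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
        raise FormatError(f"duplicate locus ids: {dup}")
    calls = _parse_calls(df, sample_cols, {"0": 0, "1": 1}, "PA")
    meta = _collect_meta(df, meta_cols, locus_ids)
    return GenotypeMatrix(calls, locus_ids, sample_cols, "PA", meta)


def read_dart_snp(path, dialect: str = "two_row", *,
                  missing_tokens=DEFAULT_MISSING_TOKENS,
                  column_map: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read a DArTseq SNP table in the ``two_row`` or ``one_row`` dialect."""
    if dialect not in ("two_row", "one_row"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df, meta_cols, sample_cols = _split_columns(
        _read_table(path, missing_tokens), column_map)

    if dialect == "one_row":
        locus_ids = df["locus_id"].tolist()
        if len(set(locus_ids)) != len(locus_ids):
            dup = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
            raise FormatError(f"duplicate locus ids: {dup}")
        calls = _parse_calls(df, sample_cols, {"0": 0, "1": 1, "2": 2}, "SNP")
        meta = _collect_meta(df, meta_cols, locus_ids)
        return GenotypeMatrix(calls, locus_ids, sample_cols, "SNP", meta)

    if len(df) % 2 != 0:
        raise FormatError("two_row SNP table has an odd number of rows")
    allele = _parse_calls(df, sample_cols, {"0": 0, "1": 1}, "allele score")
    row_missing = np.zeros(allele.shape, dtype=bool)
    for j, col in enumerate(sample_cols):
        row_missing[:, j] = [cell is None for cell in df[col].tolist()]

    locus_ids: list[str] = []
    n_loci = len(df) // 2
    ids = df["locus_id"].tolist()
    for k in range(n_loci):
        a, b = ids[2 * k], ids[2 * k + 1]
        if a != b:
            raise FormatError(
                f"two_row pairing broken at rows {2 * k + 2}-{2 * k + 3}: "
                f"locus {a!r} vs {b!r} (a locus must span exactly two rows)"
            )
        locus_ids.append(a)
    if len(set(locus_ids)) != n_loci:
        dup = sorted({l for l in locus_ids if locus_ids.count(l) > 1})
        raise FormatError(f"locus appears in more than one row pair: {dup}")

    ref = allele[0::2, :]
    alt = allele[1::2, :]
    either_missing = row_missing[0::2, :] | row_missing[1::2, :]
    calls = np.full(ref.shape, MISSING, dtype=np.int8)
    ok = ~either_missing
    calls[ok & (ref == 1) & (alt == 0)] = 0
    calls[ok & (ref == 1) & (alt == 1)] = 1
    calls[ok & (ref == 0) & (alt == 1)] = 2
    # (0,0) — neither allele scored — stays MISSING
    meta = _collect_meta(df.iloc[0::2], meta_cols, locus_ids)
    return GenotypeMatrix(calls, locus_ids, sample_cols, "SNP", meta)


def read_sample_sheet(path, *, sex_tokens: Mapping[str, str] = DEFAULT_SEX_TOKENS,
                      column_map: Mapping[str, str] | None = None) -> SampleSheet:
    """Read a sample sheet with columns sample_id, sex, population_id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (column_map or {}).items()}
    df = df.rename(columns=rename)
    required = {"sample_id", "sex", "population_id"}
    if not required <= set(df.columns):
        raise FormatError(f"sample sheet requires columns {sorted(required)}")
    if len(df) == 0:
        raise FormatError("empty sample sheet")
    sexes = []
    for i, tok in enumerate(df["sex"].tolist()):
        if tok not in sex_tokens:
            raise FormatError(f"unrecognized sex token {tok!r} at row {i + 2}")
        sexes.append(sex_tokens[tok])
    df = df.assign(sex=sexes)
    return SampleSheet(df[["sample_id", "sex", "population_id"]])


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


def write_matrix(matrix: GenotypeMatrix, path, dialect: str | None = None) -> None:
    """Write a genotype matrix; ``read(write(m))`` reproduces ``m`` exactly.

    PA matrices use the one-row PA format.  SNP matrices default to
    ``one_row``; pass ``dialect="two_row"`` for the paired-row export.
    """
    path = Path(path)
    if matrix.marker_type == "PA":
        dialect = "pa"
    elif dialect is None:
        dialect = "one_row"

    meta_cols = [c for c in META_COLUMNS if matrix.meta[c].notna().any()]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus_id", *meta_cols, *matrix.sample_ids])

        def meta_cells(i):
            out = []
            for c in meta_cols:
                v = matrix.meta[c].iloc[i]
                out.append("" if pd.isna(v) else repr(float(v)))
            return out

        if dialect in ("pa", "one_row"):
            for i, locus in enumerate(matrix.locus_ids):
                cells = [WRITE_MISSING_TOKEN if v == MISSING else str(v)
                         for v in matrix.calls[i]]
                w.writerow([locus, *meta_cells(i), *cells])
        elif dialect == "two_row":
            # genotype code → (ref score, alt score)
            enc = {0: ("1", "0"), 1: ("1", "1"), 2: ("0", "1"),
                   MISSING: (WRITE_MISSING_TOKEN, WRITE_MISSING_TOKEN)}
            for i, locus in enumerate(matrix.locus_ids):
                pairs = [enc[int(v)] for v in matrix.calls[i]]
                w.writerow([locus, *meta_cells(i), *[p[0] for p in pairs]])
                w.writerow([locus, *meta_cells(i), *[p[1] for p in pairs]])
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_matrix(path, marker_type: str, dialect: str = "one_row", **kw) -> GenotypeMatrix:
    """Dispatch to :func:`read_dart_pa` / :func:`read_dart_snp` by marker type."""
    if marker_type == "PA":
        return read_dart_pa(path, **kw)
    return read_dart_snp(path, dialect=dialect, **kw)
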