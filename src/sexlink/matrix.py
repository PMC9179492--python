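"""Core in-memory containers: genotype matrices and sample sheets.

A :class:`GenotypeMatrix` stores calls as a dense ``int8`` array of shape
``(n_loci, n_samples)``.  SNP matrices use the codes 0 (reference
homozygote), 1 (heterozygote), 2 (alternate homozygote); dominant
presence/absence (PA) matrices use 0 (fragment absent) and 1 (fragment
present).  Missing calls are ``MISSING`` (−1) for either marker type.

A :class:`SampleSheet` maps each sample to its phenotypic sex and source
population, and drives every sex-stratified statistic in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: canonical per-locus metadata columns; NaN marks "unavailable"
META_COLUMNS = ("reproducibility", "mean_depth", "allele_balance", "call_rate")

_LEGAL_CODES = {"SNP": frozenset({0, 1, 2, MISSING}), "PA": frozenset({0, 1, MISSING})}


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


def _as_str_list(items: Iterable) -> list[str]:
    return [str(x) for x in items]


@dataclass
class GenotypeMatrix:
    """Loci × samples call matrix with per-locus QC metadata.

    Parameters
    ----------
    calls:
        ``int8`` array of shape ``(n_loci, n_samples)``.
    locus_ids, sample_ids:
        Unique identifiers for rows and columns.
    marker_type:
        ``"SNP"`` or ``"PA"``.
    meta:
        Optional per-locus metadata frame indexed like ``locus_ids`` with
        (a subset of) the columns in :data:`META_COLUMNS`.
    """

    calls: np.ndarray
    locus_ids: list[str]
    sample_ids: list[str]
    marker_type: str
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.locus_ids = _as_str_list(self.locus_ids)
        self.sample_ids = _as_str_list(self.sample_ids)
        if self.marker_type not in _LEGAL_CODES:
            raise ValueError(f"unknown marker_type {self.marker_type!r}")
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (loci × samples)")
        n_loci, n_samples = self.calls.shape
        if n_loci != len(self.locus_ids):
            raise ValueError("locus_ids length does not match calls")
        if n_samples != len(self.sample_ids):
            raise ValueError("sample_ids length does not match calls")
        if len(set(self.locus_ids)) != n_loci:
            raise ValueError("duplicate locus ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        legal = _LEGAL_CODES[self.marker_type]
        observed = set(np.unique(self.calls).tolist())
        if not observed <= legal:
            raise ValueError(
                f"illegal {self.marker_type} call codes: {sorted(observed - legal)}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(
                np.nan, index=pd.Index(self.locus_ids, name="locus_id"),
                columns=list(META_COLUMNS),
            )
        else:
            self.meta = self.meta.reindex(
                index=pd.Index(self.locus_ids, name="locus_id"),
                columns=list(META_COLUMNS),
            )

    # -- basic geometry ------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as ``calls``."""
        return self.calls != MISSING

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of samples with a non-missing call."""
        return self.called.mean(axis=1)

    # -- subsetting ----------------------------------------------------
    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.locus_ids[i] for i in index]
        return GenotypeMatrix(
            self.calls[index, :], ids, list(self.sample_ids),
            self.marker_type, self.meta.iloc[index],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            self.calls[:, cols], list(self.locus_ids), list(sample_ids),
            self.marker_type, self.meta,
        )

    def loc(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        return self.subset_loci([pos[l] for l in locus_ids])

    # -- interop -------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        """Samples × loci float array with NaN for missing calls.

        This is the orientation scikit-learn estimators expect.
        """
        X = self.calls.T.astype(float)
        X[X == MISSING] = np.nan
        return X

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=pd.Index(self.locus_ids, name="locus_id"),
                            columns=self.sample_ids)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.marker_type == other.marker_type
            and self.locus_ids == other.locus_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.calls, other.calls)
        )


SEXES = ("male", "female", "unknown")


@dataclass
class SampleSheet:
    """Sample metadata: id, phenotypic sex, population."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "sex", "population_id"}
        if not required <= set(self.table.columns):
            raise ValueError(f"sample sheet requires columns {sorted(required)}")
        t = self.table.reset_index(drop=True).copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["population_id"] = t["population_id"].astype(str)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        bad = ~t["sex"].isin(SEXES)
        if bad.any():
            raise ValueError(f"unrecognized sex values: {t.loc[bad, 'sex'].unique().tolist()}")
        if (t["population_id"].str.len() == 0).any():
            raise ValueError("empty population_id")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def ids_of(self, sex: str, population_id: str | None = None) -> list[str]:
        t = self.table
        mask = t["sex"] == sex
        if population_id is not None:
            mask &= t["population_id"] == population_id
        return t.loc[mask, "sample_id"].tolist()

    @property
    def males(self) -> list[str]:
        return self.ids_of("male")

    @property
    def females(self) -> list[str]:
        return self.ids_of("female")

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population_id"].unique().tolist())

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(t)

    def require_both_sexes(self) -> None:
        if not self.males or not self.females:
            raise ValueError("sex-stratified statistics need at least one male and one female")

    def sex_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Sex labels aligned with ``sample_ids`` (default: sheet order)."""
        s = self.table.set_index("sample_id")["sex"]
        if sample_ids is not None:
            s = s.loc[list(sample_ids)]
        return s.to_numpy()
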