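"""Marker quality filtering ahead of the sex scan.

Loci are retained only if they strictly exceed every applicable
threshold: reproducibility, mean sequencing depth, SNP allele balance,
and call rate.  Call rate is always recomputed from the call matrix
rather than trusted from metadata; the other criteria come from the
platform's per-locus metadata and are governed by a strictness policy
when unavailable.  Allele balance applies to SNP loci only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class QcConfig:
    """Thresholds for marker retention; all comparisons are strict (>)."""

    min_reproducibility: float = 0.95
    min_depth: float = 5.0
    min_allele_balance: float = 0.9
    min_call_rate: float = 0.8
    strictness: str = "drop_if_unavailable"

    def __post_init__(self) -> None:
        for name in ("min_reproducibility", "min_allele_balance", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if self.strictness not in ("drop_if_unavailable", "pass_if_unavailable"):
            raise ValueError(f"unknown strictness {self.strictness!r}")


@dataclass
class QcReport:
    """Per-criterion pass/fail flags and retention counts."""

    flags: pd.DataFrame          # loci × criteria booleans (True = pass)
    config: QcConfig
    n_input: int
    n_retained: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_retained

    def counts(self) -> pd.DataFrame:
        """Retained/dropped counts per criterion and overall."""
        rows = []
        for c in self.flags.columns:
            rows.append({"criterion": c,
                         "retained": int(self.flags[c].sum()),
                         "dropped": int((~self.flags[c]).sum())})
        rows.append({"criterion": "overall",
                     "retained": self.n_retained, "dropped": self.n_dropped})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"config": asdict(self.config), "n_input": self.n_input,
                "n_retained": self.n_retained, "n_dropped": self.n_dropped,
                "per_criterion": self.counts().to_dict(orient="records")}


def _criterion(values: np.ndarray, threshold: float, strictness: str) -> np.ndarray:
    """Strict-> pass mask with the unavailable-value policy applied."""
    values = np.asarray(values, dtype=float)
    passing = values > threshold
    unavailable = np.isnan(values)
    if strictness == "pass_if_unavailable":
        passing |= unavailable
    else:
        passing &= ~unavailable
    return passing


def qc_flags(matrix: GenotypeMatrix, config: QcConfig) -> pd.DataFrame:
    """Per-locus pass/fail flags for every applicable criterion."""
    s = config.strictness
    flags = pd.DataFrame(index=pd.Index(matrix.locus_ids, name="locus_id"))
    flags["reproducibility"] = _criterion(
        matrix.meta["reproducibility"].to_numpy(), config.min_reproducibility, s)
    flags["mean_depth"] = _criterion(
        matrix.meta["mean_depth"].to_numpy(), config.min_depth, s)
    if matrix.marker_type == "SNP":
        flags["allele_balance"] = _criterion(
            matrix.meta["allele_balance"].to_numpy(), config.min_allele_balance, s)
    # call rate is recomputable, so the unavailable policy never applies
    flags["call_rate"] = matrix.call_rate() > config.min_call_rate
    return flags


def apply_qc(matrix: GenotypeMatrix, config: QcConfig | None = None
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop every locus failing at least one applicable criterion."""
    config = config or QcConfig()
    flags = qc_flags(matrix, config)
    keep = flags.all(axis=1).to_numpy()
    report = QcReport(flags=flags, config=config,
                      n_input=matrix.n_loci, n_retained=int(keep.sum()))
    log.info("QC retained %d/%d %s loci", report.n_retained, report.n_input,
             matrix.marker_type)
    return matrix.subset_loci(keep), report


class MarkerQualityFilter(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector applying the marker QC thresholds.

    ``X`` is samples × loci with NaN for missing calls (the orientation of
    :attr:`GenotypeMatrix.X`).  Call rate is computed from ``X``; the
    metadata-backed criteria are used when a metadata frame is passed to
    :meth:`fit`.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[1.0, np.nan], [0.0, np.nan], [1.0, np.nan],
    ...               [1.0, 0.0], [0.0, 1.0]])
    >>> MarkerQualityFilter(min_call_rate=0.8).fit(X).get_support()
    array([ True, False])
    """

    def __init__(self, min_reproducibility: float = 0.95, min_depth: float = 5.0,
                 min_allele_balance: float = 0.9, min_call_rate: float = 0.8,
                 strictness: str = "drop_if_unavailable", marker_type: str = "PA"):
        self.min_reproducibility = min_reproducibility
        self.min_depth = min_depth
        self.min_allele_balance = min_allele_balance
        self.min_call_rate = min_call_rate
        self.strictness = strictness
        self.marker_type = marker_type

    def _config(self) -> QcConfig:
        return QcConfig(self.min_reproducibility, self.min_depth,
                        self.min_allele_balance, self.min_call_rate,
                        self.strictness)

    def fit(self, X, y=None, meta: pd.DataFrame | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples × loci)")
        config = self._config()
        n_loci = X.shape[1]
        call_rate = (~np.isnan(X)).mean(axis=0)
        passing = call_rate > config.min_call_rate
        if meta is not None:
            if len(meta) != n_loci:
                raise ValueError("meta rows must match the number of loci")
            s = config.strictness
            passing &= _criterion(meta["reproducibility"].to_numpy(),
                                  config.min_reproducibility, s)
            passing &= _criterion(meta["mean_depth"].to_numpy(),
                                  config.min_depth, s)
            if self.marker_type == "SNP":
                passing &= _criterion(meta["allele_balance"].to_numpy(),
                                      config.min_allele_balance, s)
        self.n_features_in_ = n_loci
        self.support_ = passing
        self.call_rate_ = call_rate
        return self

    def _get_support_mask(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise AttributeError("MarkerQualityFilter is not fitted")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags
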