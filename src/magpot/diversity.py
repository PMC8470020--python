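"""Amplicon alpha-diversity statistics and taxonomy aggregation.

Works on an ASV count table (asv_id, count, taxonomy). Chao1 corrects the
observed richness upward from the singleton/doubleton frequencies; the
optional ``corrected_singletons`` variant replaces the raw singleton count by
a Good-Turing estimate of the *true* number of singletons (sequencing errors
inflate f1), derived from the doubleton/tripleton ratio. Coverage is defined
as S_obs / Chao1. Taxonomy aggregation reproduces a composition bar plot's
display convention: groups above a strict relative-abundance cutoff are shown,
the rest pooled into "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

__all__ = [
    "DiversityResult",
    "chao1",
    "shannon",
    "coverage_estimate",
    "diversity_summary",
    "aggregate_relative_abundance",
]

UNCLASSIFIED = "unclassified"
OTHER = "other"


@dataclass(frozen=True)
class DiversityResult:
    s_obs: int
    f1: int
    f2: int
    f3: int
    f4: int
    chao1: float
    shannon: float
    coverage_pct: float

    @property
    def coverage_display(self) -> int:
        return int(round(self.coverage_pct))


def _positive_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0 or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be a non-empty numeric array")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("all counts are zero")
    return arr


def chao1(counts, corrected_singletons: bool = False) -> float:
    """Bias-corrected Chao1 richness estimate.

    Classic form: S_obs + f1*(f1-1) / (2*(f2+1)). With
    ``corrected_singletons=True`` the raw f1 is first replaced by the
    Good-Turing estimate f1_hat = 2*f2^2 / (3*f3) (ratio of successive
    frequency counts under a Poisson abundance model), then the same form is
    applied; when f3 = 0 the estimate is undefined and the classic form is
    used with a warning.
    """
    arr = _positive_counts(counts)
    if not corrected_singletons:
        return float(_skbio_chao1(arr.astype(int), bias_corrected=True))
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    f3 = int((arr == 3).sum())
    if f3 == 0:
        warnings.warn("corrected-singleton Chao1 undefined (f3 = 0); "
                      "falling back to the classic estimator")
        return chao1(counts, corrected_singletons=False)
    s_obs = int(arr.size)
    f1_hat = 2.0 * f2 * f2 / (3.0 * f3)
    return s_obs + f1_hat * (f1_hat - 1.0) / (2.0 * (f2 + 1.0))


def shannon(counts, log_base: float = np.e) -> float:
    """Shannon diversity H = -sum p_i log(p_i), natural log by default."""
    arr = _positive_counts(counts)
    return float(_skbio_shannon(arr.astype(int), base=log_base))


def coverage_estimate(s_obs: int, chao1_value: float) -> float:
    """Percent of the estimated true richness that was observed."""
    if s_obs <= 0:
        raise ValueError("observed richness must be positive")
    if chao1_value < s_obs:
        raise ValueError(
            f"chao1 ({chao1_value}) < observed richness ({s_obs}): "
            "violates the estimator contract")
    return 100.0 * s_obs / chao1_value


def diversity_summary(counts, log_base: float = np.e,
                      corrected_singletons: bool = False) -> DiversityResult:
    """One-stop summary: richness, frequency counts, Chao1, Shannon, coverage."""
    arr = _positive_counts(counts)
    est = chao1(arr, corrected_singletons=corrected_singletons)
    return DiversityResult(
        s_obs=int(arr.size),
        f1=int((arr == 1).sum()),
        f2=int((arr == 2).sum()),
        f3=int((arr == 3).sum()),
        f4=int((arr == 4).sum()),
        chao1=float(est),
        shannon=shannon(arr, log_base=log_base),
        coverage_pct=coverage_estimate(int(arr.size), est),
    )


def _group_at_rank(taxonomy: object, rank: int) -> str:
    if not isinstance(taxonomy, str) or not taxonomy.strip():
        return UNCLASSIFIED
    parts = [p.strip() for p in taxonomy.split(";")]
    if rank >= len(parts) or not parts[rank]:
        return UNCLASSIFIED
    return parts[rank]


def aggregate_relative_abundance(
    table: pd.DataFrame,
    rank: int,
    min_display_fraction: float = 0.01,
) -> Tuple[pd.Series, pd.Series]:
    """Sum ASV counts by the taxonomy group at ``rank`` (0-based index into
    the semicolon-delimited lineage) and convert to percentages.

    Returns ``(full, display)``: ``full`` holds every group's percentage
    (sums to 100); ``display`` keeps groups strictly above the cutoff and
    pools the remainder into a single "other" bucket.
    """
    for col in ("count", "taxonomy"):
        if col not in table.columns:
            raise ValueError(f"ASV table lacks column {col!r}")
    counts = table["count"].astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("ASV table has zero total count")
    groups = table["taxonomy"].map(lambda t: _group_at_rank(t, rank))
    pct = (100.0 * counts.groupby(groups).sum() / total).sort_values(ascending=False)
    keep = pct[pct > 100.0 * min_display_fraction]
    display = keep.copy()
    rest = float(pct.sum() - keep.sum())
    if rest > 0:
        display[OTHER] = rest
    return pct, display
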