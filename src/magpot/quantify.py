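"""Absolute quantification: qPCR standard curves and radiotracer AOM rates.

qPCR: the quantification cycle is linear in log10 of template copies,
Cq = intercept + slope * log10(copies). A standard dilution series is fitted
by least squares; amplification efficiency follows from the slope,
E% = (10^(-1/slope) - 1) * 100, so a perfect doubling per cycle gives
slope -3.3219 and 100%. Unknowns are inverted through the fitted line and a
target group's share of the community is the ratio of its copy number to the
total 16S copy number.

Radiotracer: a sediment sample spiked with 14C-methane converts a fraction of
the label to oxidation products over the incubation; the volumetric rate is
(product activity / total activity) * CH4 pool / incubation time, averaged
over replicates (mean +/- sample SD), with the killed-control rate
subtracted and the result clamped at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "RateResult",
    "fit_standard_curve",
    "copies_from_cq",
    "quantify_samples",
    "group_fraction",
    "aom_rate",
]

LOW_EFFICIENCY_WARN_PCT = 70.0


@dataclass(frozen=True)
class StandardCurve:
    slope: float        # Cq per log10(copies); negative for a valid curve
    intercept: float    # Cq at 1 copy
    r_squared: float

    @property
    def efficiency_pct(self) -> float:
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0


@dataclass(frozen=True)
class RateResult:
    rate: float          # nmol cm^-3 day^-1, control-subtracted
    sd: float
    n: int
    control_rate: float
    control_sd: float = 0.0


def fit_standard_curve(standards) -> StandardCurve:
    """Least-squares fit of Cq on log10(copies) for a dilution series.

    ``standards`` is a sequence of (copies, cq) pairs or a DataFrame with
    ``copies`` and ``cq`` columns. Requires >= 3 points with non-degenerate
    copy numbers; warns when the implied efficiency is below 70%.
    """
    if isinstance(standards, pd.DataFrame):
        copies = standards["copies"].to_numpy(dtype=float)
        cq = standards["cq"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(standards), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("standards must be (copies, cq) pairs")
        copies, cq = arr[:, 0], arr[:, 1]
    if len(copies) < 3:
        raise ValueError(f"need >= 3 standard points, got {len(copies)}")
    if (copies <= 0).any():
        raise ValueError("standard copy numbers must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("standard copy numbers are all identical")
    fit = stats.linregress(x, cq)
    curve = StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue) ** 2)
    if curve.slope >= 0:
        raise ValueError(f"fitted slope {curve.slope:.3f} is non-negative; "
                         "Cq must decrease with template amount")
    if curve.efficiency_pct < LOW_EFFICIENCY_WARN_PCT:
        warnings.warn(f"low amplification efficiency: {curve.efficiency_pct:.1f}%")
    return curve


def copies_from_cq(cq, curve: StandardCurve, volume_basis: float = 1.0):
    """Invert Cq values through the standard curve; scalar in, scalar out."""
    arr = np.asarray(cq, dtype=float)
    if not np.isfinite(arr).all():
        warnings.warn("non-finite Cq values skipped")
    result = 10.0 ** ((arr - curve.intercept) / curve.slope) * volume_basis
    if np.isscalar(cq) or arr.ndim == 0:
        return float(result)
    return result


def quantify_samples(
    samples: pd.DataFrame, curve: StandardCurve, volume_basis: float = 1.0
) -> pd.DataFrame:
    """Per-label mean and sample SD of copy numbers for replicated unknowns.

    ``samples`` needs columns ``label`` and ``cq``; non-finite Cq rows are
    skipped with a warning. Returns a frame indexed by label with columns
    copies_mean, copies_sd, n.
    """
    finite = samples[np.isfinite(samples["cq"].astype(float))]
    if len(finite) < len(samples):
        warnings.warn(f"skipped {len(samples) - len(finite)} rows with non-finite Cq")
    rows = []
    for label, group in finite.groupby("label", sort=False):
        copies = copies_from_cq(group["cq"].to_numpy(dtype=float), curve, volume_basis)
        rows.append({
            "label": label,
            "copies_mean": float(np.mean(copies)),
            "copies_sd": float(np.std(copies, ddof=1)) if len(copies) > 1 else 0.0,
            "n": int(len(copies)),
        })
    return pd.DataFrame(rows).set_index("label")


def group_fraction(target_copies: float, total_copies: float) -> float:
    """Percent share of a target group in the total community, by copy number."""
    if total_copies <= 0:
        raise ValueError("total copy number must be positive")
    pct = 100.0 * target_copies / total_copies
    if pct > 100.0:
        warnings.warn(f"group fraction exceeds 100% ({pct:.2f}%)")
    return pct


def _replicate_rates(records: pd.DataFrame, ch4_pool: float, days: float) -> np.ndarray:
    a_prod = records["a_product"].to_numpy(dtype=float)
    a_tot = records["a_total"].to_numpy(dtype=float)
    if (a_tot <= 0).any():
        raise ValueError("total activity must be positive")
    if (a_prod < 0).any():
        raise ValueError("product activity must be non-negative")
    bad = a_prod > a_tot
    if bad.any():
        raise ValueError(
            f"rejecting {int(bad.sum())} record(s) with product activity "
            "exceeding total activity")
    return (a_prod / a_tot) * ch4_pool / days


def aom_rate(
    samples: pd.DataFrame,
    controls: Optional[pd.DataFrame],
    ch4_pool: float,
    days: float,
) -> RateResult:
    """Anaerobic methane-oxidation rate from tracer incubations.

    ``samples``/``controls`` carry columns ``a_product`` and ``a_total``
    (activities of the oxidation-product and total label pools). The rate per
    replicate is (a_product / a_total) * ch4_pool / days; the reported rate is
    the replicate mean minus the mean killed-control rate, clamped at zero
    with a warning, +/- the sample SD (n-1).
    """
    if days <= 0:
        raise ValueError("incubation time must be positive")
    if ch4_pool <= 0:
        raise ValueError("methane pool must be positive")
    rates = _replicate_rates(samples, ch4_pool, days)
    if controls is not None and len(controls):
        control_rates = _replicate_rates(controls, ch4_pool, days)
        control_rate = float(np.mean(control_rates))
        control_sd = float(np.std(control_rates, ddof=1)) if len(control_rates) > 1 else 0.0
    else:
        control_rate, control_sd = 0.0, 0.0
    net = float(np.mean(rates)) - control_rate
    if net < 0:
        warnings.warn("control-subtracted rate is negative; clamped to 0")
        net = 0.0
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return RateResult(rate=net, sd=sd, n=int(len(rates)),
                      control_rate=control_rate, control_sd=control_sd)
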