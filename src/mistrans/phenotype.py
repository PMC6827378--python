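"""Growth-curve fitting, doubling times and reporter fold changes.

Cultures sampled on a microplate reader (OD600 every 15 min over 24 h) are
fit with the three-parameter logistic N(t) = K / (1 + ((K - N0)/N0) e^(-rt));
the doubling time is ln 2 / r. Variant toxicity is reported as the fold
increase of doubling time over the wild-type control, heat-shock reporter
induction as the ratio of density-normalized fluorescence means, and RTD
susceptibility as a colony-size ratio with a Welch test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .calling import welch_t_test

LN2 = math.log(2.0)


def logistic(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    """Three-parameter logistic growth model."""
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * np.asarray(t, dtype=float)))


@dataclass
class GrowthCurve:
    strain_id: str
    replicate_id: str
    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray  # OD600, non-negative

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValueError("times and od differ in length")
        if self.times.size < 10:
            raise ValueError("growth curve needs at least 10 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("negative OD reading")


@dataclass
class GrowthFit:
    K: float
    N0: float
    r: float  # 1/min
    rss: float
    converged: bool
    strain_id: str = ""
    replicate_id: str = ""

    @property
    def doubling_time(self) -> float:
        """t_d = ln 2 / r, minutes."""
        return LN2 / self.r


@dataclass
class FoldChange:
    value: float
    numerator_id: str = ""
    denominator_id: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("fold change must be positive")

    @property
    def rounded(self) -> float:
        """One decimal place, the convention used for reported folds."""
        return round(self.value, 1)


def fit_logistic(curve: GrowthCurve) -> GrowthFit:
    """Least-squares logistic fit of one growth curve.

    Initialization: K from the plateau, N0 from the first reading, r from
    the log-OD slope over the first quartile of points. Failure to converge
    (or a curve with no net growth) yields ``converged=False`` rather than
    an exception.
    """
    t, od = curve.times, curve.od
    failed = GrowthFit(
        K=float(od.max()), N0=float(od[0]), r=np.nan, rss=np.nan,
        converged=False, strain_id=curve.strain_id, replicate_id=curve.replicate_id,
    )
    if od[-1] <= od[0] or od.max() <= 0:
        return failed
    K0 = float(od.max())
    N00 = float(max(od[0], 1e-6))
    q = max(3, t.size // 4)
    with np.errstate(divide="ignore"):
        log_od = np.log(np.maximum(od[:q], 1e-9))
    slope = float(np.polyfit(t[:q], log_od, 1)[0])
    r0 = slope if slope > 0 else LN2 / 90.0
    try:
        popt, _ = curve_fit(
            logistic,
            t,
            od,
            p0=[K0, N00, r0],
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return failed
    K, N0, r = (float(v) for v in popt)
    rss = float(np.sum((logistic(t, K, N0, r) - od) ** 2))
    converged = K > N0 > 0 and r > 0
    return GrowthFit(
        K=K, N0=N0, r=r, rss=rss, converged=converged,
        strain_id=curve.strain_id, replicate_id=curve.replicate_id,
    )


def relative_doubling_time(variant: GrowthFit, reference: GrowthFit) -> FoldChange:
    """Fold increase of the variant's doubling time over the reference's."""
    if not (variant.converged and reference.converged):
        raise ValueError("both fits must have converged")
    return FoldChange(
        value=variant.doubling_time / reference.doubling_time,
        numerator_id=variant.strain_id,
        denominator_id=reference.strain_id,
    )


def doubling_time_fold(variant_td: float, reference_td: float) -> FoldChange:
    """Fold change from doubling times directly (e.g. tabulated values)."""
    if variant_td <= 0 or reference_td <= 0:
        raise ValueError("doubling times must be positive")
    return FoldChange(value=variant_td / reference_td)


def heat_shock_fold(
    variant_readings: Sequence[float],
    reference_readings: Sequence[float],
    variant_id: str = "",
    reference_id: str = "",
) -> FoldChange:
    """Mean density-normalized fluorescence of variant over reference."""
    if len(variant_readings) < 1 or len(reference_readings) < 1:
        raise ValueError("need at least one reading per strain")
    ref_mean = float(np.mean(reference_readings))
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return FoldChange(
        value=float(np.mean(variant_readings)) / ref_mean,
        numerator_id=variant_id,
        denominator_id=reference_id,
    )


def colony_ratio_test(
    sizes_wt_background: Sequence[float],
    sizes_mutant_background: Sequence[float],
    alpha: float = 0.05,
) -> Tuple[float, float, bool]:
    """Ratio of mean colony sizes (wild-type over mutant background) with
    a Welch test; returns (ratio, two-sided p, significant-at-alpha)."""
    if len(sizes_wt_background) < 2 or len(sizes_mutant_background) < 2:
        raise ValueError("need at least 2 colony sizes per group")
    mut_mean = float(np.mean(sizes_mutant_background))
    if mut_mean <= 0:
        raise ValueError("mutant-background mean must be positive")
    ratio = float(np.mean(sizes_wt_background)) / mut_mean
    _, _, p = welch_t_test(list(sizes_wt_background), list(sizes_mutant_background))
    return ratio, p, p < alpha


def fit_growth_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit every (strain, replicate) curve of a long-format growth table.

    Expects columns strain_id, replicate_id, time_min, od600; returns one
    row per curve with the fitted parameters and doubling time.
    """
    required = {"strain_id", "replicate_id", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing column(s): {sorted(missing)}")
    rows = []
    for (strain, rep), grp in df.groupby(["strain_id", "replicate_id"], sort=True):
        grp = grp.sort_values("time_min")
        fit = fit_logistic(
            GrowthCurve(str(strain), str(rep), grp["time_min"].to_numpy(),
                        grp["od600"].to_numpy())
        )
        rows.append(
            {
                "strain_id": strain,
                "replicate_id": rep,
                "K": fit.K,
                "N0": fit.N0,
                "r_per_min": fit.r,
                "doubling_time_min": fit.doubling_time if fit.converged else np.nan,
                "rss": fit.rss,
                "converged": int(fit.converged),
            }
        )
    return pd.DataFrame(rows)


def strain_doubling_times(fits: pd.DataFrame) -> Dict[str, float]:
    """Mean doubling time per strain from a fit table (converged fits only)."""
    ok = fits[fits["converged"] == 1]
    return ok.groupby("strain_id")["doubling_time_min"].mean().to_dict()
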