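"""Robustness statistics for denoising-response distributions.

Metric distributions coming out of the sweep are screened for normality with
a Chi-squared goodness-of-fit test (they are essentially never normal), and
two datasets' distributions are then compared per wavelet family with the
Mann–Whitney U test. A family whose response does not shift between datasets
is considered robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRICS
from .response import VolumetricResponse, best_values_flat


@dataclass
class StatTestResult:
    test: str  # "chi2_normality" | "mann_whitney"
    statistic: float
    p_value: float
    alpha: float = 0.05
    reject: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        self.reject = bool(self.p_value < self.alpha)


def sturges_bins(n: int) -> int:
    """Sturges' rule k = ceil(1 + 3.322·log10 n)."""
    return int(np.ceil(1.0 + 3.322 * np.log10(n)))


def chi2_normality(
    samples, alpha: float = 0.05, n_bins: int | None = None
) -> StatTestResult:
    """Chi-squared goodness-of-fit test of normality.

    Bins are equal-probability under N(μ̂, σ̂²) fitted to the sample; the
    statistic Σ(Oᵢ−Eᵢ)²/Eᵢ is referred to χ² with k−3 degrees of freedom
    (two estimated parameters). Requires n ≥ 20 and nonzero variance.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    n = x.size
    if n < 20:
        raise ValueError(f"need n >= 20 samples, got {n}")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: normality test undefined")
    k = n_bins if n_bins is not None else sturges_bins(n)
    if k < 4:
        raise ValueError("need at least 4 bins for dof = k - 3 >= 1")
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, k + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=np.concatenate(([-np.inf], edges[1:-1], [np.inf])))
    expected = n / k
    statistic = float(np.sum((observed - expected) ** 2) / expected)
    p = float(stats.chi2.sf(statistic, df=k - 3))
    return StatTestResult("chi2_normality", statistic, p, alpha)


def mann_whitney(
    x, y, alternative: str = "two-sided", alpha: float = 0.05
) -> StatTestResult:
    """Mann–Whitney U test comparing the locations of two samples.

    The U statistic comes from rank sums with midranks for ties. The p-value
    is exact (full enumeration of rank assignments) when both samples have at
    most 8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return StatTestResult("mann_whitney", float(res.statistic), float(res.pvalue), alpha)


def compare_datasets(
    responses_a: dict[str, dict[str, VolumetricResponse]],
    responses_b: dict[str, dict[str, VolumetricResponse]],
    metrics: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family Mann–Whitney comparison of two datasets' best-value
    distributions, with Chi-squared normality screening alongside.

    Inputs are nested ``{family: {metric: VolumetricResponse}}`` mappings for
    each dataset; the populations compared are the per-η-per-item best values
    (one value per noise level per input item). Returns a tidy frame with one
    row per (family, metric).
    """
    if set(responses_a) != set(responses_b):
        raise ValueError("datasets must cover the same families")
    rows = []
    for family in responses_a:
        fam_a, fam_b = responses_a[family], responses_b[family]
        use_metrics = metrics if metrics is not None else tuple(
            m for m in METRICS if m in fam_a and m in fam_b
        )
        for m in use_metrics:
            vr_a, vr_b = fam_a[m], fam_b[m]
            if vr_a.metric != vr_b.metric:
                raise ValueError("metric mismatch between datasets")
            if not np.array_equal(vr_a.schedule.levels, vr_b.schedule.levels):
                raise ValueError("schedules must match between datasets")
            a = best_values_flat(vr_a)
            b = best_values_flat(vr_b)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            mw = mann_whitney(a, b, alpha=alpha)
            rows.append(
                {
                    "family": family,
                    "metric": m,
                    "mw_u": mw.statistic,
                    "mw_p": mw.p_value,
                    "reject_equal_medians": mw.reject,
                    "chi2_p_a": _screen(a, alpha),
                    "chi2_p_b": _screen(b, alpha),
                }
            )
    return pd.DataFrame(rows)


def _screen(sample: np.ndarray, alpha: float) -> float:
    try:
        return chi2_normality(sample, alpha=alpha).p_value
    except ValueError:
        return float("nan")


def comparison_table(tidy: pd.DataFrame, value: str = "mw_p") -> pd.DataFrame:
    """Pivot the tidy comparison frame into the families × metrics layout."""
    return tidy.pivot(index="family", columns="metric", values=value)
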