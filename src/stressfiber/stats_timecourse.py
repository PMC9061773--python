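"""Population statistics over per-cell OOPs and fiber counts.

Implements the summary and inference conventions used downstream of the
extraction: two-sample equal-variance (pooled, Student) t-tests at the 5%
level, Pearson correlation, mean +- SEM summaries, boxplot statistics with
1.5 x IQR whiskers, and OOP-versus-time table assembly with optional
per-timepoint treatment-versus-control comparison.

Quantiles throughout use linear interpolation between order statistics
(type-7), so the printed boxplot numbers are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PopulationSample",
    "TTestResult",
    "BoxplotStats",
    "two_sample_ttest",
    "pearson_correlation",
    "summarize_population",
    "boxplot_stats",
    "assemble_timecourse",
]


@dataclass(frozen=True)
class PopulationSample:
    """A labelled sample of per-cell scalars (OOPs or fiber counts)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if v.size < 1:
            raise ValueError("a population sample needs at least one value")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_value: float
    reject_at_alpha: bool
    alpha: float


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def two_sample_ttest(a: PopulationSample, b: PopulationSample,
                     alpha: float = 0.05) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-sided.

    Tests the null that both samples come from normal distributions with
    equal means and equal variances; rejection at the given significance
    level (default 5%).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    x, y = a.values, b.values
    n1, n2 = a.n, b.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    t_stat = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t_stat), df)
    return TTestResult(t_stat=float(t_stat), df=int(df), p_value=float(p),
                       reject_at_alpha=bool(p < alpha), alpha=alpha)


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1D arrays with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def summarize_population(s: PopulationSample) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd / sqrt(n)).

    SEM is NaN for n < 2, where the sample sd is undefined.
    """
    mean = float(s.values.mean())
    if s.n < 2:
        return mean, float("nan")
    sem = float(s.values.std(ddof=1) / np.sqrt(s.n))
    return mean, sem


def boxplot_stats(s: PopulationSample) -> BoxplotStats:
    """Median, quartile box, 1.5 x IQR whiskers and outliers.

    Whiskers extend to the most extreme data points within 1.5 x IQR of the
    box edges; anything beyond is an outlier.
    """
    v = np.sort(s.values)
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # type-7 interpolation
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(median=float(q50), q25=float(q25), q75=float(q75),
                        whisker_low=float(inside.min()),
                        whisker_high=float(inside.max()),
                        outliers=outliers)


def assemble_timecourse(samples, control: list[PopulationSample] | None = None,
                        alpha: float = 0.05,
                        bonferroni: bool = False) -> pd.DataFrame:
    """Build a (time, n, mean, sem) table from time-labelled samples.

    ``samples`` is a list of :class:`PopulationSample` whose labels parse as
    numeric times in hours.  If ``control`` is given (a second condition
    sampled at the same times), a per-timepoint pooled t-test column is
    added; ``bonferroni`` optionally scales alpha by the number of shared
    timepoints (off by default — raw per-timepoint tests are the reported
    convention).
    """
    if not samples:
        raise ValueError("need at least one sample")

    def _parse(label: str) -> float:
        try:
            return float(label)
        except ValueError as exc:
            raise ValueError(f"time label {label!r} is not numeric") from exc

    times = [_parse(s.label) for s in samples]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time labels")
    rows = []
    control_by_time = {}
    if control is not None:
        control_by_time = {_parse(s.label): s for s in control}
        if len(control_by_time) != len(control):
            raise ValueError("duplicate time labels in control condition")
    shared = [t for t in times if t in control_by_time]
    eff_alpha = alpha / max(1, len(shared)) if (bonferroni and shared) else alpha
    for t, s in sorted(zip(times, samples)):
        mean, sem = summarize_population(s)
        row = {"time_h": t, "n": s.n, "mean_oop": mean, "sem_oop": sem}
        if control is not None and t in control_by_time:
            c = control_by_time[t]
            res = two_sample_ttest(s, c, alpha=eff_alpha)
            row.update({"t_stat": res.t_stat, "p_value": res.p_value,
                        "reject": res.reject_at_alpha})
        rows.append(row)
    return pd.DataFrame(rows)
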