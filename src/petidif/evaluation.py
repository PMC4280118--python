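"""Method-agreement statistics for input functions and V_T estimates.

Two input functions are compared by peak/tail AUC ratios (peak = first 180 s
of scan); two sets of regional V_T estimates by ordinary least-squares
regression (r^2, slope, intercept, slope t-test) and Bland-Altman analysis
(bias and 95% limits of agreement). The Amari index, a permutation- and
scale-invariant distance between a demixing estimate and the true mixing,
benchmarks the source-separation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .curves import TimeActivityCurve


@dataclass
class AgreementStats:
    """Container for regression and Bland-Altman agreement fields."""

    r2: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    t_statistic: float = np.nan
    p_value: float = np.nan
    bias: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan
    loa_width: float = np.nan
    n_within: int = 0
    n: int = 0
    plot_data: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("r2", "slope", "intercept", "t_statistic", "p_value",
                 "bias", "loa_low", "loa_high", "loa_width", "n_within", "n")}


def auc_ratio(test: TimeActivityCurve, ref: TimeActivityCurve,
              peak_window: float = 180.0) -> tuple[float, float]:
    """(peak, tail) AUC ratios test/ref: trapezoids on [0, 180 s] and beyond."""
    t0 = max(test.times[0], ref.times[0], 0.0)
    t1 = min(test.times[-1], ref.times[-1])
    split = min(peak_window, t1)
    ref_peak, ref_tail = ref.auc(t0, split), ref.auc(split, t1)
    if ref_peak <= 0 or (t1 > split and ref_tail <= 0):
        raise ValueError("reference AUC is zero")
    peak = test.auc(t0, split) / ref_peak
    tail = test.auc(split, t1) / ref_tail if t1 > split else np.nan
    return peak, tail


def regression_agreement(x, y) -> AgreementStats:
    """OLS y = b0 + b1 x with r^2 and the slope-vs-zero t-test (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:  # flat y: slope and correlation are exactly zero
        return AgreementStats(r2=0.0, slope=0.0, intercept=float(y[0]),
                              t_statistic=0.0, p_value=1.0, n=x.size)
    res = stats.linregress(x, y)
    t_stat = res.slope / res.stderr if res.stderr > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t_stat), x.size - 2)
    return AgreementStats(r2=res.rvalue ** 2, slope=res.slope,
                          intercept=res.intercept, t_statistic=t_stat,
                          p_value=p, n=x.size)


def bland_altman(x, y, quantile: float = 1.96) -> AgreementStats:
    """Bland-Altman agreement of paired measurements (differences x - y).

    bias = mean difference; 95% limits of agreement = bias +/- 1.96 SD
    (sample SD, n-1); loa_width is the full width between the limits.
    ``quantile`` can be swapped for a small-sample t quantile.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - quantile * sd, bias + quantile * sd
    within = int(np.sum((d >= lo) & (d <= hi)))
    return AgreementStats(bias=bias, loa_low=lo, loa_high=hi,
                          loa_width=2.0 * quantile * sd, n_within=within,
                          n=x.size,
                          plot_data={"means": (x + y) / 2.0, "diffs": d})


def bland_altman_plot(stats_: AgreementStats, ax=None, label: str = ""):
    """Render the classic means-vs-differences plot with bias and limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(stats_.plot_data["means"], stats_.plot_data["diffs"], s=18)
    for yv, style in ((stats_.bias, "-"), (stats_.loa_low, "--"),
                      (stats_.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods (mL/cm$^3$)")
    ax.set_ylabel("difference (mL/cm$^3$)")
    if label:
        ax.set_title(label)
    return ax


def amari_index(P: np.ndarray) -> float:
    """Amari separation index of a gain matrix P = W_estimated @ A_true.

    0 for a perfect separation (P = permutation x diagonal), normalized to
    [0, 1] by 2 n (n - 1).
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * n * (n - 1)))
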