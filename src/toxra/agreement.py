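"""Agreement statistics between predicted and known toxicity values.

All metrics operate on log-transformed values: Ej is the log of the j-th
predicted LC50 and A the log of the matching known LC50 (base 10 by
toxicological convention, configurable).  With residuals r_j = Ej − A:

* bias         = mean(r)                         (systematic log offset)
* relative bias = (exp(bias) − 1) × 100%         (natural exponential)
* precision    = sample SD of r (divisor n − 1)  (spread about the bias)
* accuracy     = mean |r|                        (mean absolute error)

A Bland–Altman analysis reports the mean difference and 95% limits of
agreement mean ± 1.96 SD, plotting differences against per-point means.
Pearson's r between Ej and A summarises linear association.  An
Anderson–Darling normality check annotates whether log transformation
brought the values near normality; it never blocks computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .readacross import Prediction

_LOG_FNS = {10: np.log10, "10": np.log10, "e": np.log, math.e: np.log}


@dataclass(frozen=True)
class ResidualSet:
    """Paired log-transformed predicted (e) and known (a) values."""

    e: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "e", np.asarray(self.e, dtype=float))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        if self.e.shape != self.a.shape or self.e.ndim != 1:
            raise ValueError("e and a must be 1-d arrays of equal length")
        if self.n < 1:
            raise ValueError("a residual set needs at least one pair")

    @property
    def n(self) -> int:
        return int(self.e.size)

    @property
    def residuals(self) -> np.ndarray:
        return self.e - self.a

    @classmethod
    def from_predictions(
        cls, predictions: Sequence[Prediction], log_base: int | str = 10
    ) -> "ResidualSet":
        """Build from predictions that carry known values (others are skipped)."""
        fn = _LOG_FNS[log_base]
        pairs = [
            (p.predicted_lc50_ug_L, p.known_lc50_ug_L)
            for p in predictions
            if p.known_lc50_ug_L is not None
        ]
        if not pairs:
            raise ValueError("no predictions with known values")
        pred, known = zip(*pairs)
        return cls(e=fn(np.array(pred)), a=fn(np.array(known)))


def bias(rs: ResidualSet) -> float:
    """Mean residual (mean log overprediction)."""
    return float(np.mean(rs.residuals))


def relative_bias(bias_value: float) -> float:
    """Back-transform a log bias to a percent: (e^bias − 1) × 100."""
    return (math.exp(bias_value) - 1.0) * 100.0


def precision(rs: ResidualSet) -> float:
    """Sample standard deviation of the residuals about the bias."""
    if rs.n < 2:
        raise ValueError("precision requires at least two residuals")
    return float(np.std(rs.residuals, ddof=1))


def accuracy_mae(rs: ResidualSet) -> float:
    """Mean absolute residual (MAE); always ≥ |bias|."""
    return float(np.mean(np.abs(rs.residuals)))


@dataclass(frozen=True)
class BlandAltman:
    mean: float
    upper: float
    lower: float
    point_means: np.ndarray  # (Ej + A)/2, x-axis of the plot
    differences: np.ndarray  # Ej − A


def bland_altman(rs: ResidualSet) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD)."""
    if rs.n < 2:
        raise ValueError("Bland–Altman limits require at least two pairs")
    diffs = rs.residuals
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        mean=mean,
        upper=mean + 1.96 * sd,
        lower=mean - 1.96 * sd,
        point_means=(rs.e + rs.a) / 2.0,
        differences=diffs,
    )


def pearson_r(rs: ResidualSet) -> float:
    """Product-moment correlation between log predicted and log known."""
    if rs.n < 3:
        raise ValueError("Pearson's r requires at least three pairs")
    if np.std(rs.e) == 0 or np.std(rs.a) == 0:
        raise ValueError("Pearson's r is undefined for a zero-variance sequence")
    return float(stats.pearsonr(rs.e, rs.a).statistic)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float | None
    pvalue: float | None
    passed: bool | None  # None = inconclusive (n too small)


def normality_gate(values: Sequence[float], min_n: int = 8) -> NormalityResult:
    """Anderson–Darling normality check at the 5% level (annotation only)."""
    values = np.asarray(values, dtype=float)
    if values.size < min_n:
        return NormalityResult(statistic=None, pvalue=None, passed=None)
    try:
        res = stats.anderson(values, dist="norm", method="interpolate")
        pvalue = float(res.pvalue)
    except TypeError:  # scipy < 1.17: compare against the 5% critical value
        res = stats.anderson(values, dist="norm")
        idx = list(res.significance_level).index(5.0)
        pvalue = 0.5 if res.statistic < res.critical_values[idx] else 0.01
    return NormalityResult(
        statistic=float(res.statistic),
        pvalue=pvalue,
        passed=bool(pvalue > 0.05),
    )


@dataclass(frozen=True)
class AgreementSummary:
    """Per-group lack-of-agreement panel; None where n is too small."""

    group: str
    n: int
    bias: float
    relative_bias_pct: float
    accuracy_mae: float
    mean_offset: float  # |mean(E) − mean(A)|, equals |bias| by construction
    precision: float | None
    ba_mean: float | None
    ba_upper: float | None
    ba_lower: float | None
    pearson_r: float | None


def _summarise_one(group: str, rs: ResidualSet) -> AgreementSummary:
    b = bias(rs)
    prec = precision(rs) if rs.n >= 2 else None
    ba = bland_altman(rs) if rs.n >= 2 else None
    try:
        r = pearson_r(rs)
    except ValueError:
        r = None
    return AgreementSummary(
        group=group,
        n=rs.n,
        bias=b,
        relative_bias_pct=relative_bias(b),
        accuracy_mae=accuracy_mae(rs),
        mean_offset=abs(float(np.mean(rs.e)) - float(np.mean(rs.a))),
        precision=prec,
        ba_mean=ba.mean if ba else None,
        ba_upper=ba.upper if ba else None,
        ba_lower=ba.lower if ba else None,
        pearson_r=r,
    )


def summarize(
    predictions: Sequence[Prediction],
    grouping: str = "overall",
    log_base: int | str = 10,
) -> list[AgreementSummary]:
    """Lack-of-agreement summaries, overall or per functional group.

    Only predictions with known values contribute.  Grouping uses the
    pair's reporting label (the source chemical's functional group).
    """
    with_known = [p for p in predictions if p.known_lc50_ug_L is not None]
    if not with_known:
        raise ValueError("no predictions with known values to summarise")
    if grouping == "overall":
        groups = {"overall": with_known}
    elif grouping == "functional_group":
        groups = {}
        for p in with_known:
            groups.setdefault(p.pair.functional_group_label, []).append(p)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return [
        _summarise_one(name, ResidualSet.from_predictions(preds, log_base=log_base))
        for name, preds in sorted(groups.items())
    ]


def plot_scatter(rs: ResidualSet, path, title: str = "") -> None:
    """Scatter of log predicted vs log known with an OLS fit and 95% CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = stats.linregress(rs.a, rs.e)
    x = np.linspace(rs.a.min(), rs.a.max(), 100)
    y = fit.intercept + fit.slope * x
    # CI of the mean response from the t distribution
    n = rs.n
    resid = rs.e - (fit.intercept + fit.slope * rs.a)
    s = math.sqrt(float(np.sum(resid**2)) / max(n - 2, 1))
    xbar = float(np.mean(rs.a))
    sxx = float(np.sum((rs.a - xbar) ** 2))
    tcrit = stats.t.ppf(0.975, max(n - 2, 1))
    half = tcrit * s * np.sqrt(1.0 / n + (x - xbar) ** 2 / sxx) if sxx > 0 else 0 * x

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(rs.a, rs.e, s=12, alpha=0.6, edgecolor="none")
    ax.plot(x, y, color="C1")
    ax.fill_between(x, y - half, y + half, color="grey", alpha=0.3)
    ax.set_xlabel("log known LC50")
    ax.set_ylabel("log predicted LC50")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(ba: BlandAltman, path, title: str = "") -> None:
    """Standard Bland–Altman layout: differences vs means with dashed limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.point_means, ba.differences, s=12, alpha=0.6, edgecolor="none")
    for y, label in ((ba.mean, "mean"), (ba.upper, "+1.96 SD"), (ba.lower, "−1.96 SD")):
        ax.axhline(y, linestyle="--", color="grey")
        ax.annotate(f"{label} = {y:.2f}", xy=(1.0, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of log predicted and log known")
    ax.set_ylabel("difference (log predicted − log known)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
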