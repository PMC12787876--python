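"""Method-agreement battery for cadence estimates vs. ground truth.

Implements the validation statistics used to compare a cadence estimator
against video-based ground truth: RMSE/MAE (per treadmill speed and
pooled), Bland–Altman bias and 95% limits of agreement with outlier
counts, Pearson and Spearman correlation, two-way random-effects
absolute-agreement ICC (single and average measures, F-based 95% CIs),
Cronbach's alpha, and a Wilcoxon signed-rank comparison of per-trial
errors with effect sizes (r and Cohen's d in paired and pooled flavors).

ICC conventions
---------------
Subjects are trials; the two "raters" are the estimation method and the
video ground truth, crossed with subjects, hence the two-way random
model with absolute agreement — ICC(2,1) for a single measurement and
ICC(2,k) for the average of the raters.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "GroupAgreement",
    "AgreementReport",
    "error_metrics",
    "bland_altman",
    "correlations",
    "reliability",
    "paired_tests",
    "evaluate_methods",
]


@dataclasses.dataclass(frozen=True)
class PairedSeries:
    """Paired cadence series: one estimate and one truth value per trial.

    ``labels`` carries ``(participant, speed)`` per entry for grouped
    (per-speed) statistics.
    """

    estimate: np.ndarray
    truth: np.ndarray
    labels: tuple[tuple[object, object], ...] = ()

    def __post_init__(self) -> None:
        est = np.asarray(self.estimate, dtype=float)
        tru = np.asarray(self.truth, dtype=float)
        object.__setattr__(self, "estimate", est)
        object.__setattr__(self, "truth", tru)
        if est.shape != tru.shape or est.ndim != 1 or est.size < 2:
            raise ValueError("estimate and truth must be equal-length 1-D, n >= 2")
        if not (np.all(np.isfinite(est)) and np.all(np.isfinite(tru))):
            raise ValueError("all paired values must be finite")
        if np.any(est <= 0) or np.any(tru <= 0):
            raise ValueError("cadence values must be positive")
        if self.labels:
            if len(self.labels) != est.size:
                raise ValueError("labels must match series length")
            object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.estimate.size

    @property
    def diffs(self) -> np.ndarray:
        """Per-trial differences, estimate - truth."""
        return self.estimate - self.truth

    @property
    def speeds(self) -> tuple[object, ...]:
        return tuple(sorted({lab[1] for lab in self.labels})) if self.labels else ()

    def by_speed(self, speed: object) -> "PairedSeries":
        if not self.labels:
            raise ValueError("series has no labels to group by")
        idx = [i for i, lab in enumerate(self.labels) if lab[1] == speed]
        if not idx:
            raise ValueError(f"no entries at speed {speed!r}")
        return PairedSeries(
            estimate=self.estimate[idx],
            truth=self.truth[idx],
            labels=tuple(self.labels[i] for i in idx),
        )


def error_metrics(p: PairedSeries) -> tuple[float, float]:
    """(RMSE, MAE) of estimate vs truth in steps/min."""
    d = p.diffs
    return float(np.sqrt(np.mean(d**2))), float(np.mean(np.abs(d)))


@dataclasses.dataclass(frozen=True)
class GroupAgreement:
    """Error and Bland–Altman block for one group of trials."""

    n: int
    rmse: float
    mae: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outliers_above: int
    n_outliers_below: int


def bland_altman(p: PairedSeries) -> GroupAgreement:
    """Bland–Altman agreement: bias, SD of differences, 95% LoA, outliers.

    LoA = bias +/- 1.96 * SD (sample SD, n-1). Outliers are counted
    strictly outside the LoA interval. Zero-variance differences collapse
    the LoA to the bias with zero outliers.
    """
    d = p.diffs
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    rmse, mae = error_metrics(p)
    return GroupAgreement(
        n=len(p),
        rmse=rmse,
        mae=mae,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        n_outliers_above=int(np.sum(d > loa_high)),
        n_outliers_below=int(np.sum(d < loa_low)),
    )


def bland_altman_plot_data(p: PairedSeries) -> dict[str, np.ndarray | float]:
    """Mean-vs-difference pairs plus bias/LoA lines, ready for plotting."""
    g = bland_altman(p)
    return {
        "mean": (p.estimate + p.truth) / 2.0,
        "diff": p.diffs,
        "bias": g.bias,
        "loa_low": g.loa_low,
        "loa_high": g.loa_high,
    }


def correlations(p: PairedSeries) -> dict[str, float]:
    """Pearson r and Spearman rho with two-sided p-values."""
    if len(p) < 3:
        raise ValueError("need at least 3 pairs for correlation")
    if np.ptp(p.estimate) == 0 or np.ptp(p.truth) == 0:
        raise ValueError("zero variance: correlation undefined")
    pr = stats.pearsonr(p.estimate, p.truth)
    sr = stats.spearmanr(p.estimate, p.truth)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) mean squares: rows, columns, residual."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def _icc2_ci_single(
    icc: float, msr: float, msc: float, mse: float, n: int, k: int, alpha: float
) -> tuple[float, float]:
    """F-based CI for ICC(2,1), Shrout–Fleiss / McGraw–Wong construction."""
    denom = n * (1.0 - icc)
    if denom == 0:  # perfect agreement: degenerate interval
        return icc, icc
    a = k * icc / denom
    b = 1.0 + k * icc * (n - 1) / denom
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(lower), float(upper)


def _spearman_brown(icc_single: float, k: int) -> float:
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def reliability(p: PairedSeries, alpha: float = 0.05) -> dict[str, object]:
    """Two-way random absolute-agreement ICC and Cronbach's alpha.

    Returns ICC(2,1) and ICC(2,k) with F-based ``1 - alpha`` confidence
    intervals (average-measures bounds via the Spearman–Brown step-up of
    the single-measures bounds) plus Cronbach's alpha from the
    item-variance formula.
    """
    if len(p) < 5:
        raise ValueError("need at least 5 subjects for a stable ICC")
    data = np.column_stack([p.estimate, p.truth])
    n, k = data.shape
    msr, msc, mse = _anova_mean_squares(data)
    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    denom_avg = msr + (msc - mse) / n
    if denom_single <= 0 or denom_avg <= 0:
        raise ValueError("degenerate mean squares: ICC undefined")
    icc_single = (msr - mse) / denom_single
    icc_average = (msr - mse) / denom_avg
    lo1, hi1 = _icc2_ci_single(icc_single, msr, msc, mse, n, k, alpha)
    lo_k, hi_k = _spearman_brown(lo1, k), _spearman_brown(hi1, k)

    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance: alpha undefined")
    cronbach = k / (k - 1) * (1.0 - float(item_var.sum()) / float(total_var))

    return {
        "icc_single": float(icc_single),
        "icc_single_ci": (lo1, hi1),
        "icc_average": float(icc_average),
        "icc_average_ci": (lo_k, hi_k),
        "cronbach_alpha": float(cronbach),
    }


def paired_tests(
    errors_a: Sequence[float], errors_b: Sequence[float]
) -> dict[str, float]:
    """Wilcoxon signed-rank comparison of two paired error series.

    Zero differences are excluded (Wilcoxon convention); the statistic is
    the tie-corrected normal approximation Z, with effect size
    ``r = Z / sqrt(N)`` over the N retained pairs. Cohen's d is reported
    in both paired (mean diff / SD diff) and pooled-SD forms.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 6:
        raise ValueError("need equal-length error series with at least 6 pairs")
    d = a - b
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValueError("all differences are zero: no test possible")
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=False, method="approx"
    )
    z = float(res.zstatistic)
    n_used = int(nonzero.size)
    sd_d = float(np.std(d, ddof=1))
    pooled_sd = float(
        np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    )
    return {
        "wilcoxon_z": z,
        "wilcoxon_p": float(res.pvalue),
        "effect_r": z / np.sqrt(n_used),
        "n_used": n_used,
        "cohens_d_paired": float(np.mean(d)) / sd_d if sd_d > 0 else np.inf,
        "cohens_d_pooled": (float(np.mean(a)) - float(np.mean(b))) / pooled_sd
        if pooled_sd > 0
        else np.inf,
    }


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    """Full agreement report for one estimation method vs ground truth."""

    method: str
    pooled: GroupAgreement
    per_speed: dict[object, GroupAgreement]
    correlations: dict[str, float]
    reliability: dict[str, object]

    def to_rows(self) -> list[dict[str, object]]:
        """Flatten to tabular rows (one per group) for delimited output."""
        rows = []
        for name, g in [("pooled", self.pooled), *self.per_speed.items()]:
            rows.append({"method": self.method, "group": name, **dataclasses.asdict(g)})
        return rows


def _report(name: str, p: PairedSeries) -> AgreementReport:
    per_speed = {s: bland_altman(p.by_speed(s)) for s in p.speeds}
    return AgreementReport(
        method=name,
        pooled=bland_altman(p),
        per_speed=per_speed,
        correlations=correlations(p),
        reliability=reliability(p),
    )


def evaluate_methods(
    tables: Mapping[str, PairedSeries],
) -> tuple[dict[str, AgreementReport], dict[str, object]]:
    """Agreement reports per method plus a pairwise error comparison.

    All methods must cover the same labeled trials. The comparison block
    holds, for each method pair, the Wilcoxon test on per-trial absolute
    errors with effect sizes.
    """
    if not tables:
        raise ValueError("no methods supplied")
    names = list(tables)
    ref_labels = tables[names[0]].labels
    for name in names[1:]:
        if tables[name].labels != ref_labels:
            raise ValueError(f"method {name!r} labels differ from {names[0]!r}")
    reports = {name: _report(name, p) for name, p in tables.items()}
    comparison: dict[str, object] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            abs_a = np.abs(tables[na].diffs)
            abs_b = np.abs(tables[nb].diffs)
            try:
                comparison[f"{na}_vs_{nb}"] = paired_tests(abs_a, abs_b)
            except ValueError:
                # identical error series: nothing to test
                comparison[f"{na}_vs_{nb}"] = None
    return reports, comparison
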