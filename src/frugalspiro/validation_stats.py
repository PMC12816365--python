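"""Device-agreement statistics for paired spirometry measurements.

Implements the method-comparison battery used to validate a prototype
flow meter against a reference device: elementary error metrics (MAE,
MAPE, MSPE, RMSE, bias), Bland-Altman limits of agreement, a
normality-gated correlation (Shapiro-Wilk choosing between Pearson and
Spearman) and the intraclass correlation coefficient ICC(A-1) -- the
McGraw & Wong two-way, absolute-agreement, single-measurement model --
with F-distribution confidence intervals at several nested levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ErrorMetrics",
    "BlandAltmanResult",
    "CorrelationResult",
    "AgreementReport",
    "error_metrics",
    "bland_altman",
    "icc_a1",
    "correlation_gated",
    "agreement_report",
]

DEFAULT_CI_LEVELS = (80, 90, 95, 99)


class UndefinedICCError(ValueError):
    """Total variance is zero; the ICC is undefined."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-subject mean values from the device under test and a reference."""

    device: np.ndarray
    reference: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "device", np.asarray(self.device, dtype=float))
        object.__setattr__(self, "reference", np.asarray(self.reference, dtype=float))
        if self.device.shape != self.reference.shape or self.device.ndim != 1:
            raise ValueError("device and reference must be equal-length 1-D arrays")
        if np.any(~np.isfinite(self.device)) or np.any(~np.isfinite(self.reference)):
            raise ValueError("missing/non-finite values must be dropped upstream")

    @property
    def n(self) -> int:
        return self.device.size


@dataclass(frozen=True)
class ErrorMetrics:
    """Elementary paired error metrics, in the metric's own units.

    Signed quantities follow the device - reference convention, so a
    positive bias means the device over-reads.
    """

    mae: float
    mape_pct: float
    mspe_pct: float
    rmse: float
    bias: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of device - reference."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    normality_p_device: float
    normality_p_reference: float


@dataclass(frozen=True)
class AgreementReport:
    label: str
    errors: ErrorMetrics
    bland_altman: BlandAltmanResult
    correlation: CorrelationResult
    icc: float
    icc_ci: Dict[int, Tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.errors.n,
            "mae": self.errors.mae,
            "mape_pct": self.errors.mape_pct,
            "mspe_pct": self.errors.mspe_pct,
            "rmse": self.errors.rmse,
            "bias": self.errors.bias,
            "bland_altman": {
                "bias": self.bland_altman.bias,
                "loa_low": self.bland_altman.loa_low,
                "loa_high": self.bland_altman.loa_high,
            },
            "correlation": {
                "method": self.correlation.method,
                "coefficient": self.correlation.coefficient,
                "p_value": self.correlation.p_value,
            },
            "icc_a1": self.icc,
            "icc_ci": {str(k): list(v) for k, v in self.icc_ci.items()},
        }


def error_metrics(pairs: PairedMeasurements) -> ErrorMetrics:
    """MAE, MAPE, MSPE, RMSE and bias of device vs reference.

    Percentage errors use the reference value as denominator; a zero
    reference raises, naming the offending subject index.
    """
    if pairs.n < 1:
        raise ValueError("need at least one pair")
    zero = np.nonzero(pairs.reference == 0)[0]
    if zero.size:
        raise ValueError(
            f"reference value is zero at subject index {int(zero[0])}: "
            "percentage metrics undefined"
        )
    d = pairs.device - pairs.reference
    rel = d / pairs.reference
    return ErrorMetrics(
        mae=float(np.mean(np.abs(d))),
        mape_pct=float(np.mean(np.abs(rel)) * 100.0),
        mspe_pct=float(np.mean(rel) * 100.0),
        rmse=float(np.sqrt(np.mean(d**2))),
        bias=float(np.mean(d)),
        n=pairs.n,
    )


def bland_altman(pairs: PairedMeasurements, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and limits bias +/- 1.96 sd(diff).

    Uses the sample (n-1) standard deviation of the per-subject
    differences.  The per-subject means and differences are returned as
    the plot payload.
    """
    if pairs.n < 2:
        raise ValueError("Bland-Altman requires at least two pairs")
    diffs = pairs.device - pairs.reference
    means = (pairs.device + pairs.reference) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )


def _two_way_mean_squares(data: np.ndarray) -> Tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares of an n x k layout."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_a1(
    pairs: PairedMeasurements,
    ci_levels: Iterable[int] = DEFAULT_CI_LEVELS,
) -> Tuple[float, Dict[int, Tuple[float, float]]]:
    """ICC(A-1): two-way model, absolute agreement, single measurement.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) with k = 2
    raters (device, reference).  Confidence intervals use the
    F-distribution method with Satterthwaite degrees of freedom; the
    returned dict maps each confidence level (percent) to its
    ``(low, high)`` bounds, which nest by construction.
    """
    if pairs.n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    data = np.column_stack([pairs.device, pairs.reference])
    n, k = data.shape
    if np.ptp(data) == 0:
        raise UndefinedICCError("all measurements identical: zero total variance")
    msr, msc, mse = _two_way_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedICCError("zero denominator in ICC")
    icc = (msr - mse) / denom

    cis: Dict[int, Tuple[float, float]] = {}
    for level in sorted(set(int(round(c)) for c in ci_levels)):
        alpha = 1.0 - level / 100.0
        if icc >= 1.0:  # perfect agreement: degenerate interval
            cis[level] = (1.0, 1.0)
            continue
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = (n * (msr - f_l * mse)) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = (n * (f_u * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        cis[level] = (float(lower), float(upper))
    return float(icc), cis


def correlation_gated(
    pairs: PairedMeasurements, alpha: float = 0.05
) -> CorrelationResult:
    """Normality-gated correlation.

    Shapiro-Wilk is applied to each series; if either is non-normal at
    ``alpha`` the association is summarised by Spearman's rho, else by
    Pearson's r.
    """
    if pairs.n < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.ptp(pairs.device) == 0 or np.ptp(pairs.reference) == 0:
        raise ValueError("constant series: correlation undefined")
    p_dev = float(stats.shapiro(pairs.device).pvalue)
    p_ref = float(stats.shapiro(pairs.reference).pvalue)
    if p_dev < alpha or p_ref < alpha:
        res = stats.spearmanr(pairs.device, pairs.reference)
        method = "spearman"
    else:
        res = stats.pearsonr(pairs.device, pairs.reference)
        method = "pearson"
    return CorrelationResult(
        method=method,
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p_device=p_dev,
        normality_p_reference=p_ref,
    )


def agreement_report(
    pairs: PairedMeasurements,
    ci_levels: Iterable[int] = DEFAULT_CI_LEVELS,
    alpha: float = 0.05,
) -> AgreementReport:
    """Full agreement battery for one metric (e.g. FEV1 or PEF)."""
    icc, cis = icc_a1(pairs, ci_levels)
    return AgreementReport(
        label=pairs.label,
        errors=error_metrics(pairs),
        bland_altman=bland_altman(pairs),
        correlation=correlation_gated(pairs, alpha),
        icc=icc,
        icc_ci=cis,
    )
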