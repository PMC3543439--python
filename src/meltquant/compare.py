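"""Concordance analysis between two paired methylation measurements.

Implements the comparison used to validate melt-curve quantification
against a reference assay: Pearson correlation with a Fisher-z 95%
confidence interval and t-test p-value, plus Bland-Altman limits of
agreement — per sample the abscissa is the mean of the two measurements
and the ordinate their difference; the limits of agreement are
mean difference ± 1.96 × SD of the differences (sample SD, n−1
denominator).  Points beyond the limits are reported as outliers but
never removed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["ComparisonReport", "pearson_r", "bland_altman", "comparison_study"]

Z95 = 1.96


@dataclass
class ComparisonReport:
    """Pearson + Bland-Altman summary of two paired % vectors (y − x)."""

    n: int
    r: float
    r_ci: tuple[float, float]
    p_value: float
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]
    outliers: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n": self.n,
            "r": round(self.r, 4),
            "r_ci_low": round(self.r_ci[0], 4),
            "r_ci_high": round(self.r_ci[1], 4),
            "p_value": self.p_value,
            "mean_diff": round(self.mean_diff, 4),
            "sd_diff": round(self.sd_diff, 4),
            "loa_low": round(self.loa[0], 4),
            "loa_high": round(self.loa[1], 4),
            "n_outliers": len(self.outliers),
            "outliers": ";".join(self.outliers),
        }])


def pearson_r(x, y) -> tuple[float, tuple[float, float], float]:
    """Sample Pearson r with Fisher-z 95% CI and two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("undefined correlation: zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        ci = (r, r)
        p = 0.0
    else:
        if n > 3:  # Fisher z needs n-3 > 0; at n=3 the CI is vacuous
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n - 3)
            ci = (float(np.tanh(z - Z95 * se)), float(np.tanh(z + Z95 * se)))
        else:
            ci = (-1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, ci, p


def bland_altman(x, y, ids=None) -> ComparisonReport:
    """Limits-of-agreement analysis of paired measurements (difference y − x).

    Outliers are sample ids whose difference lies outside
    mean ± 1.96 × SD; with n < 2 the analysis is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValidationError("Bland-Altman needs n >= 2")
    ids = [str(i) for i in (ids if ids is not None else range(n))]
    if len(ids) != n:
        raise ValidationError("ids length must match the vectors")
    diff = y - x
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa = (mean_diff - Z95 * sd_diff, mean_diff + Z95 * sd_diff)
    outside = np.abs(diff - mean_diff) > Z95 * sd_diff
    try:
        r, ci, p = pearson_r(x, y)
    except ValidationError:
        r, ci, p = float("nan"), (float("nan"), float("nan")), float("nan")
    return ComparisonReport(
        n=n, r=r, r_ci=ci, p_value=p,
        mean_diff=mean_diff, sd_diff=sd_diff, loa=loa,
        outliers=[i for i, o in zip(ids, outside) if o],
    )


def comparison_study(hrm_results, reference: pd.DataFrame
                     ) -> tuple[ComparisonReport, pd.DataFrame]:
    """Join melt-based estimates with a reference table and compare.

    ``hrm_results`` is a list of :class:`~meltquant.quantify.QuantResult`
    or a frame with ``sample, pct_interp``; ``reference`` needs columns
    ``sample, pct_reference``.  Returns the report plus a per-sample paired
    table with mean/difference columns (the Bland-Altman plot data).
    """
    if isinstance(hrm_results, pd.DataFrame):
        hrm = hrm_results[["sample", "pct_interp"]].copy()
        het = hrm_results.get("heterogeneous")
        if het is not None:
            hrm["heterogeneous"] = het
    else:
        hrm = pd.DataFrame({
            "sample": [r.sample for r in hrm_results],
            "pct_interp": [r.pct_interp for r in hrm_results],
            "heterogeneous": [r.heterogeneous for r in hrm_results],
        })
    if "pct_reference" not in reference.columns:
        raise ValidationError("reference table needs a 'pct_reference' column")
    hrm["sample"] = hrm["sample"].astype(str)
    ref = reference[["sample", "pct_reference"]].copy()
    ref["sample"] = ref["sample"].astype(str)
    paired = hrm.merge(ref, on="sample", how="inner").sort_values("sample")
    if len(paired) < 3:
        raise ValidationError(
            f"only {len(paired)} shared sample ids between estimates and "
            "reference; need >=3"
        )
    x = paired["pct_reference"].to_numpy()
    y = paired["pct_interp"].to_numpy()
    report = bland_altman(x, y, ids=paired["sample"].tolist())
    paired = paired.assign(mean=(x + y) / 2.0, difference=y - x)
    return report, paired.reset_index(drop=True)


def bland_altman_plot(report: ComparisonReport, paired: pd.DataFrame, path) -> None:
    """Scatter of difference vs mean with the limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(paired["mean"], paired["difference"], s=18)
    ax.axhline(report.mean_diff, color="k", lw=1)
    for lim in report.loa:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of the two measurements (%)")
    ax.set_ylabel("difference, melt − reference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def paired_profile_plot(paired: pd.DataFrame, path) -> None:
    """Per-sample methylation profile from both techniques, side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    idx = np.arange(len(paired))
    ax.plot(idx, paired["pct_interp"], "o-", ms=3, label="melt estimate")
    ax.plot(idx, paired["pct_reference"], "s-", ms=3, label="reference")
    ax.set_xlabel("sample")
    ax.set_ylabel("methylation (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
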