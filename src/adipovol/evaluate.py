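"""Agreement statistics between two segmentations or volume sets.

Given a test segmentation A and a reference segmentation B, the module
computes:

* Jaccard difference 100·(1 − |A∩B|/|A∪B|), the volumetric overlap error
  (0 % = perfect overlap), pooled over all analysed slices of a subject;
* relative volume difference RVD = 100·(A − B)/B, signed;
* Spearman rank correlation of paired volumes;
* Bland–Altman analysis of paired volumes: bias (mean difference), 1.96·SD
  limits of agreement, 95 % confidence intervals, and a proportional-bias
  test (Spearman correlation of the differences against the pair means), in
  absolute or proportional (difference / pair mean) mode;
* grouped summary tables of mean (sd) Jaccard difference and RVD with
  Spearman rho (p) per cohort and depot.
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "jaccard_difference",
    "relative_volume_difference",
    "spearman_correlation",
    "BlandAltmanResult",
    "bland_altman",
    "agreement_summary",
    "bland_altman_plot",
]


def jaccard_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Volumetric overlap error in percent; 0 is perfect overlap.

    Computed over all voxels of all slices (a single pooled number per
    subject/depot). Symmetric in its arguments.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("undefined overlap")
    inter = np.logical_and(a, b).sum()
    return 100.0 * (1.0 - inter / union)


def relative_volume_difference(volume_a: float, volume_b: float) -> float:
    """Signed RVD in percent of the reference volume B."""
    if volume_b <= 0:
        raise ValueError("reference volume zero")
    return 100.0 * (volume_a - volume_b) / volume_b


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_correlation(
    x, y, method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``method='t'`` uses the t-approximation with n−2 degrees of freedom
    (appropriate from n ≈ 10 up); ``method='exact'`` enumerates all rank
    permutations (n ≤ 9 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation")
    if method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        if n > 9:
            raise ValueError("exact method limited to n <= 9")
        rx = _rank(x)
        ry = _rank(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        rho = float(np.mean(rx * ry))
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ry[perms] * rx).mean(axis=1)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    raise ValueError("method must be 't' or 'exact'")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, limits of agreement and proportional-bias test for one depot."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    prop_bias_rho: float
    prop_bias_p: float
    y_axis_mode: str
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(
    volume_a,
    volume_b,
    y_axis_mode: str = "absolute",
    difference_direction: str = "b_minus_a",
) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of paired volumes.

    Differences default to reference − test (B − A). In proportional mode
    each difference is divided by the pair mean. Limits of agreement are
    bias ± 1.96·sd(d); their 95 % CIs use the standard SE ≈ sd·√(3/n).
    Proportional bias is the Spearman correlation of differences against
    pair means.
    """
    a = np.asarray(volume_a, dtype=float)
    b = np.asarray(volume_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D volume sequences required")
    n = a.size
    if n < 3:
        raise ValueError("insufficient pairs")
    if y_axis_mode not in ("absolute", "proportional"):
        raise ValueError("y_axis_mode must be 'absolute' or 'proportional'")
    means = (a + b) / 2.0
    d = b - a if difference_direction == "b_minus_a" else a - b
    if y_axis_mode == "proportional":
        if np.any(means == 0):
            raise ValueError("zero pair mean in proportional mode")
        d = d / means

    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    t = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    if sd > 0:
        rho, p = spearman_correlation(means, d)
    else:
        rho, p = 0.0, 1.0
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_low=(loa_low - t * se_loa, loa_low + t * se_loa),
        ci_loa_high=(loa_high - t * se_loa, loa_high + t * se_loa),
        prop_bias_rho=rho,
        prop_bias_p=p,
        y_axis_mode=y_axis_mode,
        means=means,
        diffs=d,
    )


def agreement_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Cohort/depot summary of per-subject agreement statistics.

    ``per_subject`` needs columns ``subject, group, depot, jaccard_pct,
    rvd_pct, volume_a, volume_b``. Returns one row per (group, depot) with
    mean (sd) Jaccard difference, mean (sd) RVD and Spearman rho (p) of the
    paired volumes. Groups with fewer than 2 subjects are omitted with a
    warning. Pooled groups must be recomputed from subject-level rows, never
    averaged from group summaries.
    """
    required = {"subject", "group", "depot", "jaccard_pct", "rvd_pct", "volume_a", "volume_b"}
    missing = required - set(per_subject.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (group, depot), sub in per_subject.groupby(["group", "depot"], sort=False):
        if len(sub) < 2:
            warnings.warn(f"group {group!r} has <2 subjects; omitted", stacklevel=2)
            continue
        try:
            rho, p = spearman_correlation(sub["volume_a"], sub["volume_b"])
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append(
            {
                "group": group,
                "depot": depot,
                "n": len(sub),
                "jaccard_mean": sub["jaccard_pct"].mean(),
                "jaccard_sd": sub["jaccard_pct"].std(ddof=1),
                "rvd_mean": sub["rvd_pct"].mean(),
                "rvd_sd": sub["rvd_pct"].std(ddof=1),
                "spearman_rho": rho,
                "spearman_p": p,
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(result: BlandAltmanResult, path: str | os.PathLike) -> None:
    """Scatter of pair means vs differences with bias, LoA and shaded CIs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, color="tab:blue", zorder=3)
    span = (
        (result.means.min(), result.means.max())
        if result.means.size
        else (0.0, 1.0)
    )
    for value, ci, style in (
        (result.bias, result.ci_bias, "-"),
        (result.loa_low, result.ci_loa_low, "--"),
        (result.loa_high, result.ci_loa_high, "--"),
    ):
        ax.axhline(value, linestyle=style, color="black", linewidth=1)
        ax.axhspan(ci[0], ci[1], color="grey", alpha=0.2)
    ylabel = "difference" if result.y_axis_mode == "absolute" else "difference / mean"
    ax.set_xlabel("mean of methods (cm³)")
    ax.set_ylabel(ylabel)
    ax.set_title(
        f"bias={result.bias:.3g}, LoA=({result.loa_low:.3g}, {result.loa_high:.3g}), "
        f"prop. bias p={result.prop_bias_p:.3g}"
    )
    ax.set_xlim(span[0] - 0.05 * (span[1] - span[0] + 1e-9), span[1] + 0.05 * (span[1] - span[0] + 1e-9))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
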