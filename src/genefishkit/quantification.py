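"""Detection-efficiency and relative-gene-abundance statistics from FOV counts.

The counting unit is the microscope field of view (FOV).  The per-FOV
percentage is 100 * positive_cells / total_cells, where ``total_cells`` is
the DAPI count (efficiency mode) or the number of 16S-rRNA-probe-positive
cells (relative gene abundance, RGA, mode).  The experiment-level estimate
is the unweighted mean of the per-FOV percentages with its sample standard
deviation (n-1 denominator, the spreadsheet STDEV convention); a pooled
(cell-weighted) estimate is reported alongside for reference.

Two experiments are compared the classical way: a two-sample F-test on the
variances first, then a two-tailed pooled-variance t-test (with a Welch
fallback reported whenever the F-test rejects variance equality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "FOVCount",
    "EfficiencyResult",
    "ComparisonResult",
    "efficiency",
    "compare",
    "significance_stars",
    "nc_adjusted_mean",
    "read_fov_table",
]


@dataclass(frozen=True)
class FOVCount:
    """Cell counts for one field of view."""

    fov_id: str
    total_cells: int
    positive_cells: int

    def __post_init__(self) -> None:
        if self.total_cells < 1:
            raise ValidationError(f"FOV {self.fov_id!r}: total_cells must be >= 1")
        if not 0 <= self.positive_cells <= self.total_cells:
            raise ValidationError(
                f"FOV {self.fov_id!r}: positive_cells ({self.positive_cells}) must be "
                f"between 0 and total_cells ({self.total_cells})"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.positive_cells / self.total_cells


@dataclass(frozen=True)
class EfficiencyResult:
    """Mean +/- SD detection efficiency or RGA across fields of view."""

    mode: str
    percentages: tuple[float, ...]
    mean_percent: float
    sd_percent: float | None
    n_fovs: int
    n_cells_total: int
    pooled_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_percent <= 100.0:
            raise ValidationError(f"mean_percent out of range: {self.mean_percent}")


def efficiency(fovs: list[FOVCount], mode: str = "efficiency") -> EfficiencyResult:
    """Per-FOV percentages, their unweighted mean and sample SD.

    With a single FOV the SD is reported as not available (``None``).
    """
    if mode not in {"efficiency", "rga"}:
        raise InvalidParameterError(f"mode must be 'efficiency' or 'rga', got {mode!r}")
    if not fovs:
        raise InvalidParameterError("at least one FOV is required")
    pct = [f.percent for f in fovs]
    n = len(pct)
    mean = sum(pct) / n
    sd = math.sqrt(sum((p - mean) ** 2 for p in pct) / (n - 1)) if n > 1 else None
    total = sum(f.total_cells for f in fovs)
    pooled = 100.0 * sum(f.positive_cells for f in fovs) / total
    return EfficiencyResult(
        mode=mode,
        percentages=tuple(pct),
        mean_percent=mean,
        sd_percent=sd,
        n_fovs=n,
        n_cells_total=total,
        pooled_percent=pooled,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """F-test on variances plus two-tailed t-tests between two groups."""

    f_statistic: float
    f_p_value: float
    equal_variance_assumed: bool
    t_statistic: float
    t_p_value: float
    df: float
    welch_t_statistic: float
    welch_t_p_value: float


def compare(group_a, group_b, alpha_variance: float = 0.05) -> ComparisonResult:
    """Two-sample comparison of percentage groups.

    The variance-ratio F-test (two-tailed) runs first; the pooled-variance
    two-tailed t-test is always reported, with ``equal_variance_assumed``
    False (and the Welch result as the recommended alternative) when the
    F-test rejects at ``alpha_variance``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs at least 2 observations")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        f_stat, f_p = 1.0, 1.0
    elif var_b == 0.0:
        f_stat, f_p = math.inf, 0.0
    else:
        f_stat = var_a / var_b
        cdf = stats.f.cdf(f_stat, len(a) - 1, len(b) - 1)
        f_p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
    w_stat, w_p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        f_statistic=float(f_stat),
        f_p_value=float(f_p),
        equal_variance_assumed=bool(f_p > alpha_variance),
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        df=float(len(a) + len(b) - 2),
        welch_t_statistic=float(w_stat),
        welch_t_p_value=float(w_p),
    )


def significance_stars(p: float) -> str:
    """Figure-legend significance tiers: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def nc_adjusted_mean(result: EfficiencyResult, nc_result: EfficiencyResult) -> float:
    """Negative-control-adjusted mean: difference of the two group means.

    Reported only behind an explicit flag; headline values are never
    NC-subtracted.
    """
    return result.mean_percent - nc_result.mean_percent


def read_fov_table(path) -> dict[str, list[FOVCount]]:
    """Read a count TSV (experiment_id, fov_id, total_cells, positive_cells)."""
    df = pd.read_csv(path, sep="\t")
    required = {"experiment_id", "fov_id", "total_cells", "positive_cells"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[FOVCount]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.experiment_id), []).append(
            FOVCount(
                fov_id=str(r.fov_id),
                total_cells=int(r.total_cells),
                positive_cells=int(r.positive_cells),
            )
        )
    return out
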