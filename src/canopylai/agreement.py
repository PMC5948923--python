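"""Agreement metrics: trueness against known references and paired method
comparison.

Trueness is the closeness of replicate-mean estimates to reference values,
quantified by the coefficient of determination (squared Pearson correlation)
and the relative root mean squared error, RRMSE = 100·RMSE/mean(reference).

The method effect (e.g. "sky" vs "green" segmentation of the same images) is
assessed with the classical paired t-test on per-image differences, plus the
fraction of images whose absolute difference exceeds a practical cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TruenessResult", "PairedComparison", "trueness_metrics", "paired_t"]


@dataclass(frozen=True)
class TruenessResult:
    """R² and RRMSE of estimates against references."""

    r_squared: float
    rrmse: float  # percent
    n: int
    mean_reference: float

    def __post_init__(self) -> None:
        if self.rrmse < 0 or not 0 <= self.r_squared <= 1 or self.n < 2:
            raise ValueError("invalid trueness result")


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test between two estimate series on the same items."""

    mean_difference: float  # mean of a - b
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    fraction_abs_diff_gt: float
    cutoff: float
    n: int


def trueness_metrics(estimates, references) -> TruenessResult:
    """Trueness of ``estimates`` against known ``references``.

    R² is the squared Pearson correlation; RRMSE is the RMSE of the
    estimate−reference differences divided by the reference mean, in percent.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1 or est.size < 2:
        raise ValueError("need two equal-length series of at least 2 values")
    if np.ptp(ref) == 0:
        raise ValueError("references are all equal: R² undefined")
    mean_ref = float(ref.mean())
    if mean_ref <= 0:
        raise ValueError("mean reference must be > 0 for a relative error")
    if np.ptp(est) == 0:
        r2 = 0.0  # constant estimates carry no association
    else:
        r2 = float(np.corrcoef(est, ref)[0, 1] ** 2)
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    return TruenessResult(
        r_squared=r2, rrmse=100.0 * rmse / mean_ref, n=est.size, mean_reference=mean_ref
    )


def paired_t(a, b, cutoff: float = 0.5) -> PairedComparison:
    """Classical paired t-test on the per-item differences ``a - b``.

    Also reports the fraction of items with ``|a - b| > cutoff`` (default
    0.5, a practically relevant LAI discrepancy). Raises when the
    differences have zero spread ("no test possible").
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length series of at least 2 values")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ValueError("zero spread of differences: no test possible")
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(
        mean_difference=float(d.mean()),
        t_statistic=float(t),
        degrees_of_freedom=a.size - 1,
        p_value=float(p),
        fraction_abs_diff_gt=float(np.mean(np.abs(d) > cutoff)),
        cutoff=cutoff,
        n=a.size,
    )
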