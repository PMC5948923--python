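"""Interlaboratory precision statistics (ISO 5725 protocol).

Given a balanced p-laboratory × n-replicate matrix of estimates for one
entity, the analysis proceeds in three stages:

1. **Outlier screening.** Cochran's test on the within-laboratory variances
   (``C = S²_max / Σ S²_i``) and Grubbs' test on the laboratory means
   (``G = |suspect − x̄| / S``). A laboratory whose statistic exceeds the 1%
   critical value is an *outlier* and is excluded; above the 5% but not the
   1% value it is a *straggler* (flagged, retained). Cochran is applied
   first, then Grubbs on the remaining laboratories; each test once.

2. **Variance components.** One-way random-effects decomposition over the
   retained laboratories: repeatability variance ``S_r²`` is the pooled
   within-laboratory variance; the between-laboratory component is
   ``S_L² = max(0, S_d² − S_r²/n)`` with ``S_d²`` the variance of laboratory
   means; reproducibility variance ``S_R² = S_r² + S_L²``.

3. **Precision limits.** ``r = √2·t·S_r`` and ``R = √2·t·S_R`` with
   ``t = 1.959964`` (two-tailed 95% normal quantile, i.e. Student t with
   infinite degrees of freedom): the maximum absolute difference expected at
   the 95% level between two results under repeatability respectively
   reproducibility conditions. If rounding makes r exceed R, R is set equal
   to r. Relative forms ``RSD_r = 100·S_r/mean`` and ``RSD_R = 100·S_R/mean``
   are in percent.

The module exposes both the individual operations and a statsmodels-style
model: build :class:`InterlabPrecision` from estimate matrices or a long
DataFrame, call :meth:`~InterlabPrecision.fit`, and read per-entity results,
outlier reports and stratified aggregates off the returned
:class:`InterlabPrecisionResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from canopylai.synthetic import EstimateMatrix

__all__ = [
    "T_95_TWO_TAILED_INF",
    "LIMIT_FACTOR",
    "OutlierReport",
    "PrecisionResult",
    "Stratum",
    "StratumSummary",
    "cochran_statistic",
    "grubbs_statistic",
    "critical_values",
    "classify_laboratories",
    "variance_components",
    "precision_limits",
    "stratify_summaries",
    "InterlabPrecision",
    "InterlabPrecisionResults",
]

#: Two-tailed 95% Student-t critical value at infinite degrees of freedom.
T_95_TWO_TAILED_INF = 1.959964
#: Limit factor √2·t turning a standard deviation into a 95% two-result limit.
LIMIT_FACTOR = math.sqrt(2.0) * T_95_TWO_TAILED_INF

# Classical critical values of Cochran's C (balanced groups), indexed by
# (p groups, nu = n - 1 within-group df). Widely reprinted table used by the
# ISO 5725-2 screening stage.
_COCHRAN_TABLE = {
    0.05: {
        (2, 1): 0.9985, (2, 2): 0.9750, (2, 3): 0.9392, (2, 4): 0.9057, (2, 5): 0.8772,
        (3, 1): 0.9669, (3, 2): 0.8709, (3, 3): 0.7977, (3, 4): 0.7457, (3, 5): 0.7071,
        (4, 1): 0.9065, (4, 2): 0.7679, (4, 3): 0.6841, (4, 4): 0.6287, (4, 5): 0.5895,
        (5, 1): 0.8412, (5, 2): 0.6838, (5, 3): 0.5981, (5, 4): 0.5441, (5, 5): 0.5065,
        (6, 1): 0.7808, (6, 2): 0.6161, (6, 3): 0.5321, (6, 4): 0.4803, (6, 5): 0.4447,
    },
    0.01: {
        (2, 1): 0.9999, (2, 2): 0.9950, (2, 3): 0.9794, (2, 4): 0.9586, (2, 5): 0.9373,
        (3, 1): 0.9933, (3, 2): 0.9423, (3, 3): 0.8831, (3, 4): 0.8335, (3, 5): 0.7933,
        (4, 1): 0.9676, (4, 2): 0.8643, (4, 3): 0.7814, (4, 4): 0.7212, (4, 5): 0.6761,
        (5, 1): 0.9279, (5, 2): 0.7885, (5, 3): 0.6957, (5, 4): 0.6329, (5, 5): 0.5875,
        (6, 1): 0.8828, (6, 2): 0.7218, (6, 3): 0.6258, (6, 4): 0.5635, (6, 5): 0.5195,
    },
}

RETAINED = "retained"
STRAGGLER = "straggler"
OUTLIER = "outlier"


@dataclass(frozen=True)
class OutlierReport:
    """Outcome of the Cochran + Grubbs screening for one entity.

    Statistics are NaN when the corresponding test was not possible
    (degenerate data, or too few laboratories for Grubbs).
    """

    cochran_statistic: float
    cochran_suspect: str | None
    cochran_critical_5: float
    cochran_critical_1: float
    grubbs_statistic: float
    grubbs_suspect: str | None
    grubbs_critical_5: float
    grubbs_critical_1: float
    classification: dict[str, str]
    excluded_labs: tuple[str, ...]

    @property
    def stragglers(self) -> tuple[str, ...]:
        return tuple(l for l, c in self.classification.items() if c == STRAGGLER)


@dataclass(frozen=True)
class PrecisionResult:
    """Per-entity precision statistics after outlier screening."""

    entity_id: str
    mean_estimate: float
    S_r: float
    S_R: float
    r: float
    R: float
    RSD_r: float
    RSD_R: float
    labs_used: int
    canopy_class: str = ""

    def __post_init__(self) -> None:
        if self.S_r < 0 or self.S_R < self.S_r - 1e-12:
            raise ValueError("require 0 <= S_r <= S_R")
        if self.R < self.r - 1e-12:
            raise ValueError("require r <= R")


@dataclass(frozen=True)
class Stratum:
    """A stratum definition: a canopy class and/or an open LAI interval.

    Bounds are strict: an entity belongs if ``lai_gt < mean < lai_lt``
    (whichever bounds are set) and, when ``canopy_class`` is set, its class
    matches.
    """

    name: str
    canopy_class: str | None = None
    lai_gt: float | None = None
    lai_lt: float | None = None

    def contains(self, mean_estimate: float, canopy_class: str = "") -> bool:
        if self.canopy_class is not None and canopy_class != self.canopy_class:
            return False
        if self.lai_gt is not None and not mean_estimate > self.lai_gt:
            return False
        if self.lai_lt is not None and not mean_estimate < self.lai_lt:
            return False
        return True


@dataclass(frozen=True)
class StratumSummary:
    """Arithmetic means of precision limits over a stratum's entities.

    Relative summaries are per-entity ratios averaged:
    ``mean_relative_r = mean over entities of 100·r/mean_estimate``.
    """

    stratum: Stratum
    mean_r: float
    mean_R: float
    mean_relative_r: float
    mean_relative_R: float
    n_entities: int


# ---------------------------------------------------------------------------
# statistics


def cochran_statistic(variances) -> float:
    """Cochran's C: the largest within-laboratory variance over their sum."""
    v = np.asarray(variances, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 laboratories")
    if np.any(v < 0):
        raise ValueError("variances must be >= 0")
    total = v.sum()
    if total == 0:
        raise ValueError("all variances are zero: no test possible")
    return float(v.max() / total)


def grubbs_statistic(means) -> tuple[float, int]:
    """Single-Grubbs statistic over laboratory means.

    Both the largest and the smallest mean are tested against the grand mean;
    the larger standardized deviation wins (ties broken toward the maximum).
    Returns ``(G, index of the suspect laboratory)``. ``S`` is the sample
    standard deviation (n−1 denominator) of the laboratory means.
    """
    m = np.asarray(means, dtype=float)
    if m.size < 3:
        raise ValueError("Grubbs' test needs at least 3 laboratories")
    s = m.std(ddof=1)
    if s == 0:
        raise ValueError("zero spread of laboratory means: no test possible")
    xbar = m.mean()
    i_hi = int(np.argmax(m))
    i_lo = int(np.argmin(m))
    g_hi = (m[i_hi] - xbar) / s
    g_lo = (xbar - m[i_lo]) / s
    if g_hi >= g_lo:
        return float(g_hi), i_hi
    return float(g_lo), i_lo


def critical_values(test: str, alpha: float, p: int, nu: int | None = None) -> float:
    """Critical value of the Cochran or single-Grubbs outlier test.

    Cochran: the embedded classical table for small balanced designs, with
    the F-distribution formula ``C = [1 + (p−1)/F_{1−α/p}(ν, (p−1)ν)]⁻¹`` as
    fallback for designs outside the table. Grubbs: closed form through the
    Student-t quantile,
    ``G = ((p−1)/√p)·√(t² / (p−2+t²))`` with ``t = t_{1−α/(2p), p−2}``.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if test == "cochran":
        if p < 2:
            raise ValueError("Cochran's test needs p >= 2")
        if nu is None or nu < 1:
            raise ValueError("Cochran's test needs nu = replicates - 1 >= 1")
        table = _COCHRAN_TABLE.get(alpha)
        if table is not None and (p, nu) in table:
            return table[(p, nu)]
        f = stats.f.ppf(1.0 - alpha / p, nu, (p - 1) * nu)
        return float(1.0 / (1.0 + (p - 1) / f))
    if test == "grubbs":
        if p < 3:
            raise ValueError("Grubbs' test needs p >= 3")
        t = stats.t.ppf(1.0 - alpha / (2.0 * p), p - 2)
        return float((p - 1) / math.sqrt(p) * math.sqrt(t * t / (p - 2 + t * t)))
    raise ValueError("test must be 'cochran' or 'grubbs'")


def classify_laboratories(
    m: EstimateMatrix,
    alpha_straggler: float = 0.05,
    alpha_outlier: float = 0.01,
) -> OutlierReport:
    """Screen laboratories with Cochran's then Grubbs' test.

    Each test is applied once (no iterative re-testing). Cochran targets the
    laboratory with the largest replicate variance; Grubbs, applied to the
    laboratories Cochran retained, targets the most deviant laboratory mean.
    Statistic above the ``alpha_outlier`` critical value: outlier, excluded.
    Above ``alpha_straggler`` only: straggler, retained but flagged.
    Degenerate data (all variances zero, or all means equal) make the
    corresponding test "not possible": no laboratory is flagged by it.
    """
    labs = list(m.labs)
    values = m.values
    p, n = values.shape
    classification = {lab: RETAINED for lab in labs}

    # Cochran stage
    variances = values.var(axis=1, ddof=1)
    c_crit5 = critical_values("cochran", alpha_straggler, p, n - 1)
    c_crit1 = critical_values("cochran", alpha_outlier, p, n - 1)
    c_stat = math.nan
    c_suspect: str | None = None
    try:
        c_stat = cochran_statistic(variances)
        c_suspect = labs[int(np.argmax(variances))]
        if c_stat > c_crit1:
            classification[c_suspect] = OUTLIER
        elif c_stat > c_crit5:
            classification[c_suspect] = STRAGGLER
    except ValueError:
        pass

    # Grubbs stage on the laboratories Cochran retained
    keep = [i for i, lab in enumerate(labs) if classification[lab] != OUTLIER]
    g_stat = math.nan
    g_suspect: str | None = None
    g_crit5 = math.nan
    g_crit1 = math.nan
    if len(keep) >= 3:
        means = values[keep].mean(axis=1)
        g_crit5 = critical_values("grubbs", alpha_straggler, len(keep))
        g_crit1 = critical_values("grubbs", alpha_outlier, len(keep))
        try:
            g_stat, idx = grubbs_statistic(means)
            g_suspect = labs[keep[idx]]
            if g_stat > g_crit1:
                classification[g_suspect] = OUTLIER
            elif g_stat > g_crit5 and classification[g_suspect] == RETAINED:
                classification[g_suspect] = STRAGGLER
        except ValueError:
            pass

    excluded = tuple(lab for lab in labs if classification[lab] == OUTLIER)
    return OutlierReport(
        cochran_statistic=c_stat,
        cochran_suspect=c_suspect,
        cochran_critical_5=c_crit5,
        cochran_critical_1=c_crit1,
        grubbs_statistic=g_stat,
        grubbs_suspect=g_suspect,
        grubbs_critical_5=g_crit5,
        grubbs_critical_1=g_crit1,
        classification=classification,
        excluded_labs=excluded,
    )


def variance_components(
    m: EstimateMatrix, report: OutlierReport | None = None
) -> tuple[float, float, float]:
    """One-way variance components over the retained laboratories.

    Returns ``(S_r, S_R, mean_estimate)``: the repeatability standard
    deviation (pooled within-laboratory), the reproducibility standard
    deviation ``√(S_r² + S_L²)`` with the between-laboratory component
    ``S_L² = max(0, S_d² − S_r²/n)``, and the grand mean of retained values.
    """
    values = m.values
    if report is not None and report.excluded_labs:
        keep = [i for i, lab in enumerate(m.labs) if lab not in report.excluded_labs]
        values = values[keep]
    p, n = values.shape
    if p < 2:
        raise ValueError("need at least 2 retained laboratories")
    s2_within = values.var(axis=1, ddof=1)
    s_r2 = float(s2_within.mean())  # balanced: pooled = mean of per-lab variances
    lab_means = values.mean(axis=1)
    s_d2 = float(lab_means.var(ddof=1))
    s_l2 = max(0.0, s_d2 - s_r2 / n)
    s_r = math.sqrt(s_r2)
    s_R = math.sqrt(s_r2 + s_l2)
    return s_r, s_R, float(values.mean())


def precision_limits(
    S_r: float,
    S_R: float,
    mean_estimate: float,
    entity_id: str = "",
    canopy_class: str = "",
    labs_used: int = 0,
    limit_factor: float = LIMIT_FACTOR,
) -> PrecisionResult:
    """Turn variance components into 95% repeatability/reproducibility limits.

    ``r = limit_factor·S_r`` and ``R = limit_factor·S_R`` with the default
    factor ``√2·1.959964 ≈ 2.7718``; R is floored at r. Relative standard
    deviations are in percent of the mean estimate.
    """
    if S_r < 0 or S_R < 0:
        raise ValueError("standard deviations must be >= 0")
    if mean_estimate <= 0 and (S_r > 0 or S_R > 0):
        raise ValueError("mean_estimate must be > 0 for relative precision")
    r = limit_factor * S_r
    R = max(limit_factor * S_R, r)
    if mean_estimate > 0:
        rsd_r = 100.0 * S_r / mean_estimate
        rsd_R = 100.0 * S_R / mean_estimate
    else:
        rsd_r = rsd_R = 0.0
    return PrecisionResult(
        entity_id=entity_id,
        mean_estimate=mean_estimate,
        S_r=S_r,
        S_R=max(S_R, S_r),
        r=r,
        R=R,
        RSD_r=rsd_r,
        RSD_R=rsd_R,
        labs_used=labs_used,
        canopy_class=canopy_class,
    )


def stratify_summaries(
    results: list[PrecisionResult], strata: list[Stratum]
) -> list[StratumSummary]:
    """Aggregate per-entity precision limits over strata.

    Absolute summaries are arithmetic means of r and R; relative summaries
    average the per-entity ratios ``100·limit/mean_estimate``. Raises on an
    empty stratum.
    """
    out = []
    for st in strata:
        members = [
            res for res in results if st.contains(res.mean_estimate, res.canopy_class)
        ]
        if not members:
            raise ValueError(f"stratum {st.name!r} has no member entities")
        r = np.array([res.r for res in members])
        R = np.array([res.R for res in members])
        mu = np.array([res.mean_estimate for res in members])
        out.append(
            StratumSummary(
                stratum=st,
                mean_r=float(r.mean()),
                mean_R=float(R.mean()),
                mean_relative_r=float((100.0 * r / mu).mean()),
                mean_relative_R=float((100.0 * R / mu).mean()),
                n_entities=len(members),
            )
        )
    return out


# ---------------------------------------------------------------------------
# model / results


class InterlabPrecision:
    """Interlaboratory precision model over one or more entities.

    Parameters
    ----------
    matrices : list of EstimateMatrix
        One balanced laboratory × replicate matrix per entity.

    Use :meth:`from_dataframe` for long-format data
    (entity × laboratory × replicate × value).
    """

    def __init__(self, matrices: list[EstimateMatrix] | EstimateMatrix):
        if isinstance(matrices, EstimateMatrix):
            matrices = [matrices]
        if not matrices:
            raise ValueError("need at least one estimate matrix")
        self.matrices = list(matrices)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str = "lai",
        lab_col: str = "laboratory",
        replicate_col: str = "replicate",
        entity_col: str = "entity_id",
        class_col: str | None = "canopy_class",
    ) -> "InterlabPrecision":
        """Build the model from a long table of replicated estimates."""
        matrices = []
        for entity, grp in df.groupby(entity_col, sort=False):
            wide = grp.pivot(index=lab_col, columns=replicate_col, values=value_col)
            if wide.isna().any().any():
                raise ValueError(
                    f"entity {entity!r}: unbalanced design (missing cells)"
                )
            canopy_class = ""
            if class_col is not None and class_col in grp:
                canopy_class = str(grp[class_col].iloc[0])
            matrices.append(
                EstimateMatrix(
                    values=wide.to_numpy(dtype=float),
                    entity_id=str(entity),
                    canopy_class=canopy_class,
                    labs=tuple(str(l) for l in wide.index),
                )
            )
        return cls(matrices)

    def fit(
        self,
        alpha_straggler: float = 0.05,
        alpha_outlier: float = 0.01,
        limit_factor: float = LIMIT_FACTOR,
        screen_outliers: bool = True,
    ) -> "InterlabPrecisionResults":
        """Run screening, variance components and limits for every entity."""
        results: list[PrecisionResult] = []
        reports: dict[str, OutlierReport] = {}
        for m in self.matrices:
            report = None
            if screen_outliers and m.n_labs >= 2:
                report = classify_laboratories(m, alpha_straggler, alpha_outlier)
                reports[m.entity_id] = report
            s_r, s_R, mean = variance_components(m, report)
            labs_used = m.n_labs - (len(report.excluded_labs) if report else 0)
            results.append(
                precision_limits(
                    s_r,
                    s_R,
                    mean,
                    entity_id=m.entity_id,
                    canopy_class=m.canopy_class,
                    labs_used=labs_used,
                    limit_factor=limit_factor,
                )
            )
        return InterlabPrecisionResults(self, results, reports, limit_factor)


class InterlabPrecisionResults:
    """Fitted interlaboratory precision results.

    Attributes
    ----------
    results : list of PrecisionResult
    outlier_reports : dict entity_id -> OutlierReport
    """

    def __init__(self, model, results, outlier_reports, limit_factor):
        self.model = model
        self.results = results
        self.outlier_reports = outlier_reports
        self.limit_factor = limit_factor

    @property
    def table(self) -> pd.DataFrame:
        """Per-entity precision table (mean, r, RSDr, R, RSDR, labs used)."""
        return pd.DataFrame(
            {
                "entity_id": [x.entity_id for x in self.results],
                "canopy_class": [x.canopy_class for x in self.results],
                "mean_lai": [x.mean_estimate for x in self.results],
                "S_r": [x.S_r for x in self.results],
                "S_R": [x.S_R for x in self.results],
                "r": [x.r for x in self.results],
                "RSD_r": [x.RSD_r for x in self.results],
                "R": [x.R for x in self.results],
                "RSD_R": [x.RSD_R for x in self.results],
                "labs_used": [x.labs_used for x in self.results],
            }
        )

    def stratify(self, strata: list[Stratum]) -> list[StratumSummary]:
        """Aggregate limits over strata (see :func:`stratify_summaries`)."""
        return stratify_summaries(self.results, strata)

    def summary(self) -> str:
        """Human-readable report of per-entity limits and flagged labs."""
        lines = [
            "Interlaboratory precision (ISO 5725 protocol)",
            f"entities: {len(self.results)}    "
            f"limit factor: {self.limit_factor:.4f} (= sqrt(2) x t95,inf)",
            "",
            self.table.to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
        ]
        flagged = []
        for entity, rep in self.outlier_reports.items():
            for lab, cls in rep.classification.items():
                if cls != RETAINED:
                    flagged.append(f"  {entity}: laboratory {lab} -> {cls}")
        lines.append("")
        lines.append("flagged laboratories:" if flagged else "flagged laboratories: none")
        lines.extend(flagged)
        return "\n".join(lines)
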