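"""Growth rates, per-ring correlations, slab comparisons and grader agreement.

Lesion growth is summarized by the square-root-transformed yearly enlargement
rate

    yER = (sqrt(GA2) - sqrt(GA1)) / FU      [mm / year]

with GA1, GA2 the baseline and follow-up lesion areas in mm^2 and FU the
follow-up interval in years; the square-root transform removes the dependence
of raw area growth on baseline lesion size.

Association between perilesional FD% and yER is assessed per ring and per
slab with Spearman's rank correlation (average ranks for ties; exact
permutation p-value for n <= 9, t-approximation otherwise).  Paired slab
medians are compared with the two-sided Wilcoxon signed-rank test, and
two-grader agreement with the intraclass correlation ICC(2,1) — two-way
random effects, absolute agreement, single measures — with an F-based 95% CI.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateTestError
from .geometry import SlabSpec

__all__ = [
    "GrowthRecord",
    "RingCorrelation",
    "AgreementResult",
    "yearly_enlargement_rate",
    "spearman_corr",
    "per_ring_correlation",
    "paired_slab_test",
    "icc_two_grader",
    "cohort_summary",
]


@dataclass(frozen=True)
class GrowthRecord:
    """Baseline/follow-up lesion areas and the derived yearly enlargement rate."""

    ga1_mm2: float
    ga2_mm2: float
    fu_years: float
    yer_mm: float


def yearly_enlargement_rate(ga1_mm2: float, ga2_mm2: float, fu_years: float) -> GrowthRecord:
    """Square-root-transformed yearly enlargement rate.

    A shrinking lesion yields a negative rate; it is flagged with a warning
    but not clamped.
    """
    if fu_years <= 0:
        raise ValueError(f"follow-up interval must be positive, got {fu_years}")
    if ga1_mm2 < 0 or ga2_mm2 < 0:
        raise ValueError("lesion areas must be non-negative")
    yer = (math.sqrt(ga2_mm2) - math.sqrt(ga1_mm2)) / fu_years
    if yer < 0:
        warnings.warn(f"negative enlargement rate ({yer:.4f} mm/yr): lesion shrank")
    return GrowthRecord(ga1_mm2=ga1_mm2, ga2_mm2=ga2_mm2, fu_years=fu_years, yer_mm=yer)


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Pairs with a missing value in either vector are deleted.  For n <= 9 the
    p-value is computed by exhaustive permutation of one rank vector; for
    larger n the usual t-approximation is used.  A constant input vector has
    no defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("rank correlation undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom
    if n <= 9:
        perms = np.array(list(itertools.permutations(ryc)))
        rho_all = (perms @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


@dataclass(frozen=True)
class RingCorrelation:
    """Per-ring, per-slab Spearman correlation between FD% and yER."""

    slab: str | SlabSpec
    ring_index: int
    rho: float
    p_value: float
    n: int


def per_ring_correlation(
    fd: pd.DataFrame,
    yer: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[RingCorrelation]:
    """Correlate FD% with yER for every (slab, ring) cell of a cohort table.

    Parameters
    ----------
    fd
        Long table with columns ``eye``, ``slab``, ``ring``, ``fd_pct``;
        missing FD% (NaN) values are deleted pairwise per ring.
    yer
        Mapping from eye identifier to yearly enlargement rate.
    alpha
        Significance level carried in downstream reports; rows are never
        deleted on it.
    fdr
        If true, replace p-values by Benjamini-Hochberg adjusted values
        across all (slab, ring) cells (off by default: per-ring reporting at
        alpha matches standard practice for this analysis).

    Rings with fewer than 3 complete eyes are recorded with NaN rho/p rather
    than dropped silently.  A cohort with fewer than 3 eyes raises.
    """
    yer = pd.Series(yer)
    if fd["eye"].nunique() < 3:
        raise ValueError("per-ring correlation requires at least 3 eyes")
    out: list[RingCorrelation] = []
    for (slab, ring), grp in fd.groupby(["slab", "ring"], sort=True):
        vals = grp.set_index("eye")["fd_pct"]
        joined = pd.concat([vals, yer.rename("yer")], axis=1, join="inner").dropna()
        n = len(joined)
        if n < 3:
            out.append(RingCorrelation(slab, int(ring), float("nan"), float("nan"), n))
            continue
        try:
            rho, p = spearman_corr(joined["fd_pct"].values, joined["yer"].values)
        except DegenerateTestError:
            rho, p = float("nan"), float("nan")
        out.append(RingCorrelation(slab, int(ring), rho, p, n))
    if fdr:
        ps = np.array([rc.p_value for rc in out])
        ok = np.isfinite(ps)
        adj = ps.copy()
        adj[ok] = sps.false_discovery_control(ps[ok], method="bh")
        out = [
            RingCorrelation(rc.slab, rc.ring_index, rc.rho, float(q), rc.n)
            for rc, q in zip(out, adj)
        ]
    return out


def paired_slab_test(fd_slab_a: Sequence[float], fd_slab_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-eye FD% vectors."""
    a = np.asarray(fd_slab_a, dtype=float)
    b = np.asarray(fd_slab_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if a.size < 6:
        raise ValueError(f"need at least 6 pairs, got {a.size}")
    if np.all(a == b):
        raise DegenerateTestError("all paired differences are zero; test undefined")
    return float(sps.wilcoxon(a, b, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class AgreementResult:
    """Intraclass correlation with its 95% confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way random, absolute agreement, single measures (ICC2,1)"


def icc_two_grader(g1: Sequence[float], g2: Sequence[float]) -> AgreementResult:
    """ICC(2,1) absolute agreement between two graders' paired measurements."""
    import pingouin as pg  # deferred: pingouin import is heavy

    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("grader vectors must be 1-D and of equal length")
    n = a.size
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if np.ptp((a + b) / 2.0) == 0:
        raise DegenerateTestError("zero between-subject variance; ICC undefined")
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "grader": np.repeat(["g1", "g2"], n),
            "score": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="subject", raters="grader", ratings="score"
        )
    table = table.set_index("Type")
    # absolute-agreement single-measures row; label varies across versions
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = row[ci_col]
    icc = float(row["ICC"])
    # guard the CI invariant against rounding in the reported bounds
    return AgreementResult(icc=icc, ci_low=min(float(lo), icc), ci_high=max(float(hi), icc))


def _median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def cohort_summary(metrics: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Median and IQR (linear-interpolated quartiles) per named metric.

    Returns a frame indexed by metric name with columns ``median``, ``q1``,
    ``q3`` and ``n``.
    """
    if not metrics:
        raise ValueError("no metrics to summarize")
    rows = {}
    for name, vals in metrics.items():
        med, q1, q3 = _median_iqr(vals)
        rows[name] = {"median": med, "q1": q1, "q3": q3, "n": len(list(vals))}
    return pd.DataFrame.from_dict(rows, orient="index")[["median", "q1", "q3", "n"]]
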