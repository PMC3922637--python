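"""Observer-agreement statistics for multi-rater extent panels.

Covers the statistical layer used to compare readers and programs quantifying
ischemic extent: descriptive column summaries, the intraclass correlation
ICC(2,1) from a two-way random-effects (patients x observers) ANOVA
decomposition with a Shrout-Fleiss F-based 95% CI, the between-observer
standard deviation (square root of the observer variance component),
Bland-Altman limits of agreement, the Wilcoxon signed-rank test (exact by
enumeration, or normal approximation), and fixed-effect method contrasts for
balanced complete designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RaterPanel:
    """Complete patients x observers matrix of extent values (percent LV)."""

    values: np.ndarray
    patient_ids: tuple = ()
    observer_ids: tuple = ()
    n_clipped: int = 0  # cells clipped into [0, 100] by a simulator

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(
                f"panel needs >= 2 patients and >= 2 observers, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("panel has missing or non-finite cells; complete designs only")
        object.__setattr__(self, "values", v)
        if not self.patient_ids:
            object.__setattr__(
                self, "patient_ids", tuple(f"P{i+1}" for i in range(v.shape[0]))
            )
        if not self.observer_ids:
            object.__setattr__(
                self, "observer_ids", tuple(f"O{j+1}" for j in range(v.shape[1]))
            )

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_observers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.observer_ids)
        )


@dataclass(frozen=True)
class ColumnSummary:
    mean: float
    sd: float
    median: float
    min: float
    max: float
    n: int
    degenerate: bool = False  # single observation: SD reported as 0 and flagged


def column_summary(values) -> ColumnSummary:
    """Mean, sample SD (n-1), median, min, max of one column of values.

    A single observation is a degenerate case: the sample SD is undefined and
    is reported as 0.0 with ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("column_summary requires at least one value")
    degenerate = v.size == 1
    sd = 0.0 if degenerate else float(np.std(v, ddof=1))
    return ColumnSummary(
        mean=float(np.mean(v)),
        sd=sd,
        median=float(np.median(v)),
        min=float(np.min(v)),
        max=float(np.max(v)),
        n=int(v.size),
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# ICC(2,1): two-way random effects, absolute agreement, single rater
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    var_patient: float
    var_observer: float
    var_error: float
    ms_patient: float = 0.0
    ms_observer: float = 0.0
    ms_error: float = 0.0
    degenerate: bool = False


def _two_way_mean_squares(v: np.ndarray) -> tuple[float, float, float]:
    """ANOVA mean squares for a complete two-way layout, one obs per cell."""
    n, k = v.shape
    gm = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - gm) ** 2))
    ss_cols = n * float(np.sum((col_means - gm) ** 2))
    ss_total = float(np.sum((v - gm) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_random(panel: RaterPanel, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with variance components and an F-based 95% CI.

    The two-way random-effects model ``value_ij = mu + p_i + o_j + e_ij``
    (patients and observers both random) is estimated by ANOVA method of
    moments:

        sigma2_e = MSE,  sigma2_p = (MSR - MSE)/k,  sigma2_o = (MSC - MSE)/n

    with negative component estimates truncated to zero before forming

        ICC = sigma2_p / (sigma2_p + sigma2_o + sigma2_e).

    The confidence interval is the Shrout-Fleiss interval for ICC(2,1),
    based on an F approximation with Satterthwaite degrees of freedom.
    A constant panel (zero total variance) is returned as ICC 1 with a
    degenerate [1, 1] interval and flagged.
    """
    v = panel.values
    n, k = v.shape
    if np.allclose(v, v.flat[0]):
        return ICCResult(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, degenerate=True)

    msr, msc, mse = _two_way_mean_squares(v)
    var_e = mse
    var_p = max((msr - mse) / k, 0.0)
    var_o = max((msc - mse) / n, 0.0)
    total = var_p + var_o + var_e
    icc = var_p / total if total > 0 else 1.0

    # Shrout & Fleiss F-based CI for ICC(2,1)
    if mse <= 0:
        # no residual variance: interval collapses onto the point estimate
        return ICCResult(icc, icc, icc, var_p, var_o, var_e, msr, msc, mse,
                         degenerate=True)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v_df = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v_df)
        f_u = stats.f.ppf(1 - alpha / 2, v_df, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        lo = float(np.clip(lo, 0.0, 1.0))
        hi = float(np.clip(hi, 0.0, 1.0))
        lo, hi = min(lo, icc), max(hi, icc)
    else:
        lo, hi = icc, icc
    return ICCResult(icc, lo, hi, var_p, var_o, var_e, msr, msc, mse)


def between_observer_sd(panel: RaterPanel) -> float:
    """SD between observers: sqrt of the observer variance component.

    Uses the same two-way ANOVA decomposition as :func:`icc_two_way_random`
    (population definition over observer offsets; a panel with observer
    offsets (-5, 0, +5) and no residual error yields exactly 5.0).
    """
    return float(np.sqrt(icc_two_way_random(panel).var_observer))


def observer_mean_sd(panel: RaterPanel) -> float:
    """Alternative reading of 'SD between observers': sample SD of the
    per-observer mean values (exposed alongside the component-based one)."""
    return float(np.std(panel.values.mean(axis=0), ddof=1))


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)
    max_diff_boundary: np.ndarray = field(repr=False, default=None)


def bland_altman(reference, test) -> BlandAltmanResult:
    """Bland-Altman agreement of ``test`` against ``reference``.

    Differences are ``test - reference``; the limits of agreement are
    ``bias +/- 1.96 * SD`` (sample SD of the differences).  Because extents
    live in [0, 100], the difference at a given mean m cannot fall below
    ``max(-2m, 2m - 200)`` (test at 0 or reference at 100); that per-point
    diagonal bound is returned as ``max_diff_boundary``.
    """
    x = np.asarray(reference, dtype=float).ravel()
    y = np.asarray(test, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: reference {x.size} vs test {y.size}")
    if x.size < 2:
        raise ValueError("bland_altman requires at least 2 paired values")
    d = y - x
    m = (x + y) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    boundary = np.maximum(-2.0 * m, 2.0 * m - 200.0)
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=m,
        diffs=d,
        max_diff_boundary=boundary,
    )


# --------------------------------------------------------------------------
# Wilcoxon signed-rank (exact enumeration / normal approximation)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    mode: str  # "exact" | "approx" | "no-test"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all sign assignments of the ranks.

    Implemented as a dynamic program over the distribution of W+ (ranks are
    doubled so midranks become integers), equivalent to summing over the 2^n
    sign patterns.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    # dist[s] = number of sign patterns with doubled W+ == s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x, y, mode: str = "auto") -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive midranks.
    ``mode``: "exact" enumerates the null distribution of W+ (all sign
    assignments), "approx" uses the normal approximation with tie correction
    and a 0.5 continuity correction, "auto" picks exact when the number of
    nonzero differences is <= 20.  If every difference is zero there is
    nothing to test and p = 1 is returned flagged as "no-test".
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("wilcoxon_signed_rank requires equal-length paired samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0, mode="no-test")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= 20 else "approx"
    if mode == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
    elif mode == "approx":
        mean_w = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = float(np.sum(counts**3 - counts)) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        if var_w <= 0:
            p = 1.0
        else:
            z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / np.sqrt(var_w)
            p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"mode must be 'exact', 'approx' or 'auto', got {mode!r}")
    return WilcoxonResult(statistic=w_plus, p_value=min(p, 1.0), n_nonzero=n, mode=mode)


# --------------------------------------------------------------------------
# Fixed-effect method contrasts (balanced complete designs)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MethodContrast:
    method_a: str
    method_b: str
    mean_difference: float  # mean(A) - mean(B) across patients
    p_value: float
    n: int


def method_contrast(records: pd.DataFrame) -> list[MethodContrast]:
    """Pairwise mean differences between methods in a balanced design.

    ``records`` is long format with columns ``patient``, ``method``,
    ``value``: every method measured once on every patient.  In that balanced
    complete layout the mixed-model fixed-effect contrast between two methods
    (patients random) reduces algebraically to the paired mean difference
    across patients; the p-value is the paired t-test.  Unbalanced or
    incomplete input raises rather than being silently approximated.
    """
    required = {"patient", "method", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    wide = records.pivot_table(
        index="patient", columns="method", values="value", aggfunc="count"
    )
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError(
            "unsupported design: every method must be observed exactly once "
            "per patient (balanced complete design required)"
        )
    pivot = records.pivot(index="patient", columns="method", values="value")
    methods = list(pivot.columns)
    out: list[MethodContrast] = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            da = pivot[a].to_numpy()
            db = pivot[b].to_numpy()
            diff = float(np.mean(da - db))
            if np.allclose(da, db):
                p = 1.0
            else:
                p = float(stats.ttest_rel(da, db).pvalue)
            out.append(MethodContrast(a, b, diff, p, len(da)))
    return out
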