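"""Comparison and correlation machinery with explicit design records.

Every comparison returns a :class:`TestResult` that records which test ran,
its sidedness, pairing, and any multiple-comparison correction, so analysis
outputs are self-describing.  Test selection can be automated (normality
screening with the Anderson-Darling test routes to t-type tests when all
samples look normal, rank-type otherwise) or pinned per analysis.

Wilcoxon procedures use exact null distributions for n <= 25 and the
normal approximation with continuity correction above, so small-cohort
p-values are deterministic and enumeration-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

EXACT_WILCOXON_MAX_N = 25


class InsufficientDataError(ValueError):
    """Raised when a sample is too small for the requested procedure."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test, with its full design record."""

    test_name: str  # paired-t | unpaired-t | one-sample-t | wilcoxon-signed-rank | wilcoxon-rank-sum | anova-tukey
    sidedness: str  # "one" | "two"
    statistic: float
    p: float
    n: int
    p_adjusted: float | None = None
    correction: str = "none"  # none | bonferroni | tukey-kramer
    detail: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p-value below raw p-value")


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation, optionally aggregated across animals (mean +- SEM)."""

    method: str  # "pearson-R2-linfit" | "spearman"
    value: float
    n: int
    undefined: bool = False
    per_animal_values: tuple[float, ...] = field(default_factory=tuple)
    sem: float | None = None


def is_normal(x: Sequence[float], level: float = 0.05) -> bool:
    """Anderson-Darling normality screen at the given significance level."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4 or np.ptp(x) == 0:
        return False
    try:
        res = sps.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue > level)
    except TypeError:  # older scipy: compare against tabulated critical values
        res = sps.anderson(x, dist="norm")
        levels = np.asarray(res.significance_level, dtype=float) / 100.0
        idx = int(np.argmin(np.abs(levels - level)))
        return bool(res.statistic < res.critical_values[idx])


def _alternative(sidedness: str, direction: str) -> str:
    if sidedness == "two":
        return "two-sided"
    if direction not in ("greater", "less"):
        raise ValueError("one-sided tests need direction 'greater' or 'less'")
    return direction


def _wilcoxon_signed_rank(d: np.ndarray, alternative: str) -> tuple[float, float]:
    d = d[d != 0]
    if len(d) == 0:  # all differences zero: maximally null
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= EXACT_WILCOXON_MAX_N and not has_ties) else "approx"
    res = sps.wilcoxon(
        d,
        alternative=alternative,
        method=method,
        correction=(method == "approx"),
    )
    return float(res.statistic), float(res.pvalue)


def compare(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    *,
    paired: bool = False,
    sidedness: str = "two",
    direction: str = "greater",
    test: str = "auto",
    popmean: float = 0.0,
) -> TestResult:
    """Compare one or two samples, returning a full design record.

    Parameters
    ----------
    a, b:
        Samples.  ``b=None`` runs a one-sample test of ``a`` against
        ``popmean``.  Paired designs require matching lengths.
    sidedness, direction:
        ``"two"``-sided, or ``"one"``-sided in the hypothesized
        ``direction`` (``"greater"``: a > b, or a > popmean).
    test:
        ``"auto"`` routes on Anderson-Darling normality (t-type when all
        samples screen normal, rank-type otherwise), or pin one of
        ``paired-t``, ``unpaired-t``, ``one-sample-t``,
        ``wilcoxon-signed-rank``, ``wilcoxon-rank-sum``.
    """
    a = np.asarray(a, dtype=float)
    if len(a) < 2:
        raise InsufficientDataError(f"need n >= 2, got n = {len(a)}")
    if b is not None:
        b = np.asarray(b, dtype=float)
        if paired and len(a) != len(b):
            raise InsufficientDataError("paired samples must have matching lengths")
        if len(b) < 2:
            raise InsufficientDataError(f"need n >= 2, got n = {len(b)}")

    one_sample = b is None
    alt = _alternative(sidedness, direction)

    if test == "auto":
        if one_sample:
            normal = is_normal(a)
            test = "one-sample-t" if normal else "wilcoxon-signed-rank"
        elif paired:
            normal = is_normal(a - b)
            test = "paired-t" if normal else "wilcoxon-signed-rank"
        else:
            normal = is_normal(a) and is_normal(b)
            test = "unpaired-t" if normal else "wilcoxon-rank-sum"

    if test == "one-sample-t":
        res = sps.ttest_1samp(a, popmean, alternative=alt)
        stat, p, n = res.statistic, res.pvalue, len(a)
    elif test == "paired-t":
        res = sps.ttest_rel(a, b, alternative=alt)
        stat, p, n = res.statistic, res.pvalue, len(a)
    elif test == "unpaired-t":
        res = sps.ttest_ind(a, b, alternative=alt)
        stat, p, n = res.statistic, res.pvalue, len(a) + len(b)
    elif test == "wilcoxon-signed-rank":
        d = (a - popmean) if one_sample else (a - b)
        stat, p = _wilcoxon_signed_rank(d, alt)
        n = len(a)
    elif test == "wilcoxon-rank-sum":
        if one_sample or paired:
            raise ValueError("rank-sum test needs two independent samples")
        use_exact = (
            max(len(a), len(b)) <= EXACT_WILCOXON_MAX_N
            and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        )
        res = sps.mannwhitneyu(
            a, b, alternative=alt, method="exact" if use_exact else "asymptotic"
        )
        stat, p, n = res.statistic, res.pvalue, len(a) + len(b)
    else:
        raise ValueError(f"unknown test: {test!r}")

    if np.isnan(p):  # degenerate (e.g. zero-variance t): treat as maximally null
        stat, p = 0.0, 1.0
    return TestResult(
        test_name=test,
        sidedness=sidedness,
        statistic=float(stat),
        p=float(min(p, 1.0)),
        n=int(n),
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> CorrelationResult:
    """Correlate paired values; NaN pairs are dropped.

    ``pearson-R2-linfit`` reports the squared Pearson r of a linear
    regression fit; ``spearman`` reports the rank correlation.  Constant
    input yields an undefined (NaN) result with the flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"need n >= 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method=method, value=float("nan"), n=len(x), undefined=True)
    if method == "pearson-R2-linfit":
        res = sps.linregress(x, y)
        value = float(res.rvalue**2)
    elif method == "spearman":
        value = float(sps.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return CorrelationResult(method=method, value=value, n=len(x))


def correlate_by_animal(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    method: str = "spearman",
) -> CorrelationResult:
    """Per-animal correlations aggregated as mean +- SEM across animals."""
    values = [correlate(x, y, method).value for x, y in pairs]
    arr = np.asarray(values, dtype=float)
    defined = arr[np.isfinite(arr)]
    if len(defined) == 0:
        return CorrelationResult(
            method=method, value=float("nan"), n=0, undefined=True,
            per_animal_values=tuple(values),
        )
    sem = float(sps.sem(defined)) if len(defined) > 1 else None
    return CorrelationResult(
        method=method,
        value=float(defined.mean()),
        n=len(defined),
        per_animal_values=tuple(values),
        sem=sem,
    )


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m); m defaults to len(pvals)."""
    pvals = list(pvals)
    if m is None:
        m = len(pvals)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    out = []
    for p in pvals:
        if not (0.0 <= p <= 1.0 or np.isnan(p)):
            raise ValueError(f"p-value out of range: {p}")
        out.append(float(min(1.0, p * m)) if np.isfinite(p) else float("nan"))
    return out


def anova_tukey(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None):
    """One-way ANOVA with Tukey-Kramer corrected pairwise comparisons.

    Returns ``(omnibus, pairwise)``: the omnibus F as a TestResult, and a
    DataFrame of all pairwise comparisons with Tukey-Kramer adjusted
    p-values.
    """
    import pandas as pd

    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    for lab, g in zip(labels, arrays):
        if len(g) < 2:
            raise InsufficientDataError(f"group {lab!r} has n < 2")

    f_res = sps.f_oneway(*arrays)
    n_total = sum(len(g) for g in arrays)
    omnibus = TestResult(
        test_name="anova-tukey",
        sidedness="two",
        statistic=float(f_res.statistic),
        p=float(f_res.pvalue),
        n=n_total,
    )

    values = np.concatenate(arrays)
    group_labels = np.concatenate([[lab] * len(g) for lab, g in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, group_labels, alpha=0.05)
    pairwise = pd.DataFrame(
        data=tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    pairwise = pairwise.rename(columns={"p-adj": "p_adjusted"})
    pairwise["p_adjusted"] = pairwise["p_adjusted"].astype(float)
    pairwise["correction"] = "tukey-kramer"
    return omnibus, pairwise
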