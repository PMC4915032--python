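"""Normality-gated two-group comparisons, KS against a reference, ECDFs.

The comparison workflow mirrors the published analysis: samples are
screened with the D'Agostino & Pearson omnibus normality test; if both
groups pass, an unpaired two-sided Student's t-test is used, otherwise
a two-sided Mann-Whitney test. Distributions are compared with the
two-sample Kolmogorov-Smirnov test, with the control group as
reference. All tests are two-sided; the t-test defaults to the classic
equal-variance form with Welch available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "TestResult",
    "NormalityResult",
    "Ecdf",
    "DegenerateSampleError",
    "normality_gate",
    "compare_two_groups",
    "ks_two_sample",
    "ecdf",
    "wilcoxon_matched_pairs",
]


class DegenerateSampleError(ValueError):
    """Sample admits no test (constant, empty, too small)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group test, including the gate decision path."""

    test_name: str                      # students_t | welch_t | mann_whitney |
    statistic: float                    # ks_two_sample | wilcoxon
    p_value: float
    n1: int
    n2: int
    normality_p1: float | None = None
    normality_p2: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class NormalityResult:
    p_value: float | None
    passes: bool
    applicable: bool                    # False when n < 8


@dataclass(frozen=True)
class Ecdf:
    """Right-continuous empirical CDF: F(x) = #{xi <= x} / n."""

    values: np.ndarray                  # sorted unique sample values
    fractions: np.ndarray               # nondecreasing, ends at 1

    def __call__(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.values, np.asarray(x), side="right")
        frac = np.concatenate([[0.0], self.fractions])
        out = frac[idx]
        return float(out) if np.isscalar(x) else out


def _clean(sample, name: str = "sample") -> np.ndarray:
    a = np.asarray(sample, dtype=float).ravel()
    if a.size == 0:
        raise DegenerateSampleError(f"{name} is empty")
    if not np.all(np.isfinite(a)):
        raise DegenerateSampleError(f"{name} contains non-finite values")
    return a


def normality_gate(sample, alpha: float = 0.05) -> NormalityResult:
    """D'Agostino & Pearson omnibus normality screen.

    The omnibus statistic K^2 = Z_skew^2 + Z_kurt^2 is referred to a
    chi-square with 2 df (scipy's ``normaltest``). It requires n >= 8;
    smaller samples report not-applicable (the gated workflow then falls
    back to the nonparametric branch). Constant samples are degenerate.
    """
    a = _clean(sample)
    if np.ptp(a) == 0:
        raise DegenerateSampleError("constant sample has no defined normality")
    if a.size < 8:
        return NormalityResult(p_value=None, passes=False, applicable=False)
    stat, p = sps.normaltest(a)
    return NormalityResult(p_value=float(p), passes=bool(p > alpha),
                           applicable=True)


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small tie-free
    samples, normal approximation with tie correction otherwise."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    a,
    b,
    alpha: float = 0.05,
    *,
    gate: bool = True,
    test: str = "auto",
    welch: bool = False,
) -> TestResult:
    """Normality-gated unpaired two-group comparison (two-sided).

    With ``gate`` on and ``test="auto"``: both samples pass the
    D'Agostino-Pearson screen -> Student's t (Welch by flag); otherwise
    Mann-Whitney. ``test`` may force ``"t"`` or ``"mw"``.
    """
    a = _clean(a, "a")
    b = _clean(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise DegenerateSampleError("both samples need n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise DegenerateSampleError("both samples constant and identical")

    p1 = p2 = None
    if test == "auto":
        if gate:
            g1 = normality_gate(a, alpha)
            g2 = normality_gate(b, alpha)
            p1, p2 = g1.p_value, g2.p_value
            parametric = g1.applicable and g2.applicable and g1.passes and g2.passes
        else:
            parametric = True
        chosen = "t" if parametric else "mw"
    elif test in ("t", "mw"):
        chosen = test
    else:
        raise ValueError(f"unknown test {test!r}")

    if chosen == "t":
        res = sps.ttest_ind(a, b, equal_var=not welch)
        name = "welch_t" if welch else "students_t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        name = "mann_whitney"
        stat, p = _mann_whitney(a, b)
    return TestResult(test_name=name, statistic=stat, p_value=min(p, 1.0),
                      n1=len(a), n2=len(b),
                      normality_p1=p1, normality_p2=p2, alpha=alpha)


def _ks_statistic(reference: np.ndarray, sample: np.ndarray) -> float:
    """D = sup |ECDF_ref - ECDF_sample| over the pooled support."""
    pooled = np.sort(np.concatenate([reference, sample]))
    f1 = ecdf(reference)(pooled)
    f2 = ecdf(sample)(pooled)
    return float(np.max(np.abs(f1 - f2)))


def ks_two_sample(reference, sample, *, method: str = "auto",
                  alpha: float = 0.05) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, reference sample first.

    D is the supremum ECDF difference; the p-value uses the asymptotic
    Kolmogorov distribution at effective size n1*n2/(n1+n2). For pooled
    sizes up to 16 (or ``method="exact"``) the exact permutation null is
    enumerated instead.
    """
    ref = _clean(reference, "reference")
    sam = _clean(sample, "sample")
    n1, n2 = len(ref), len(sam)
    d = _ks_statistic(ref, sam)
    if method == "auto":
        method = "exact" if (n1 + n2) <= 16 else "asymptotic"
    if method == "exact":
        pooled = np.concatenate([ref, sam])
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            d_perm = _ks_statistic(pooled[mask], pooled[~mask])
            count += d_perm >= d - 1e-12
            total += 1
        p = count / total
    elif method == "asymptotic":
        en = math.sqrt(n1 * n2 / (n1 + n2))
        p = float(special.kolmogorov(en * d))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(test_name="ks_two_sample", statistic=d,
                      p_value=min(max(p, 0.0), 1.0), n1=n1, n2=n2, alpha=alpha)


def ecdf(sample) -> Ecdf:
    """Empirical CDF of a sample; duplicates collapse into taller steps."""
    a = np.sort(_clean(sample))
    values, counts = np.unique(a, return_counts=True)
    fractions = np.cumsum(counts) / a.size
    return Ecdf(values=values, fractions=fractions)


def wilcoxon_matched_pairs(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on raw values
    (exact null for n <= 20 without ties/zeros, else normal
    approximation)."""
    x = _clean(x, "x")
    y = _clean(y, "y")
    if len(x) != len(y):
        raise DegenerateSampleError("matched pairs need equal lengths")
    diff = x - y
    if np.all(diff == 0):
        raise DegenerateSampleError("all pair differences are zero")
    mode = "exact" if (len(x) <= 20 and np.all(diff != 0)
                       and len(np.unique(np.abs(diff))) == len(diff)) else "approx"
    res = sps.wilcoxon(x, y, alternative="two-sided", method=mode)
    return TestResult(test_name="wilcoxon", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n1=len(x), n2=len(y),
                      alpha=alpha)
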