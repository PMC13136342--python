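"""Statistical tests used throughout the tDR and embryo analyses.

Thin, uniform wrappers around scipy / statsmodels / lifelines so every
result arrives as a :class:`TestResult` row with the method name, statistic,
raw p and (when a family is adjusted) a BH-corrected p. Conventions:

* Mann-Whitney U is two-sided; with no ties and a combined n of at most 12
  the exact permutation null is used, otherwise the normal approximation
  with tie correction.
* Welch's t and the pooled-variance (Student) t return p = 1 when both
  groups are constant and equal, and p = 0 (flagged degenerate) when both
  are constant but different -- zero-variance data carry no sampling noise.
* BH adjustment is the standard step-up procedure applied within one family
  (one panel's set of tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mann_whitney_two_sided",
    "bh_adjust",
    "welch_t",
    "student_t_unpaired",
    "depth_profile_test",
    "ks_two_sample",
    "log_rank",
    "km_curves",
]

EXACT_MWU_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


def _as_array(x, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValueError(f"{name}: need a 1-d vector with at least {min_n} values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values")
    return arr


def mann_whitney_two_sided(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation null when there are no ties and n1 + n2 <= 12;
    otherwise the tie-corrected normal approximation (with continuity
    correction).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and pooled.size <= EXACT_MWU_MAX_N
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann_whitney_u ({method})",
        n1=xa.size,
        n2=ya.size,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (one family per call)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _two_sample_t(x, y, equal_var: bool, label: str) -> TestResult:
    xa, ya = _as_array(x, "x", 2), _as_array(y, "y", 2)
    if np.var(xa) == 0.0 and np.var(ya) == 0.0:
        equal = xa.mean() == ya.mean()
        return TestResult(
            statistic=0.0 if equal else np.inf * np.sign(xa.mean() - ya.mean()),
            p_value=1.0 if equal else 0.0,
            method=f"{label} (degenerate: zero variance)",
            n1=xa.size,
            n2=ya.size,
        )
    res = sps.ttest_ind(xa, ya, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=label,
        n1=xa.size,
        n2=ya.size,
        extra={"df": float(res.df)},
    )


def welch_t(x, y) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df)."""
    return _two_sample_t(x, y, equal_var=False, label="welch_t")


def student_t_unpaired(x, y) -> TestResult:
    """Unpaired two-tailed Student t-test (pooled variance)."""
    return _two_sample_t(x, y, equal_var=True, label="student_t_unpaired")


def depth_profile_test(
    depth_a, depth_b, lib_size_a: float | None = None, lib_size_b: float | None = None
) -> TestResult:
    """Compare two per-nucleotide coverage profiles with Welch's t.

    Positions along the mature tRNA are treated as observations. Optional
    library sizes rescale each profile to reads per million before testing,
    so a global abundance shift between libraries registers as a location
    difference. Order of positions is irrelevant to the result.
    """
    a = _as_array(depth_a, "depth_a", 2)
    b = _as_array(depth_b, "depth_b", 2)
    if a.size != b.size:
        raise ValueError(
            f"depth vectors differ in length ({a.size} vs {b.size}); "
            "profiles must cover the same positions"
        )
    if lib_size_a is not None:
        a = a / lib_size_a * 1e6
    if lib_size_b is not None:
        b = b / lib_size_b * 1e6
    result = welch_t(a, b)
    result.method = "depth_profile_welch_t"
    return result


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (D = sup |ECDF difference|)."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    res = sps.ks_2samp(xa, ya, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="ks_two_sample (asymptotic)",
        n1=xa.size,
        n2=ya.size,
    )


def _check_survival(table: pd.DataFrame) -> None:
    required = {"time", "event", "arm"}
    if not required.issubset(table.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if (table["time"] < 0).any():
        raise ValueError("negative survival times")
    arms = table["arm"].unique()
    if len(arms) != 2:
        raise ValueError(f"log-rank needs exactly two arms, got {list(arms)}")
    for arm in arms:
        sub = table[table["arm"] == arm]
        if sub.empty:
            raise ValueError(f"arm {arm!r} has no subjects")
        if (sub["event"] == 1).sum() == 0:
            raise ValueError(f"arm {arm!r} has no observed events")


def log_rank(table: pd.DataFrame) -> TestResult:
    """Log-rank comparison of two survival arms (1-df chi-square).

    ``table`` columns: time (>= 0), event (1 died / 0 censored), arm label.
    """
    from lifelines.statistics import logrank_test

    _check_survival(table)
    arms = sorted(table["arm"].unique())
    a = table[table["arm"] == arms[0]]
    b = table[table["arm"] == arms[1]]
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        method="log_rank",
        n1=len(a),
        n2=len(b),
        extra={"arms": arms},
    )


def km_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival estimates per arm (long format)."""
    from lifelines import KaplanMeierFitter

    _check_survival(table)
    frames = []
    for arm, sub in table.groupby("arm"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(arm))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["arm"] = arm
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)
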