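"""Group comparison, method agreement, and t-test power / sample size.

This layer mirrors how vasospasm studies analyze their readouts: unpaired
pooled-variance Student t-tests between sham and hemorrhage groups,
Spearman rank correlation and Bland-Altman limits of agreement between
measurement methods (digital vs. microscopic diameters), and a
noncentral-t sample-size procedure for planning treatment studies.

Sample sizes are reported PER GROUP: the smallest integer n such that a
two-sided two-sample pooled t-test at level alpha on two groups of size n
has power >= the target, with power evaluated exactly from the noncentral
t distribution (df = 2n - 2, noncentrality (delta/sd) * sqrt(n/2)).
The planning convention for a two-arm treatment study takes the detectable
effect as a fraction (default 80%) of the control-vs-disease difference
and the disease group's standard deviation as the common SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """(n, mean, SD) summary of one measurement group."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise DataError(f"group {self.label!r} needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise DataError(f"group {self.label!r} has negative SD")


@dataclass
class PowerSpec:
    """Significance level, target power, and detectable-effect fraction."""

    alpha: float = 0.05
    power: float = 0.8
    effect_fraction: float = 0.8

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise DataError("power must be in (0, 1)")
        if not self.effect_fraction > 0:
            raise DataError("effect_fraction must be > 0")


class PairedMeasurements:
    """Per-specimen values measured by two methods, with audited exclusions.

    Rows are (id, method_a, method_b). Exclusions are first-class: they are
    removed from the retained table but logged with their reasons, so
    derived counts remain auditable.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"id", "method_a", "method_b"}
        if not required <= set(table.columns):
            raise DataError(f"paired table needs columns {sorted(required)}")
        if table[["method_a", "method_b"]].isna().any().any():
            raise DataError("retained rows must not contain missing values")
        self.table = table.reset_index(drop=True)
        self.exclusions: list[tuple[object, str]] = []

    @classmethod
    def from_arrays(cls, a, b, ids=None) -> "PairedMeasurements":
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) != len(b):
            raise DataError("method_a and method_b must have equal length")
        ids = np.arange(len(a)) if ids is None else np.asarray(ids)
        return cls(pd.DataFrame({"id": ids, "method_a": a, "method_b": b}))

    @classmethod
    def from_csv(cls, path) -> "PairedMeasurements":
        return cls(pd.read_csv(path))

    def exclude(self, ids, reason: str) -> "PairedMeasurements":
        """Drop the given row ids, logging the reason. Returns self."""
        ids = list(np.atleast_1d(ids))
        missing = [i for i in ids if i not in set(self.table["id"])]
        if missing:
            raise DataError(f"cannot exclude unknown ids {missing}")
        for i in ids:
            self.exclusions.append((i, reason))
            logger.info("excluded measurement %r: %s", i, reason)
        self.table = self.table[~self.table["id"].isin(ids)].reset_index(drop=True)
        return self

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def a(self) -> np.ndarray:
        return self.table["method_a"].to_numpy(float)

    @property
    def b(self) -> np.ndarray:
        return self.table["method_b"].to_numpy(float)


# -- comparison -------------------------------------------------------------


def two_sample_ttest(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired Student t-test (pooled variance by default; Welch optional).

    Returns (t, df, two-sided p). With zero pooled variance, equal means
    give p = 1 and unequal means are an error (the statistic diverges).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs n >= 2")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise DataError("zero pooled variance with unequal means: t is undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def spearman_corr(pairs: PairedMeasurements, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation t = rho * sqrt((n-2)/(1-rho^2))
    with n - 2 degrees of freedom; `exact=True` enumerates all rank
    permutations instead (only for n <= 10).
    """
    if pairs.n < 3:
        raise DataError("Spearman correlation needs n >= 3")
    a, b = pairs.a, pairs.b
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise DataError("Spearman correlation is undefined for a constant column")
    rho, p = sps.spearmanr(a, b)
    if exact:
        if pairs.n > 10:
            raise DataError("exact permutation p-value limited to n <= 10")
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        observed = abs(_rank_corr(ra, rb))
        count = 0
        total = 0
        for perm in permutations(rb):
            total += 1
            if abs(_rank_corr(ra, np.asarray(perm))) >= observed - 1e-12:
                count += 1
        p = count / total
    return float(rho), float(p)


def _rank_corr(ra, rb) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


# -- agreement --------------------------------------------------------------


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman method agreement: bias = mean(a - b), limits of
    agreement = bias +/- 1.96 * SD(a - b) (sample SD, n - 1)."""
    if pairs.n < 2:
        raise DataError("Bland-Altman needs n >= 2")
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, pairs.n)


def ratio_stats(pairs: PairedMeasurements) -> tuple[float, float, int]:
    """Mean, sample SD and n of the per-row ratio a / b. Rows with a zero
    denominator are excluded with a logged reason."""
    zero_ids = pairs.table.loc[pairs.table["method_b"] == 0, "id"].tolist()
    if zero_ids:
        pairs.exclude(zero_ids, "zero denominator in ratio computation")
    if pairs.n < 1:
        raise DataError("no rows left for ratio statistics")
    r = pairs.a / pairs.b
    sd = float(r.std(ddof=1)) if pairs.n > 1 else 0.0
    return float(r.mean()), sd, pairs.n


# -- power / sample size ----------------------------------------------------


def ttest_power(n_per_group: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided two-sample pooled t-test with `n_per_group`
    subjects per arm, true mean difference `delta` and common SD `sd`."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = (delta / sd) * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_ttest(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.8, n_max: int = 10**6
) -> int:
    """Smallest per-group n giving a two-sided two-sample pooled t-test at
    level `alpha` power >= `power` for true difference `delta` and common
    SD `sd` (noncentral-t evaluation; result >= 2)."""
    if delta <= 0:
        raise DataError("delta must be > 0 (a zero effect needs infinite n)")
    if sd <= 0:
        raise DataError("sd must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise DataError("alpha and power must be in (0, 1)")
    n = 2
    while n <= n_max:
        if ttest_power(n, delta, sd, alpha) >= power:
            return n
        n += 1
    raise DataError(f"required sample size exceeds {n_max} per group")


def treatment_study_n(sham: GroupSummary, sah: GroupSummary, spec: PowerSpec | None = None) -> int:
    """Per-group animal number for a two-arm treatment study powered to
    detect `effect_fraction` of the sham-vs-disease difference, assuming
    the disease group's SD."""
    spec = spec or PowerSpec()
    if sham.mean == sah.mean:
        raise DataError("sham and disease means are equal; the effect is zero")
    delta = spec.effect_fraction * abs(sham.mean - sah.mean)
    return sample_size_ttest(delta, sah.sd, alpha=spec.alpha, power=spec.power)
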