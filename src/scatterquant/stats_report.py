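"""Statistical reporting: Student's t, one-way ANOVA, Tukey HSD, summaries.

The test statistics (pooled-variance t, ANOVA sums of squares, Tukey–Kramer
studentized range q) are computed from the textbook formulas so that
degenerate inputs — zero pooled variance, all-identical observations — get
explicit, logged conventions instead of NaNs; p-values come from the scipy
t, F and studentized-range distributions.

Significance stars follow the usual convention: * P < 0.05, ** P < 0.01,
*** P < 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p, stars."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    stars: str = field(init=False)
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.stars = significance_stars(self.p_value)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in out.items():
        if v.ndim != 1 or len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 one-dimensional observations")
    return out


def t_test(a: Sequence[float], b: Sequence[float], two_sided: bool = True,
           welch: bool = False) -> TestResult:
    """Two-sample Student's t-test (pooled variance; Welch behind a flag).

    With zero pooled variance the test is degenerate: p = 1 when the means
    are equal, p = 0 otherwise (both logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()

    if welch:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_t(ma, mb, float(na + nb - 2))
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        df = float(na + nb - 2)
        if sp2 == 0:
            return _degenerate_t(ma, mb, df)
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))

    if two_sided:
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        p = sps.t.sf(t, df)
    return TestResult("t-test" + (" (Welch)" if welch else ""), float(t),
                      (float(df),), float(min(p, 1.0)))


def _degenerate_t(ma: float, mb: float, df: float) -> TestResult:
    if ma == mb:
        logger.warning("zero pooled variance with equal means; reporting p = 1")
        return TestResult("t-test", 0.0, (df,), 1.0)
    logger.warning("zero pooled variance with unequal means; reporting p = 0")
    return TestResult("t-test", np.inf if ma > mb else -np.inf, (df,), 0.0)


def _anova_core(groups: dict[str, np.ndarray]):
    """Between/within mean squares and dfs from raw sums of squares."""
    all_obs = np.concatenate(list(groups.values()))
    grand = all_obs.mean()
    k = len(groups)
    n_total = len(all_obs)
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between, df_within = k - 1, n_total - k
    return ss_between, ss_within, df_between, df_within


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    All-identical observations are degenerate; F = 0, p = 1 is reported with
    a warning.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    ssb, ssw, dfb, dfw = _anova_core(g)
    if ssw == 0:
        if ssb == 0:
            logger.warning("all observations identical; reporting F = 0, p = 1")
            return TestResult("one-way ANOVA", 0.0, (float(dfb), float(dfw)), 1.0,
                              groups=tuple(g))
        logger.warning("zero within-group variance with unequal means; p = 0")
        return TestResult("one-way ANOVA", np.inf, (float(dfb), float(dfw)), 0.0,
                          groups=tuple(g))
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return TestResult("one-way ANOVA", float(f), (float(dfb), float(dfw)), p,
                      groups=tuple(g))


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """All-pairs Tukey post hoc with studentized-range p-values.

    Balanced designs give the exact Tukey HSD; unbalanced groups use the
    Tukey–Kramer standard error  sqrt(MS_within/2 * (1/n_i + 1/n_j)).
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    ssb, ssw, dfb, dfw = _anova_core(g)
    k = len(g)
    results = []
    for name_i, name_j in combinations(g, 2):
        vi, vj = g[name_i], g[name_j]
        diff = vi.mean() - vj.mean()
        if ssw == 0:
            p = 1.0 if diff == 0 else 0.0
            q = 0.0 if diff == 0 else np.inf
            logger.warning("zero within-group variance in Tukey HSD; p = %g", p)
        else:
            msw = ssw / dfw
            se = np.sqrt(msw / 2.0 * (1.0 / len(vi) + 1.0 / len(vj)))
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, dfw), 0.0, 1.0))
        results.append(
            TestResult("Tukey HSD", float(q), (float(k), float(dfw)), p,
                       groups=(name_i, name_j))
        )
    return results


@dataclass
class Summary:
    """Mean ± sample SD of replicate observations (SD undefined at n = 1)."""

    mean: float
    sd: float | None
    n: int

    def __str__(self) -> str:
        if self.sd is None:
            return f"{self.mean:g} (n = 1, SD undefined)"
        return f"{self.mean:g} ± {self.sd:g} (n = {self.n})"


def summarize(values: Sequence[float], n_fields: int | None = None) -> Summary:
    """Mean and sample SD (n−1 denominator) of replicate measurements.

    ``n_fields`` optionally asserts the expected replicate count, e.g. cell
    counts averaged over four microscopic fields per well.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if n_fields is not None and v.size != n_fields:
        raise ValueError(f"expected {n_fields} field values, got {v.size}")
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    if sd is None:
        logger.warning("single observation; SD undefined")
    return Summary(mean=float(v.mean()), sd=sd, n=int(v.size))


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = [
        {
            "test": r.test,
            "groups": " vs ".join(r.groups) if r.groups else "",
            "statistic": r.statistic,
            "df": "/".join(f"{d:g}" for d in r.df),
            "p_value": r.p_value,
            "stars": r.stars,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
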