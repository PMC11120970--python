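"""Group-comparison statistics for the analysis pipeline.

Mirrors the statistical toolkit of the source study: a two-sample test for
equality of proportions with Yates continuity correction (used for the
proportion of 200 nm inter-peak distances), the two-sample
Kolmogorov-Smirnov test for inter-peak distance distributions,
Kruskal-Wallis / Mann-Whitney omnibus and pairwise comparisons with
Tukey-Kramer for parametric families, chi-squared on pooled fiber counts,
and Shapiro-Wilk / Levene pre-checks reported alongside every family.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TwoPropResult",
    "StatsReport",
    "group_summary",
    "two_prop_test",
    "ks_2sample",
    "omnibus_and_pairwise",
]

FAMILIES = ("kruskal_wallis", "mann_whitney", "anova_tukey", "chi2_counts")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    median: float
    iqr: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TwoPropResult:
    statistic: float
    pvalue: float
    proportions: tuple[float, float]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class StatsReport:
    family: str
    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    prechecks: pd.DataFrame


def group_summary(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean +- SEM and median/IQR per group, as reported in figure legends."""
    rows = []
    for label, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        n = v.size
        if n < 1:
            raise ValueError(f"group {label!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        q75, q25 = np.percentile(v, [75, 25])
        rows.append(
            GroupSummary(
                group=str(label),
                n=int(n),
                mean=float(v.mean()),
                sem=sem,
                median=float(np.median(v)),
                iqr=float(q75 - q25),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def two_prop_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> TwoPropResult:
    """2-sample test for equality of proportions with continuity correction.

    Chi-squared statistic on the pooled-proportion 2x2 table with the Yates
    correction (the absolute difference of proportions is reduced by
    (1/n1 + 1/n2)/2, floored at zero) and a two-sided p-value from the
    chi-squared distribution with 1 df.  Matches R's ``prop.test``.
    Symmetric in the two groups.  When both proportions are 0 or both are 1
    the pooled variance vanishes; p = 1 by convention, flagged.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("trial counts must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TwoPropResult(0.0, 1.0, (p1, p2), flags=("degenerate",))
    se2 = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    cc = 0.5 * (1.0 / n1 + 1.0 / n2) if continuity else 0.0
    d = max(abs(p1 - p2) - cc, 0.0)
    stat = d * d / se2
    return TwoPropResult(float(stat), float(sps.chi2.sf(stat, 1)), (p1, p2))


def ks_2sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _prechecks(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for label, v in samples.items():
        if v.size >= 3 and np.ptp(v) > 0:
            w, p = sps.shapiro(v)
        else:
            w, p = float("nan"), float("nan")
        rows.append({"check": "shapiro", "group": label, "statistic": w, "pvalue": p})
    if (
        len(samples) >= 2
        and all(v.size >= 2 for v in samples.values())
        and any(np.ptp(v) > 0 for v in samples.values())
    ):
        with np.errstate(invalid="ignore"):
            w, p = sps.levene(*samples.values())
        if np.isfinite(w):
            rows.append({"check": "levene", "group": "all", "statistic": w, "pvalue": p})
    return pd.DataFrame(rows)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # asymptotic normal approximation with mid-rank tie correction and no
    # continuity correction, so identical groups give p = 1 exactly
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def omnibus_and_pairwise(
    samples: Mapping[str, Sequence[float]],
    family: str = "kruskal_wallis",
) -> StatsReport:
    """Omnibus test plus pairwise comparisons for one family of tests.

    Families: ``kruskal_wallis`` (omnibus Kruskal-Wallis, pairwise
    Mann-Whitney U), ``mann_whitney`` (two groups only), ``anova_tukey``
    (one-way ANOVA with Tukey-Kramer pairwise), ``chi2_counts``
    (chi-squared goodness of fit on pooled count totals per group, pairwise
    on group pairs).  Groups with fewer than 2 observations are excluded
    with a warning.  Normality (Shapiro-Wilk) and homogeneity of variance
    (Levene) checks are reported alongside.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    clean: dict[str, np.ndarray] = {}
    for label, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            warnings.warn(f"group {label!r} has n < 2 and was excluded", stacklevel=2)
            continue
        clean[str(label)] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    labels = list(clean)
    if family == "mann_whitney" and len(labels) != 2:
        raise ValueError("mann_whitney requires exactly 2 groups")

    pre = _prechecks(clean)
    pairs = list(itertools.combinations(labels, 2))
    pair_rows = []

    if family in ("kruskal_wallis", "mann_whitney"):
        if family == "kruskal_wallis":
            stat, p = sps.kruskal(*clean.values())
            omni_name = "kruskal_wallis"
        else:
            stat, p = _mannwhitney(clean[labels[0]], clean[labels[1]])
            omni_name = "mann_whitney"
        for a, b in pairs:
            s, pv = _mannwhitney(clean[a], clean[b])
            pair_rows.append({"group1": a, "group2": b, "test": "mann_whitney", "statistic": s, "pvalue": pv})
    elif family == "anova_tukey":
        stat, p = sps.f_oneway(*clean.values())
        omni_name = "anova"
        tk = sps.tukey_hsd(*clean.values())
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            pair_rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "test": "tukey_kramer",
                    "statistic": float(tk.statistic[i, j]),
                    "pvalue": float(tk.pvalue[i, j]),
                }
            )
    else:  # chi2_counts
        totals = {k: float(v.sum()) for k, v in clean.items()}
        obs = np.asarray(list(totals.values()))
        stat, p = sps.chisquare(obs)
        omni_name = "chi2_counts"
        for a, b in pairs:
            s, pv = sps.chisquare(np.asarray([totals[a], totals[b]]))
            pair_rows.append({"group1": a, "group2": b, "test": "chi2_counts", "statistic": float(s), "pvalue": float(pv)})

    omnibus = pd.DataFrame(
        [{"test": omni_name, "n_groups": len(labels), "statistic": float(stat), "pvalue": float(p)}]
    )
    pairwise = pd.DataFrame(pair_rows)
    return StatsReport(family=family, omnibus=omnibus, pairwise=pairwise, prechecks=pre)
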