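"""Statistical battery over axes-angle (AA) tables.

Covers the analyses of the study: per-tooth descriptives (median, range,
quartiles), a normality screen (Shapiro-Wilk), nonparametric group
comparisons (Mann-Whitney between sexes, Kruskal-Wallis between Angle
classes) with Bonferroni adjustment, intra-examiner method error
(Bland-Altman limits of agreement plus paired t-tests for systematic
error), and the Dupont-Plummer paired-design sample-size formula.

The hypothesis tests delegate to scipy.stats; the sample-size iteration,
Bland-Altman computation and Bonferroni adjustment are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleSizeParams",
    "BlandAltmanResult",
    "ToothSummary",
    "StatsError",
    "dupont_plummer_n",
    "shapiro_wilk",
    "mann_whitney",
    "kruskal_wallis",
    "bonferroni_adjust",
    "paired_t",
    "bland_altman",
    "summarize_aa",
    "repeatability_report",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# Sample size (Dupont & Plummer, paired design)
# ---------------------------------------------------------------------------


@dataclass
class SampleSizeParams:
    """Inputs to the paired-design sample-size relation.

    ``s`` is the estimated standard deviation of within-pair differences
    (degrees), ``d`` the minimum difference to detect (degrees).
    """

    s: float = 5.0
    d: float = 3.0
    alpha: float = 0.05
    power: float = 0.80

    def validate(self) -> None:
        if self.s <= 0 or self.d <= 0:
            raise StatsError("s and d must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise StatsError("alpha and power must be in (0, 1)")


def dupont_plummer_n(params: SampleSizeParams | None = None, **kwargs) -> int:
    """Smallest n with ``n >= (s/d)^2 (t_{alpha/2,n-1} + t_{beta,n-1})^2``.

    The paired-design sample-size relation is implicit in n because the
    Student t quantiles carry ``n - 1`` degrees of freedom; it is solved
    by fixed-point iteration from the normal-approximation start, with the
    ceiling applied at each step.  A floor of n = 2 applies (one degree of
    freedom is the minimum for a paired t-test).

    ``dupont_plummer_n(s=5, d=3)`` with the default alpha 0.05 and power
    0.80 gives 24.
    """
    if params is None:
        params = SampleSizeParams(**kwargs)
    elif kwargs:
        raise StatsError("pass either a SampleSizeParams or keyword fields, not both")
    params.validate()
    ratio2 = (params.s / params.d) ** 2

    def required(n: int) -> float:
        k = n - 1
        t_sum = sps.t.ppf(1 - params.alpha / 2, k) + sps.t.ppf(params.power, k)
        return ratio2 * t_sum**2

    # t quantiles exceed normal quantiles, so the normal-approximation n
    # is a lower bound; scan upward from it to the first n that satisfies
    # the relation (the satisfying set is upward-closed: required(n) is
    # decreasing in n)
    z = sps.norm.ppf(1 - params.alpha / 2) + sps.norm.ppf(params.power)
    n = max(2, math.ceil(ratio2 * z**2))
    for _ in range(1_000_000):
        if n >= required(n):
            return n
        n += 1
    raise StatsError("sample-size search did not converge")


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def _arr(x: Iterable[float], name: str) -> np.ndarray:
    a = np.asarray(list(x), dtype=float)
    if a.ndim != 1:
        raise StatsError(f"{name} must be one-dimensional")
    return a


def shapiro_wilk(values: Iterable[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p), n in [3, 5000]."""
    v = _arr(values, "values")
    if not (3 <= len(v) <= 5000):
        raise StatsError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(v)}")
    if np.ptp(v) == 0:
        raise StatsError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


_MW_EXACT_MAX_N = 12  # exact enumeration below this total n (tie-free)


def mann_whitney(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    U counts pairs with ``a_i > b_j`` (ties count one half).  The p-value
    is exact (full enumeration) when the combined sample is small
    (n_a + n_b <= 12) and tie-free; otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    x, y = _arr(a, "a"), _arr(b, "b")
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= _MW_EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(groups: Sequence[Iterable[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected), p from chi-square (k-1 df)."""
    gs = [_arr(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise StatsError("need at least 2 non-empty groups")
    if sum(len(g) for g in gs) < 3:
        raise StatsError("need at least 3 observations in total")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        raise StatsError("H is undefined when all values are identical")
    h, p = sps.kruskal(*gs)
    return float(h), float(p)


def bonferroni_adjust(pvalues: Iterable[float]) -> list[float]:
    """Bonferroni multiplicity adjustment: ``p * m`` capped at 1."""
    ps = _arr(pvalues, "pvalues")
    if np.any((ps < 0) | (ps > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    m = len(ps)
    return [float(min(p * m, 1.0)) for p in ps]


def paired_t(x: Iterable[float], y: Iterable[float]) -> tuple[float, float, int]:
    """Paired t-test: (t, two-sided p, df)."""
    xa, ya = _arr(x, "x"), _arr(y, "y")
    if len(xa) != len(ya):
        raise StatsError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 2:
        raise StatsError("need at least 2 pairs")
    d = xa - ya
    if np.ptp(d) == 0:
        raise StatsError("differences have zero variance")
    res = sps.ttest_rel(xa, ya)
    return float(res.statistic), float(res.pvalue), len(xa) - 1


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement (bias ± 1.96 SD)."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(x: Iterable[float], y: Iterable[float]) -> BlandAltmanResult:
    """Bland-Altman agreement between two measurement sets.

    Differences are ``x - y``; the limits of agreement use the classical
    1.96 multiplier on the sample SD (n-1 denominator).
    """
    xa, ya = _arr(x, "x"), _arr(y, "y")
    if len(xa) != len(ya):
        raise StatsError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 2:
        raise StatsError("need at least 2 pairs")
    d = xa - ya
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=len(d),
    )


# ---------------------------------------------------------------------------
# Study-level summaries
# ---------------------------------------------------------------------------


@dataclass
class ToothSummary:
    """Per-tooth descriptives of AA (degrees); quartiles by linear
    interpolation between order statistics."""

    tooth: int
    n: int
    median: float
    min: float
    max: float
    q1: float
    q3: float


def _tooth_summaries(aa: pd.DataFrame) -> list[ToothSummary]:
    out = []
    for tooth, grp in aa.groupby("tooth_fdi"):
        v = grp["aa_deg"].dropna().to_numpy()
        if len(v) == 0:
            continue
        out.append(
            ToothSummary(
                tooth=int(tooth),
                n=len(v),
                median=float(np.median(v)),
                min=float(v.min()),
                max=float(v.max()),
                q1=float(np.quantile(v, 0.25)),
                q3=float(np.quantile(v, 0.75)),
            )
        )
    return out


def summarize_aa(
    aa: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    pool_teeth_for_sex: bool = False,
) -> tuple[list[ToothSummary], pd.DataFrame]:
    """Descriptive and comparative statistics of an AA table.

    Parameters
    ----------
    aa
        Tidy table with columns ``subject``, ``tooth_fdi``, ``aa_deg``.
    metadata
        One row per subject: ``subject``, ``sex``, ``age``, ``angle_class``.
    pool_teeth_for_sex
        Pool all teeth into one sex comparison instead of testing per
        tooth with Bonferroni adjustment.

    Returns the per-tooth summaries and a tidy test report with columns
    ``test``, ``tooth``, ``statistic``, ``p_raw``, ``p_adjusted``.
    The age comparison uses a median split of subject age (the study
    reports an age-group comparison without defining its grouping; the
    split used here is stated in the report).
    """
    required = {"subject", "tooth_fdi", "aa_deg"}
    missing = required - set(aa.columns)
    if missing:
        raise StatsError(f"AA table is missing columns: {sorted(missing)}")
    required_md = {"subject", "sex", "age", "angle_class"}
    missing = required_md - set(metadata.columns)
    if missing:
        raise StatsError(f"metadata table is missing columns: {sorted(missing)}")

    df = aa.merge(metadata, on="subject", how="left").dropna(subset=["aa_deg"])
    summaries = _tooth_summaries(df)

    tests: list[dict] = []

    def add_block(name: str, rows: list[dict]) -> None:
        ps = [r["p_raw"] for r in rows]
        adj = bonferroni_adjust(ps) if len(ps) > 1 else list(ps)
        for r, pa in zip(rows, adj):
            tests.append({**r, "test": name, "p_adjusted": pa})

    # normality screen per tooth
    rows = []
    for tooth, grp in df.groupby("tooth_fdi"):
        v = grp["aa_deg"].to_numpy()
        if len(v) >= 3 and np.ptp(v) > 0:
            try:
                w, p = shapiro_wilk(v)
            except StatsError:
                continue
            rows.append({"tooth": int(tooth), "statistic": w, "p_raw": p})
    add_block("shapiro_wilk", rows)

    # sex comparison (Mann-Whitney)
    if pool_teeth_for_sex:
        m = df.loc[df["sex"] == "M", "aa_deg"]
        f = df.loc[df["sex"] == "F", "aa_deg"]
        if len(m) and len(f):
            u, p = mann_whitney(m, f)
            add_block("sex_mann_whitney_pooled", [{"tooth": 0, "statistic": u, "p_raw": p}])
    else:
        rows = []
        for tooth, grp in df.groupby("tooth_fdi"):
            m = grp.loc[grp["sex"] == "M", "aa_deg"]
            f = grp.loc[grp["sex"] == "F", "aa_deg"]
            if len(m) and len(f):
                try:
                    u, p = mann_whitney(m, f)
                except StatsError:
                    continue
                rows.append({"tooth": int(tooth), "statistic": u, "p_raw": p})
        add_block("sex_mann_whitney", rows)

    # Angle-class comparison (Kruskal-Wallis)
    rows = []
    for tooth, grp in df.groupby("tooth_fdi"):
        gs = [g["aa_deg"].to_numpy() for _, g in grp.groupby("angle_class") if len(g)]
        if len(gs) >= 2 and np.ptp(np.concatenate(gs)) > 0:
            try:
                h, p = kruskal_wallis(gs)
            except StatsError:
                continue
            rows.append({"tooth": int(tooth), "statistic": h, "p_raw": p})
    add_block("angle_class_kruskal_wallis", rows)

    # age comparison: median split (grouping rule stated in the report)
    med_age = metadata["age"].median()
    rows = []
    for tooth, grp in df.groupby("tooth_fdi"):
        young = grp.loc[grp["age"] <= med_age, "aa_deg"]
        old = grp.loc[grp["age"] > med_age, "aa_deg"]
        if len(young) and len(old):
            try:
                u, p = mann_whitney(young, old)
            except StatsError:
                continue
            rows.append({"tooth": int(tooth), "statistic": u, "p_raw": p})
    add_block(f"age_mann_whitney_median_split_{med_age:g}", rows)

    report = pd.DataFrame(tests, columns=["test", "tooth", "statistic", "p_raw", "p_adjusted"])
    return summaries, report


def repeatability_report(
    first: pd.DataFrame,
    second: pd.DataFrame,
    loa_flag_deg: float = 4.5,
) -> pd.DataFrame:
    """Intra-examiner method error between two AA tables.

    Both tables must cover the same (subject, tooth) keys.  Per tooth:
    Bland-Altman bias and limits of agreement plus a paired t-test for
    systematic error; teeth whose LoA half-width exceeds ``loa_flag_deg``
    (default 4.5 degrees, the agreement bound the original examiners
    achieved) are flagged.
    """
    keys = ["subject", "tooth_fdi"]
    a = first.set_index(keys)["aa_deg"]
    b = second.set_index(keys)["aa_deg"]
    unmatched = a.index.symmetric_difference(b.index)
    if len(unmatched):
        raise StatsError(f"tables cover different keys: {list(unmatched)[:10]}")
    merged = pd.DataFrame({"first": a, "second": b.loc[a.index]}).reset_index()
    rows = []
    for tooth, grp in merged.groupby("tooth_fdi"):
        ba = bland_altman(grp["first"], grp["second"])
        try:
            t, p, _ = paired_t(grp["first"], grp["second"])
        except StatsError:  # identical repeats: no systematic error testable
            t, p = 0.0, 1.0
        rows.append(
            {
                "tooth": int(tooth),
                "n": ba.n,
                "bias": ba.bias,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
                "paired_t": t,
                "p_systematic": p,
                "flagged": max(abs(ba.loa_lower - ba.bias), abs(ba.loa_upper - ba.bias))
                > loa_flag_deg,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[ToothSummary]) -> pd.DataFrame:
    """Per-tooth summary list as a table (one row per tooth)."""
    return pd.DataFrame([vars(s) for s in summaries])


def plot_aa_univariate(aa: pd.DataFrame, path: str) -> None:
    """Univariate strip plot of AA per tooth (degrees), saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = aa.dropna(subset=["aa_deg"])
    teeth = sorted(df["tooth_fdi"].unique())
    fig, ax = plt.subplots(figsize=(8, 4.5))
    rng = np.random.default_rng(0)
    for i, tooth in enumerate(teeth):
        v = df.loc[df["tooth_fdi"] == tooth, "aa_deg"].to_numpy()
        x = i + rng.uniform(-0.15, 0.15, size=len(v))
        ax.plot(x, v, "o", ms=3, alpha=0.6)
        ax.plot([i - 0.25, i + 0.25], [np.median(v)] * 2, "k-", lw=1.5)
    ax.set_xticks(range(len(teeth)), [str(t) for t in teeth])
    ax.set_xlabel("tooth (FDI)")
    ax.set_ylabel("axes angle (degrees)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
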