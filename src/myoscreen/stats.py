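"""Nonparametric group comparisons and the AWGS 2019 screening rule.

The study compares MVC-normalized sEMG features between sarcopenic and healthy
subjects with the Mann-Whitney U test, and between the two contraction levels
within each group with the Wilcoxon matched-pairs signed-rank test, at
alpha = 0.05 and without multiplicity correction. Levene and one-sample
Kolmogorov-Smirnov checks are reported for audit only; the pipeline always
proceeds nonparametrically.

Exact p-values are computed by enumeration of the permutation distribution
with midrank tie handling (shift-algorithm counting) for small samples
(combined n <= 20 for Mann-Whitney, n <= 25 nonzero pairs for Wilcoxon);
larger samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: crossover sample sizes between exact enumeration and normal approximation
MWU_EXACT_MAX_N = 20
WILCOXON_EXACT_MAX_N = 25

# AWGS 2019 cutoffs
SMI_CUTOFF = {"M": 7.0, "F": 5.7}        # kg/m^2, low muscle mass below
GRIP_CUTOFF = {"M": 28.0, "F": 18.0}     # kg, low strength below
TCST_CUTOFF = 12.0                       # s, low performance at or above


@dataclass(frozen=True)
class AWGSRecord:
    """One subject's screening measurements: sex, grip (kg), SMI (kg/m^2), 5TCST (s)."""

    sex: str
    grip_kg: float
    smi_kg_m2: float
    tcst_s: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex code {self.sex!r}, expected 'M' or 'F'")
        for name in ("grip_kg", "smi_kg_m2", "tcst_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    feature: str = ""
    level: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def awgs_screen(rec: AWGSRecord) -> str:
    """Classify a subject by the AWGS 2019 rule.

    Sarcopenic requires low muscle mass plus at least one of low grip strength
    or low chair-stand performance; healthy requires all three in the normal
    range; anything else is intermediate.
    """
    low_mass = rec.smi_kg_m2 < SMI_CUTOFF[rec.sex]
    low_strength = rec.grip_kg < GRIP_CUTOFF[rec.sex]
    low_performance = rec.tcst_s >= TCST_CUTOFF
    if low_mass and (low_strength or low_performance):
        return "sarcopenic"
    if not (low_mass or low_strength or low_performance):
        return "healthy"
    return "intermediate"


# ---------------------------------------------------------------------------
# exact enumeration machinery (midranks scaled x2 so they are integers)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _rank_sum_distribution(doubled_ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Count, for every achievable doubled rank-sum s, the number of size-n_a
    subsets of the pooled ranks attaining it. Returns counts indexed by s."""
    total = int(doubled_ranks.sum())
    # dp[k][s] = number of k-subsets with doubled rank sum s
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(min(n_a, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n_a]


def _two_sided_p(counts: np.ndarray, observed: int) -> float:
    total = counts.sum()
    p_low = counts[: observed + 1].sum() / total
    p_high = counts[observed:].sum() / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney_u(a, b, feature: str = "", level: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact permutation p for combined n <= 20, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    rank_sum_a = ranks[:n_a].sum()
    u = rank_sum_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= MWU_EXACT_MAX_N:
        doubled = np.round(ranks * 2).astype(int)
        counts = _rank_sum_distribution(doubled, n_a)
        p = _two_sided_p(counts, int(round(rank_sum_a * 2)))
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return TestResult("mann-whitney-u", float(u), p, (n_a, n_b), feature, level)


def wilcoxon_signed_rank(differences, feature: str = "", level: str = "") -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired differences.

    Zero differences are dropped; |d| are midranked. Exact sign-assignment
    enumeration for n <= 25 nonzero pairs, else normal approximation with
    continuity correction. The reported statistic is W+ (sum of positive ranks).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    n = d.size
    ranks = _midranks(np.abs(d))
    w_plus = ranks[d > 0].sum()

    if n <= WILCOXON_EXACT_MAX_N:
        doubled = np.round(ranks * 2).astype(int)
        total = int(doubled.sum())
        # distribution of doubled W+ over the 2^n equiprobable sign assignments
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        p = _two_sided_p(counts, int(round(w_plus * 2)))
    else:
        p = float(
            sps.wilcoxon(d, alternative="two-sided", correction=True,
                         method="approx").pvalue
        )
    return TestResult("wilcoxon-signed-rank", float(w_plus), p, (n,), feature, level)


def variance_and_normality_checks(a, b) -> tuple[TestResult, TestResult]:
    """Audit checks: classic Levene (absolute deviations from the mean) on the
    two groups, and a one-sample KS test of the pooled sample against a Gaussian
    with the sample's own mean and SD. Reported for the record only; the
    pipeline proceeds nonparametrically regardless."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate zero-variance input")
    lev_stat, lev_p = sps.levene(a, b, center="mean")
    mu, sd = pooled.mean(), pooled.std(ddof=1)
    ks_stat, ks_p = sps.kstest(pooled, "norm", args=(mu, sd))
    return (
        TestResult("levene", float(lev_stat), float(lev_p), (a.size, b.size)),
        TestResult("ks-normality", float(ks_stat), float(ks_p), (pooled.size,)),
    )


def feature_comparison_report(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Run the study's comparison battery on a subject-level feature table.

    ``subject_table`` has one row per (subject, level, feature) with columns
    subject, group, level, feature, value (channel/trial-averaged, normalized).
    Emits Mann-Whitney results per (feature, level) across groups and Wilcoxon
    results per (feature, group) between the two levels. No multiplicity
    correction, matching the study's reporting.
    """
    required = {"subject", "group", "level", "feature", "value"}
    if not required.issubset(subject_table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    levels = sorted(subject_table["level"].unique())
    if len(levels) < 2:
        raise ValueError("need both contraction levels present")
    groups = sorted(subject_table["group"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    for g in groups:
        if subject_table.loc[subject_table["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    rows = []
    for (feat, level), sub in subject_table.groupby(["feature", "level"]):
        a = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
        res = mann_whitney_u(a, b, feature=feat, level=str(level))
        rows.append(
            dict(feature=feat, level=str(level), test=res.test, comparison="group",
                 statistic=res.statistic, p=res.p_value, significant=res.significant)
        )
    lo, hi = levels[0], levels[1]
    for (feat, grp), sub in subject_table.groupby(["feature", "group"]):
        wide = sub.pivot_table(index="subject", columns="level", values="value")
        if lo not in wide.columns or hi not in wide.columns:
            raise ValueError(f"missing level for feature {feat!r}, group {grp!r}")
        d = (wide[hi] - wide[lo]).dropna().to_numpy()
        res = wilcoxon_signed_rank(d, feature=feat, level=f"{hi}-{lo}")
        rows.append(
            dict(feature=feat, level=f"{hi}-{lo}", test=res.test,
                 comparison=f"level-within-{grp}", statistic=res.statistic,
                 p=res.p_value, significant=res.significant)
        )
    return pd.DataFrame(rows)


def holm_correction(report: pd.DataFrame) -> pd.DataFrame:
    """Optional Holm step-down adjustment of a comparison report (off by default
    in the pipeline, provided for sensitivity analyses)."""
    out = report.copy()
    p = out["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    out["p_holm"] = adj
    out["significant_holm"] = adj < ALPHA
    return out
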