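"""Adaptive three-group comparison, post-hocs, effect sizes, correlations.

The omnibus test is chosen by a fixed decision tree at significance level
alpha (default 0.05):

1. Shapiro-Wilk normality per group, and a chi-square goodness-of-fit test
   of the group sizes against equal expected counts.
2. If any group is non-normal OR sizes are significantly unequal:
   Kruskal-Wallis, effect size epsilon^2 = H / ((n^2 - 1)/(n + 1)),
   post-hoc pairwise Wilcoxon rank-sum (Mann-Whitney) tests.
3. Otherwise Levene's test (mean-centred): homogeneous variances ->
   one-way ANOVA with pairwise t-tests; heterogeneous -> Welch's ANOVA with
   pairwise Welch t-tests.  Effect size eta^2 = SS_between / SS_total in
   both cases (approximate under the Welch branch).

All pairwise p-values receive Holm's step-down familywise adjustment.
Every intermediate assumption-check p-value is recorded so the branch taken
is always auditable.  Correlations use Pearson's r for two interval-scale
variables and Spearman's rho when either variable is ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupSample:
    """Per-group observations of one metric."""

    metric: str
    groups: dict[str, np.ndarray]

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float)
                       for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for name, vals in self.groups.items():
            if vals.size < 3:
                raise ValueError(f"group {name!r} has fewer than 3 values")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} contains non-finite values")

    @property
    def sizes(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.groups.items()}

    @property
    def n_total(self) -> int:
        return sum(v.size for v in self.groups.values())

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.groups.values()))


@dataclass
class GroupComparisonResult:
    metric: str
    test: str  # "anova" | "welch-anova" | "kruskal-wallis"
    statistic: float
    p_value: float
    effect_size: float
    effect_size_label: str  # "eta2" | "epsilon2"
    assumptions: dict[str, float]
    pairwise: pd.DataFrame  # columns: group_a, group_b, test, p_raw, p_holm
    sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def chi_square_equinumerosity(sizes) -> tuple[float, float]:
    """Chi-square goodness of fit of group sizes against equal counts."""
    sizes = np.asarray(list(sizes), dtype=float)
    stat, p = scipy.stats.chisquare(sizes)
    return float(stat), float(p)


#: Total sample size at or below which the Kruskal-Wallis p-value is
#: computed by exact enumeration of the permutation distribution.
KW_EXACT_MAX_N = 12


def _kw_h(rank_sums: np.ndarray, sizes: np.ndarray, n: int,
          tie_term: float) -> np.ndarray:
    h = 12.0 / (n * (n + 1)) * (rank_sums ** 2 / sizes).sum(axis=-1) \
        - 3.0 * (n + 1)
    return h / tie_term


def kruskal_wallis(sample: GroupSample) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H.

    The p-value comes from the chi-square (df = k-1) approximation, except
    for small pooled samples (n <= 12) where the exact permutation
    distribution of H is enumerated instead — the asymptotic tail is
    unreliable there.
    """
    pooled = sample.pooled()
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; Kruskal-Wallis undefined")
    H, p = scipy.stats.kruskal(*sample.groups.values())
    n = sample.n_total
    if n <= KW_EXACT_MAX_N:
        from itertools import combinations

        sizes = np.array(list(sample.sizes.values()))
        ranks = scipy.stats.rankdata(pooled)
        ties = np.unique(pooled, return_counts=True)[1]
        tie_term = 1.0 - (ties ** 3 - ties).sum() / (n ** 3 - n)
        idx = set(range(n))
        count = total = 0
        for g1 in combinations(range(n), int(sizes[0])):
            rest = sorted(idx - set(g1))
            for g2 in combinations(rest, int(sizes[1])):
                g3 = sorted(set(rest) - set(g2))
                rs = np.array([ranks[list(g1)].sum(), ranks[list(g2)].sum(),
                               ranks[g3].sum()])
                h = _kw_h(rs, sizes, n, tie_term)
                total += 1
                if h >= H - 1e-12:
                    count += 1
        p = count / total
    return float(H), float(p)


def epsilon_squared(H: float, n: int) -> float:
    """Rank-based effect size for Kruskal-Wallis: H / ((n^2-1)/(n+1))."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(H / ((n ** 2 - 1) / (n + 1)))


def eta_squared(sample: GroupSample) -> float:
    """ANOVA effect size SS_between / SS_total."""
    pooled = sample.pooled()
    grand = pooled.mean()
    ss_total = float(((pooled - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total sum of squares")
    ss_between = float(sum(
        g.size * (g.mean() - grand) ** 2 for g in sample.groups.values()
    ))
    return ss_between / ss_total


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (monotone, never below the raw p)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="holm")[1]


def posthoc_pairwise(sample: GroupSample, family: str) -> pd.DataFrame:
    """All unpaired pairwise tests of one family, Holm-adjusted.

    ``family``: ``"wilcoxon"`` (rank-sum / Mann-Whitney; exact for small
    tie-free samples, normal approximation with tie and continuity
    correction otherwise), ``"t"`` (pooled-variance), or ``"welch"``.
    """
    rows = []
    for a, b in combinations(sample.groups, 2):
        x, y = sample.groups[a], sample.groups[b]
        if family == "wilcoxon":
            stat, p = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="auto")
        elif family == "t":
            stat, p = scipy.stats.ttest_ind(x, y, equal_var=True)
        elif family == "welch":
            stat, p = scipy.stats.ttest_ind(x, y, equal_var=False)
        else:
            raise ValueError(f"unknown test family {family!r}")
        rows.append({"group_a": a, "group_b": b, "test": family,
                     "statistic": float(stat), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    return table


def welch_anova(sample: GroupSample) -> tuple[float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA (F, p)."""
    import pingouin

    frames = [pd.DataFrame({"y": v, "g": k}) for k, v in sample.groups.items()]
    aov = pingouin.welch_anova(
        data=pd.concat(frames, ignore_index=True), dv="y", between="g")
    return float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])


# ---------------------------------------------------------------------------
# The decision tree
# ---------------------------------------------------------------------------

def select_and_run_omnibus(sample: GroupSample,
                           alpha: float = 0.05) -> GroupComparisonResult:
    """Run the full assumption-gated three-group comparison."""
    pooled = sample.pooled()
    if np.ptp(pooled) == 0:
        raise ValueError(f"metric {sample.metric!r} is constant in all groups")

    assumptions: dict[str, float] = {}
    normal = True
    for name, vals in sample.groups.items():
        if np.ptp(vals) == 0:
            p_sw = 0.0  # a constant group is maximally non-normal
        else:
            p_sw = float(scipy.stats.shapiro(vals).pvalue)
        assumptions[f"shapiro_{name}"] = p_sw
        normal &= p_sw >= alpha
    chi_stat, chi_p = chi_square_equinumerosity(sample.sizes.values())
    assumptions["equinumerosity_chi2"] = chi_stat
    assumptions["equinumerosity_p"] = chi_p
    equinumerous = chi_p >= alpha

    if not (normal and equinumerous):
        H, p = kruskal_wallis(sample)
        return GroupComparisonResult(
            metric=sample.metric, test="kruskal-wallis", statistic=H,
            p_value=p, effect_size=epsilon_squared(H, sample.n_total),
            effect_size_label="epsilon2", assumptions=assumptions,
            pairwise=posthoc_pairwise(sample, "wilcoxon"),
            sizes=sample.sizes,
        )

    lev_stat, lev_p = scipy.stats.levene(
        *sample.groups.values(), center="mean")
    assumptions["levene_p"] = float(lev_p)
    if lev_p >= alpha:
        F, p = scipy.stats.f_oneway(*sample.groups.values())
        test, family = "anova", "t"
    else:
        F, p = welch_anova(sample)
        test, family = "welch-anova", "welch"
    return GroupComparisonResult(
        metric=sample.metric, test=test, statistic=float(F),
        p_value=float(p), effect_size=eta_squared(sample),
        effect_size_label="eta2", assumptions=assumptions,
        pairwise=posthoc_pairwise(sample, family),
        sizes=sample.sizes,
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlate(x, y, scales: str = "interval-interval",
              names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson (interval-interval) or Spearman (ordinal-any) correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if scales == "interval-interval":
        r, p = scipy.stats.pearsonr(x, y)
        method = "pearson"
    elif scales == "ordinal-any":
        r, p = scipy.stats.spearmanr(x, y)
        method = "spearman"
    else:
        raise ValueError(f"unknown scales {scales!r}")
    return CorrelationResult(pair=names, method=method, r=float(r),
                             p_value=float(p), n=int(x.size))
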