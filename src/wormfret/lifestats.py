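"""Life-history statistics: one-way ANOVA, Dunnett's many-to-one test,
percent-alive survival curves and the Mantel-Cox log-rank test.

These are implemented from first principles (sums of squares, the
correlated maximum-|t| null for Dunnett via Monte Carlo, the
hypergeometric observed-vs-expected tabulation for the log-rank test)
because the multiple-comparison structure and tie handling are the point
of the analysis; established libraries serve as independent cross-checks
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class LifeStatsError(ValueError):
    """Raised for statistically ill-posed inputs."""


@dataclass(frozen=True)
class AnovaResult:
    trait: str
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    ms_between: float
    ms_within: float
    ss_between: float
    ss_within: float
    ss_total: float


@dataclass(frozen=True)
class DunnettComparison:
    strain: str
    mean_difference: float
    t_statistic: float
    p_adjusted: float


@dataclass(frozen=True)
class DunnettResult:
    trait: str
    control: str
    comparisons: tuple[DunnettComparison, ...]
    df: int
    n_mc: int


@dataclass(frozen=True)
class SurvivalCurve:
    """Raw percent-alive trajectory on the daily monitoring grid.

    ``pct_alive[d]`` is the percentage of worms still under observation
    on day ``days[d]`` that are alive; it starts at 100 and, without
    censoring, is simply 100 x (fraction with lifespan > day).  Censored
    worms count as alive through their last observed day and leave both
    numerator and denominator thereafter (NaN once nobody remains).
    """

    strain: str
    days: np.ndarray
    pct_alive: np.ndarray


@dataclass(frozen=True)
class LogrankResult:
    strain_a: str
    strain_b: str
    chi_square: float
    df: int
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def _trait_groups(records: pd.DataFrame, trait: str) -> dict[str, np.ndarray]:
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise LifeStatsError(f"no observations for trait {trait!r}")
    return {
        strain: grp["value"].to_numpy(dtype=float)
        for strain, grp in sub.groupby("strain", sort=True)
    }


def one_way_anova(records: pd.DataFrame, trait: str) -> AnovaResult:
    """One-way fixed-effects ANOVA of one trait across strains.

    ``records`` is a long-format table with columns ``strain``, ``trait``
    and ``value``.  Requires at least two groups, each with at least two
    observations.
    """
    groups = _trait_groups(records, trait)
    if len(groups) < 2:
        raise LifeStatsError(f"need >= 2 strains for ANOVA; got {len(groups)}")
    for strain, values in groups.items():
        if len(values) < 2:
            raise LifeStatsError(
                f"strain {strain!r} has {len(values)} observation(s); need >= 2"
            )
    all_values = np.concatenate(list(groups.values()))
    grand_mean = all_values.mean()
    ss_between = float(
        sum(len(v) * (v.mean() - grand_mean) ** 2 for v in groups.values())
    )
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    ss_total = float(((all_values - grand_mean) ** 2).sum())
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        trait=trait,
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        group_means={s: float(v.mean()) for s, v in groups.items()},
        ms_between=ms_between,
        ms_within=ms_within,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_total,
    )


def _dunnett_null_maxabs(
    n_control: int,
    n_treatments: np.ndarray,
    df: int,
    n_mc: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the global null.

    Group means are simulated as independent normals with variance 1/n_j
    and the pooled variance as chi-square(df)/df, reproducing the
    correlated multivariate-t distribution of the many-to-one statistics
    (all comparisons share the control mean and the variance estimate).
    """
    z0 = rng.normal(0.0, 1.0 / np.sqrt(n_control), size=n_mc)
    zt = rng.normal(
        0.0, 1.0, size=(n_mc, len(n_treatments))
    ) / np.sqrt(n_treatments)
    s2 = rng.chisquare(df, size=n_mc) / df
    denom = np.sqrt(s2[:, None] * (1.0 / n_treatments + 1.0 / n_control))
    t_null = (zt - z0[:, None]) / denom
    return np.abs(t_null).max(axis=1)


def dunnett_test(
    records: pd.DataFrame,
    trait: str,
    control: str = "N2",
    n_mc: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Dunnett's many-to-one comparisons of each strain against a control.

    Two-sided statistics use the variance pooled over all groups
    (control included).  Familywise-adjusted p-values are Monte-Carlo
    tail probabilities of the maximum |T| over the correlated
    multivariate-t null, with ``n_mc`` draws; they are accurate to about
    three decimal places at the default ``n_mc`` and are monotone in |t|
    by construction.
    """
    groups = _trait_groups(records, trait)
    if control not in groups:
        raise LifeStatsError(f"control strain {control!r} not present in data")
    treatments = {s: v for s, v in groups.items() if s != control}
    if not treatments:
        raise LifeStatsError("need at least one treatment group")
    for strain, values in groups.items():
        if len(values) < 2:
            raise LifeStatsError(
                f"strain {strain!r} has {len(values)} observation(s); need >= 2"
            )
    ctrl = groups[control]
    n_total = sum(len(v) for v in groups.values())
    df = n_total - len(groups)
    s2_pooled = (
        sum((len(v) - 1) * v.var(ddof=1) for v in groups.values()) / df
    )
    if s2_pooled <= 0:
        raise LifeStatsError("pooled within-group variance is zero")

    names = sorted(treatments)
    n_treat = np.array([len(treatments[s]) for s in names], dtype=float)
    diffs = np.array([treatments[s].mean() - ctrl.mean() for s in names])
    t_obs = diffs / np.sqrt(s2_pooled * (1.0 / n_treat + 1.0 / len(ctrl)))

    rng = np.random.default_rng(seed)
    maxabs = _dunnett_null_maxabs(len(ctrl), n_treat, df, n_mc, rng)
    # add-one correction keeps p in (0, 1] and stabilizes the extreme tail
    p_adj = (1.0 + np.sum(maxabs[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (
        n_mc + 1.0
    )

    comparisons = tuple(
        DunnettComparison(
            strain=name,
            mean_difference=float(d),
            t_statistic=float(t),
            p_adjusted=float(p),
        )
        for name, d, t, p in zip(names, diffs, t_obs, p_adj)
    )
    return DunnettResult(
        trait=trait, control=control, comparisons=comparisons, df=df, n_mc=n_mc
    )


def percent_alive_curve(records: pd.DataFrame, strain: str) -> SurvivalCurve:
    """Raw percentage-left-alive curve on the daily grid for one strain.

    ``records`` has columns ``strain``, ``lifespan_days`` and
    ``censored``.  This is the survival display used for lifespan
    figures; it coincides with Kaplan-Meier when there is no censoring.
    """
    sub = records[records["strain"] == strain]
    if sub.empty:
        raise LifeStatsError(f"no survival records for strain {strain!r}")
    days_of_event = sub["lifespan_days"].to_numpy(dtype=int)
    censored = sub["censored"].to_numpy(dtype=bool)
    if (days_of_event < 1).any():
        raise LifeStatsError("lifespan_days must be >= 1")
    max_day = int(days_of_event.max())
    days = np.arange(0, max_day + 1)
    pct = np.empty(len(days), dtype=float)
    for i, d in enumerate(days):
        # censored worms count as alive through their last day, then drop
        # out of both numerator and denominator
        in_followup = (~censored) | (days_of_event >= d)
        denom = int(in_followup.sum())
        if denom == 0:
            pct[i] = np.nan
            continue
        alive = ((~censored) & (days_of_event > d)) | (censored & (days_of_event >= d))
        pct[i] = 100.0 * alive.sum() / denom
    return SurvivalCurve(strain=strain, days=days, pct_alive=pct)


def kaplan_meier_curve(records: pd.DataFrame, strain: str) -> pd.DataFrame:
    """Kaplan-Meier survival estimate (companion to the raw curve).

    Returns a frame with columns ``day`` and ``survival`` (fraction).
    """
    from lifelines import KaplanMeierFitter

    sub = records[records["strain"] == strain]
    if sub.empty:
        raise LifeStatsError(f"no survival records for strain {strain!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["lifespan_days"], event_observed=~sub["censored"].astype(bool))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"day": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(a: pd.DataFrame, b: pd.DataFrame) -> LogrankResult:
    """Mantel-Cox log-rank test between two survival tables.

    At each distinct death day, the deaths observed in group A are
    compared with their expectation under the hypergeometric model given
    the margins, with the usual tie-corrected variance
    ``d (n1/n) (1 - n1/n) (n - d) / (n - 1)``; deaths recorded on the
    same monitoring day are treated as simultaneous.  The statistic
    ``(O - E)^2 / V`` is chi-square with 1 degree of freedom.
    """
    names = []
    for df_ in (a, b):
        u = df_["strain"].unique()
        names.append(u[0] if len(u) == 1 else "group")
    ta = a["lifespan_days"].to_numpy(dtype=float)
    tb = b["lifespan_days"].to_numpy(dtype=float)
    ea = ~a["censored"].to_numpy(dtype=bool)
    eb = ~b["censored"].to_numpy(dtype=bool)
    if ea.sum() + eb.sum() == 0:
        raise LifeStatsError("no death events in either group")

    event_days = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var_sum = 0.0
    obs_a = 0.0
    exp_a = 0.0
    for day in event_days:
        n1 = float((ta >= day).sum())
        n2 = float((tb >= day).sum())
        n = n1 + n2
        d1 = float(((ta == day) & ea).sum())
        d2 = float(((tb == day) & eb).sum())
        d = d1 + d2
        if n <= 1 or d == 0:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
        o_minus_e += d1 - e1
        var_sum += v
        obs_a += d1
        exp_a += e1
    total_deaths = float(ea.sum() + eb.sum())
    if var_sum == 0:
        chi2 = 0.0
    else:
        chi2 = o_minus_e**2 / var_sum
    p = float(stats.chi2.sf(chi2, 1))
    return LogrankResult(
        strain_a=names[0],
        strain_b=names[1],
        chi_square=float(chi2),
        df=1,
        p_value=p,
        observed=(obs_a, total_deaths - obs_a),
        expected=(exp_a, total_deaths - exp_a),
    )
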