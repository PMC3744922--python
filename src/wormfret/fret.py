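"""Sensitized-emission FRET calibration and the corrected net FRET statistic.

The FRET channel (donor excitation / acceptor emission) of a plate well
mixes three contributions: donor emission tailing into the acceptor band,
directly excited acceptor emission, and genuine sensitized emission from
energy transfer inside aggregates.  Single-fluorophore control strains
measure the two bleed-through fractions, and the aggregation statistic is

    corrected net FRET = fret_total - (alpha * cfp + beta * yfp)

with fixed defaults alpha = 0.45 and beta = 0.07 measured from CFP-only
and YFP-only lines.  Aging comparisons are expressed as percentage change
of the group mean relative to the L4 larval baseline, which cancels any
common rescaling of worm numbers between experiments, with an unpaired
two-sample t-test on the per-well values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import DEFAULT_CROSSOVER, CrossoverCoefficients
from .simulate import WellReading

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when cross-over coefficients cannot be estimated."""


class FretStatisticsError(ValueError):
    """Raised when a group comparison is statistically ill-posed."""


@dataclass(frozen=True)
class FretGroupSummary:
    """Per-group (strain x age) corrected net FRET summary.

    Values are in relative fluorescence units (RFU).  ``sem`` is the
    standard error of the mean over replicate wells (0 for a single well).
    """

    strain: str
    age: str
    n_wells: int
    mean: float
    sem: float
    per_well_values: tuple[float, ...]


@dataclass(frozen=True)
class AgingComparison:
    """Percentage change of a group mean relative to a baseline age.

    ``pct_change`` is 100 * (aged - baseline) / baseline on group means;
    ``t_statistic`` is the unpaired two-sample t (positive when the aged
    mean exceeds the baseline), ``df`` its degrees of freedom.
    """

    strain: str
    baseline_age: str
    aged_age: str
    pct_change: float
    t_statistic: float
    p_value: float
    df: float


def corrected_net_fret(
    well: WellReading, coeffs: CrossoverCoefficients = DEFAULT_CROSSOVER
) -> float:
    """Bleed-through-corrected FRET-channel signal of one well (RFU).

    May be negative on low-signal wells; negative values are retained so
    that group means stay unbiased.
    """
    for channel in ("cfp", "yfp", "fret_total"):
        v = getattr(well, channel)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{channel} must be finite and >= 0; got {v}")
    return well.fret_total - (coeffs.alpha * well.cfp + coeffs.beta * well.yfp)


def _ratio_of_sums(
    numerators: np.ndarray, denominators: np.ndarray, label: str
) -> tuple[float, float]:
    """Ratio-of-sums estimate with a delta-method standard error.

    Equivalent to least squares through the origin of numerator on
    denominator; low-signal wells are down-weighted relative to the mean
    of per-well ratios.
    """
    total = denominators.sum()
    if total <= 0:
        raise CalibrationError(f"{label}: control wells have zero total signal")
    ratio = float(numerators.sum() / total)
    n = len(denominators)
    resid = numerators - ratio * denominators
    se = float(np.sqrt(np.sum(resid**2) / (n - 1) / n) / denominators.mean())
    return ratio, se


def estimate_crossover(
    donor_only_wells: Sequence[WellReading],
    acceptor_only_wells: Sequence[WellReading],
) -> CrossoverCoefficients:
    """Estimate bleed-through fractions from single-fluorophore controls.

    ``alpha`` is the summed FRET-channel signal over the summed donor
    channel across CFP-only wells; ``beta`` likewise over the acceptor
    channel across YFP-only wells.  A donor-only well whose acceptor
    channel exceeds 10% of its FRET reading is flagged as a contaminated
    control (and symmetrically for acceptor-only wells).
    """
    if len(donor_only_wells) < 2 or len(acceptor_only_wells) < 2:
        raise CalibrationError(
            "need at least 2 donor-only and 2 acceptor-only control wells"
        )
    for w in donor_only_wells:
        if w.fret_total > 0 and w.yfp > 0.10 * w.fret_total:
            logger.warning(
                "contaminated donor-only control %s/%s rep %d: yfp=%.3g exceeds "
                "10%% of fret_total=%.3g",
                w.strain, w.age, w.replicate, w.yfp, w.fret_total,
            )
    for w in acceptor_only_wells:
        if w.fret_total > 0 and w.cfp > 0.10 * w.fret_total:
            logger.warning(
                "contaminated acceptor-only control %s/%s rep %d: cfp=%.3g exceeds "
                "10%% of fret_total=%.3g",
                w.strain, w.age, w.replicate, w.cfp, w.fret_total,
            )
    alpha, alpha_se = _ratio_of_sums(
        np.array([w.fret_total for w in donor_only_wells]),
        np.array([w.cfp for w in donor_only_wells]),
        "donor-only calibration",
    )
    beta, beta_se = _ratio_of_sums(
        np.array([w.fret_total for w in acceptor_only_wells]),
        np.array([w.yfp for w in acceptor_only_wells]),
        "acceptor-only calibration",
    )
    return CrossoverCoefficients(
        alpha=alpha, beta=beta, alpha_se=alpha_se, beta_se=beta_se
    )


def summarize_group(
    wells: Sequence[WellReading],
    coeffs: CrossoverCoefficients = DEFAULT_CROSSOVER,
) -> FretGroupSummary:
    """Corrected net FRET of one strain x age group of replicate wells."""
    if not wells:
        raise ValueError("no wells given")
    strains = {w.strain for w in wells}
    ages = {w.age for w in wells}
    if len(strains) != 1 or len(ages) != 1:
        raise ValueError(
            f"wells must share strain and age; got strains={sorted(strains)}, ages={sorted(ages)}"
        )
    values = tuple(corrected_net_fret(w, coeffs) for w in wells)
    arr = np.asarray(values)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return FretGroupSummary(
        strain=strains.pop(),
        age=ages.pop(),
        n_wells=len(values),
        mean=float(arr.mean()),
        sem=sem,
        per_well_values=values,
    )


def _compare_values(
    baseline: np.ndarray,
    aged: np.ndarray,
    strain: str,
    baseline_age: str,
    aged_age: str,
    welch: bool = False,
) -> AgingComparison:
    if len(baseline) < 2 or len(aged) < 2:
        raise FretStatisticsError(
            "need at least 2 wells per group for an unpaired t-test"
        )
    res = stats.ttest_ind(aged, baseline, equal_var=not welch)
    if welch:
        df = float(res.df)
    else:
        df = float(len(baseline) + len(aged) - 2)
    base_mean = baseline.mean()
    if base_mean <= 0:
        warnings.warn(
            f"{strain}: baseline ({baseline_age}) mean corrected signal is "
            f"{base_mean:.4g} <= 0; percentage change is undefined",
            RuntimeWarning,
            stacklevel=3,
        )
        pct = float("nan")
    else:
        pct = float(100.0 * (aged.mean() - base_mean) / base_mean)
    return AgingComparison(
        strain=strain,
        baseline_age=baseline_age,
        aged_age=aged_age,
        pct_change=pct,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
    )


def compare_ages(
    baseline: FretGroupSummary,
    aged: FretGroupSummary,
    welch: bool = False,
) -> AgingComparison:
    """Aging comparison of corrected net FRET relative to an L4-type baseline.

    Uses a pooled-variance two-sided unpaired t-test by default (Welch's
    correction behind the ``welch`` flag).  The percentage change of group
    means is exactly invariant to multiplying every channel of every well
    in both groups by a common constant, so it is robust to differences in
    total worm numbers between experiments.
    """
    if baseline.strain != aged.strain:
        raise ValueError(
            f"groups are different strains: {baseline.strain} vs {aged.strain}"
        )
    return _compare_values(
        np.asarray(baseline.per_well_values),
        np.asarray(aged.per_well_values),
        strain=baseline.strain,
        baseline_age=baseline.age,
        aged_age=aged.age,
        welch=welch,
    )


def yfp_expression_change(
    baseline_wells: Sequence[WellReading],
    aged_wells: Sequence[WellReading],
    welch: bool = False,
) -> AgingComparison:
    """Aging change in raw acceptor-channel signal (expression control arm).

    Applied to an acceptor-fusion reporter strain, this measures how much
    of an aging FRET increase is attributable to rising transgene
    expression rather than aggregation.
    """
    if not baseline_wells or not aged_wells:
        raise FretStatisticsError("both well groups must be non-empty")
    strains = {w.strain for w in baseline_wells} | {w.strain for w in aged_wells}
    if len(strains) != 1:
        raise ValueError(f"wells must share one strain; got {sorted(strains)}")
    return _compare_values(
        np.asarray([w.yfp for w in baseline_wells]),
        np.asarray([w.yfp for w in aged_wells]),
        strain=strains.pop(),
        baseline_age=baseline_wells[0].age,
        aged_age=aged_wells[0].age,
        welch=welch,
    )
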