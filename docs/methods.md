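# Methods

## The measurement model

A plate well containing `N` worms of one strain at one age is treated as a
bulk emitter. With per-worm donor output `X_D` (CFP, already including the
age-dependent expression factor), per-worm acceptor output `X_A` (YFP),
and a FRET yield `φ ∈ [0, 1]` — the fraction of donor output diverted into
sensitized acceptor emission — the expected channel readings are

```
E[cfp]        = N · X_D · (1 − φ)                      (ex 430 / em 486)
E[yfp]        = N · X_A                                 (ex 510 / em 530)
E[fret_total] = α·E[cfp] + β·E[yfp] + N · X_D · φ       (ex 430 / em 530)
```

with bleed-through fractions α (donor emission tailing) and β (direct
acceptor excitation). This is the minimal model whose expectations satisfy
the calibration identities used in practice: a CFP-only well gives
`fret_total = α · cfp` exactly, a YFP-only well `fret_total = β · yfp`,
and the corrected net FRET `fret_total − α·cfp − β·yfp` has expectation
`N · X_D · φ`, the sensitized-emission signal. Acceptor-to-donor-channel
cross-talk is set to zero (it is negligible for this filter set), donor
quenching and sensitized yield are deliberately collapsed into the single
φ because bulk fluorometry cannot separate them, and FRET's effect on
direct acceptor excitation is neglected at first order.

φ is nonzero only for the doubly transgenic SC+SV strain: a free
fluorophore (C, V, CV, C+V) or a single fusion (SC, SV, S+V) cannot place
a donor–acceptor pair inside one aggregate, so for every other strain the
corrected net FRET has expectation zero — a property the test suite checks
at large replicate counts.

### Noise

Each channel reading is multiplied by independent lognormal noise with
unit mean and coefficient of variation `channel_cv` (default 0.05), since
plate-reader fluorescence error grows with signal. Worm counts per well
scatter multiplicatively (CV `dispense_cv`, default 0.02) around a common
dilution target (default 1250 worms/well, the midpoint of the 1000–1500
range typical for this assay). The target is a single configuration value
rather than an independent draw per well because the assay protocol
dilutes the worm suspension to equalize numbers across the strains and
time points being compared; modelled this way, the simulated assay's
per-well corrected-FRET dispersion is 7–9% CV, consistent with the
precision implied by t-statistics above 10 at four replicate wells per
group in real data of this design. Since all channels are proportional to
`N`, percentage-change statistics are exactly invariant to a common
rescaling of worm numbers.

### Default trajectory

Only the ratio of the aggregation trajectory between ages is pinned by the
study conditions: expression grows 31% from L4 to day 6 (shared between
donor and acceptor fusions — the data cannot distinguish per-fluorophore
growth) and corrected net FRET grows 82%, so `φ(day6)/φ(L4) = 1.82/1.31 ≈
1.389`. The L4 level, φ = 0.5, sets the signal-to-background of the
simulated assay and was chosen once so that per-well dispersion matches
the observed assay precision (above); day 1 takes interpolated values.
φ is constrained non-decreasing in age.

## Calibration estimator

`estimate_crossover` uses the ratio of sums `α̂ = Σ fret / Σ cfp` over
donor-only wells (equivalently least squares through the origin), which
down-weights low-signal wells relative to averaging per-well ratios; the
alternative is a one-line swap. Standard errors come from the delta
method on the residuals `fret_i − α̂ · cfp_i`. With `n` calibration wells
the interval `α̂ ± 2·SE` behaves like a t-interval with `n − 1` degrees of
freedom: at n = 4 its coverage is ≈ 86% (the t₃ value), reaching ~91% at
n = 8 and ~94% at n = 24 — small panels should use t-quantiles rather
than ±2 SE. A donor-only control well whose acceptor channel exceeds 10%
of its FRET reading is logged as contaminated (and symmetrically).

The published constants α = 0.45, β = 0.07 are the packaged default
`CrossoverCoefficients`; re-estimation from control wells is optional per
run (`--crossover calibrate`).

## Aging comparisons

Group summaries are per-well corrected net FRET values, their mean and
SEM; negative per-well values are retained so group means stay unbiased.
`compare_ages` runs a two-sided unpaired t-test on per-well values —
pooled variance by default, matching the conventions of the assay's era;
Welch's form is available behind a flag — and reports
`100·(aged − baseline)/baseline` on group means, with a positive t for an
increase. When the baseline mean is ≤ 0 (a realistic outcome for
non-FRET-competent strains whose corrected signal is centred on zero) the
percentage change is reported as missing with a warning rather than an
exception, so pipeline runs over full panels survive. The same machinery
applied to the raw acceptor channel of an acceptor-fusion strain
(`yfp_expression_change`) is the expression-control arm.

## Life-history statistics

**ANOVA.** Standard one-way fixed-effects decomposition, computed from
explicit sums of squares (the `SS_total = SS_between + SS_within` identity
is property-tested) with p from the F distribution.

**Dunnett's test.** Many-to-one t-statistics use the variance pooled over
all groups including the control. Familywise-adjusted p-values are
Monte-Carlo tail probabilities of `max_i |T_i|` under the correlated
multivariate-t null, simulated directly (independent group means with
variance 1/n_j, shared χ²ν/ν variance estimate) with a fixed seed;
`n_mc = 100 000` draws give ≈3-decimal accuracy and the add-one correction
keeps p in (0, 1]. With one treatment the procedure reduces to the
ordinary pooled t-test; the test suite cross-checks multi-group cases
against an independent implementation and verifies familywise error
control by simulation. No correction is applied across traits — each
trait is tested separately by design.

**Survival.** The display statistic is the raw percentage left alive on
each day (starting at 100), not Kaplan–Meier; censored worms count as
alive through their last observed day and then leave numerator and
denominator. Without censoring the curve coincides with Kaplan–Meier
exactly (also tested); a Kaplan–Meier companion via lifelines is provided.
The Mantel-Cox log-rank test tabulates observed vs expected deaths at each
distinct death day under the hypergeometric model with the tie-corrected
variance `d·(n₁/n)·(1−n₁/n)·(n−d)/(n−1)`; all deaths recorded on the same
monitoring day are simultaneous, matching daily scoring. The statistic is
symmetric in group labels and invariant to shifting all lifespans by a
constant.

## Trait and survival generator

Per-worm trait values are normal truncated at zero with wild-type means
74 h development, 284.2 eggs, 195.8 pumps/min and 14.2 bends per 30-s
count interval (truncation is negligible at these means). Strains
expressing α-synuclein in any form get multiplicative effects ×0.82 on
pumping and ×0.50 on locomotion — the transgenes are expressed in
body-wall but not pharyngeal muscle, so feeding is hit far less than
motility — and no effect on development or brood size. Lifespans are a
normal discretized to whole days and floored at 1: wild-type mean 17 d at
20 °C (a typical value; the source curves do not print a mean, so this is
an invented, configurable baseline) with SD 3 d, −5 d for α-synuclein
strains, −1.5 d for marker-only strains (a real but usually
non-significant effect at typical sample sizes). No censoring is
generated; every worm is followed to death.

## What the generator does and does not emulate

It reproduces the design (replicate wells, dilution-equalized worm
numbers, the three-channel read, the measured time points L4/day1/day6)
and the first and second moments that drive the statistics. It does not
model spectra, photobleaching, per-molecule kinetics, plate position
effects, worm-stage mixtures from imperfect synchronization, or
non-normal trait distributions (real brood counts are left-skewed).
Passing tests therefore demonstrate that the analysis code recovers known
truth under the assumed error structure — not that the error structure is
a complete account of real plate data.

## Numerical and interface choices

Seeds are explicit arguments everywhere; dataset-level seeds are expanded
with `numpy.random.SeedSequence.spawn`, so runs are bit-reproducible.
Floats are written to CSV with 12 significant digits (round trips are
exact to < 1e-11 relative). Degenerate inputs fail loudly with named
errors: unknown strains/ages, groups of fewer than two wells or worms,
zero-signal calibration wells, a missing control strain, negative
fluorescence (with the offending CSV line number). Test problem sizes —
24-well calibrations, 64-well aging groups, 10 000-worm trait samples,
1000-replicate type-I-error simulations — were chosen so every sampling
check sits several standard errors inside its tolerance while the whole
suite runs in well under a minute.
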