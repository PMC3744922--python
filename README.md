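# wormfret

Quantifying in vivo α-synuclein aggregation in transgenic *Caenorhabditis
elegans* by sensitized-emission FRET in a plate reader, together with the
life-history statistics that accompany such a model (development, brood
size, pharyngeal pumping, locomotion, lifespan).

The package is aimed at worm labs running bulk fluorometry on strains that
co-express α-synuclein::CFP (SC) and α-synuclein::YFP (SV) fusions in
body-wall muscle. When both fusion proteins co-aggregate, donor (CFP) and
acceptor (YFP) come within Förster distance and donor excitation produces
acceptor-band emission. Because the FRET channel (ex 430 / em 530 nm) also
carries donor emission tailing and directly excited acceptor signal, the
aggregation statistic is the bleed-through-corrected

```
corrected net FRET = F_total − (α · F_CFP + β · F_YFP)
```

with α = 0.45 and β = 0.07 measured from CFP-only and YFP-only control
strains (the package can also re-estimate α, β from control wells by a
ratio-of-sums calibration with delta-method standard errors). Aging
comparisons are reported as percentage change of the group mean relative
to an L4 larval baseline — a statistic invariant to rescaling worm numbers
— with unpaired pooled-variance t-tests over replicate wells.

Life-history traits are analysed with one-way ANOVA followed by Dunnett's
many-to-one comparisons against wild-type N2 (adjusted p-values by
Monte-Carlo sampling of the correlated maximum-|t| null), and survival
with raw percent-alive curves on the daily monitoring grid plus the
Mantel-Cox log-rank test with tie-corrected hypergeometric variance.

Because the underlying per-well and per-worm data are not public, the
package ships a first-class synthetic-data generator (`wormfret.simulate`)
that emulates the study design — the full strain panel, ≥4 replicate
wells of ~1000–1500 worms, age-dependent expression and aggregation, and
the observed trait and lifespan effect sizes — so the whole pipeline is
testable end to end.

## Worked example

```python
from wormfret import (GeneratorConfig, simulate_plate, summarize_group,
                      compare_ages, yfp_expression_change)

config = GeneratorConfig()          # packaged study-condition defaults

l4   = simulate_plate(config, "SC+SV", "L4",   seed=21, replicates=8)
day6 = simulate_plate(config, "SC+SV", "day6", seed=22, replicates=8)
aging = compare_ages(summarize_group(l4), summarize_group(day6))

sv_l4   = simulate_plate(config, "SV", "L4",   seed=23, replicates=8)
sv_day6 = simulate_plate(config, "SV", "day6", seed=24, replicates=8)
expr = yfp_expression_change(sv_l4, sv_day6)

print(f"net FRET: {aging.pct_change:+.1f}%  (t = {aging.t_statistic:.2f})")
print(f"raw YFP:  {expr.pct_change:+.1f}%  (t = {expr.t_statistic:.2f})")
```

prints

```
net FRET: +79.4%  (t = 15.61)
raw YFP:  +33.9%  (t = 11.58)
```

The corrected net FRET of the double-fusion strain rises ~80% from L4 to
day 6 while reporter expression alone (raw acceptor channel of the SV
strain) rises only ~30%: the excess is the aggregation readout. The
`examples/` directory has one short script per capability (panel
simulation, cross-over calibration, aging FRET, trait ANOVA/Dunnett,
survival/log-rank).

A `wormfret` command-line tool wraps the same stages for shell use:

```sh
wormfret run-all --seed 1 --out-dir out/       # simulate + analyse everything
wormfret calibrate --plate out/plate_readings.csv --out-dir out/
```

Every run writes plain CSV outputs and a YAML manifest recording the
configuration, seed and input checksums.

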