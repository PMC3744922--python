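"""Survival analysis: percent-alive curves and the Mantel-Cox log-rank test.

Simulates lifespans for wild type, a marker-only strain and the
alpha-synuclein double-fusion strain, draws the raw percent-alive curves on
the daily monitoring grid, and tests each strain against N2.
"""

import pandas as pd

from wormfret import (
    GeneratorConfig,
    logrank_test,
    percent_alive_curve,
    simulate_survival,
    survival_to_frame,
)

config = GeneratorConfig()
records = pd.concat(
    [
        survival_to_frame(simulate_survival(config, strain, 60, seed=200 + i))
        for i, strain in enumerate(("N2", "CV", "SC+SV"))
    ],
    ignore_index=True,
)

for strain in ("N2", "CV", "SC+SV"):
    curve = percent_alive_curve(records, strain)
    median_day = curve.days[(curve.pct_alive < 50).argmax()]
    mean_days = records.loc[records.strain == strain, "lifespan_days"].mean()
    print(f"{strain:6s} mean lifespan {mean_days:5.2f} d, median {median_day} d")

n2 = records[records.strain == "N2"]
for strain in ("CV", "SC+SV"):
    res = logrank_test(n2, records[records.strain == strain])
    print(f"log-rank N2 vs {strain:6s} chi2 = {res.chi_square:6.2f}, p = {res.p_value:.3g}")

print(
    "\nMarker expression alone costs ~1.5 days (often not significant at this\n"
    "sample size); alpha-synuclein overexpression shortens life by ~5 days,\n"
    "which the log-rank test flags decisively."
)
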