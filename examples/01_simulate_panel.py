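"""Simulate the full transgenic strain panel and write the three input tables.

Generates plate-reader wells (CFP-only, acceptor-fusion and double-fusion
strains at L4 and day 6), per-worm life-history traits and survival records
under the packaged default study conditions, and prints a preview of each.
"""

from pathlib import Path

from wormfret import GeneratorConfig, simulate_dataset
from wormfret.io import write_csv

out = Path("example_out")
config = GeneratorConfig()
tables = simulate_dataset(config, seed=1)

for name, df in tables.items():
    write_csv(df, out / f"{name}.csv")
    print(f"== {name} ({len(df)} rows) ==")
    print(df.head(4).to_string(index=False))
    print()

print(
    "plate_readings holds one row per 96-well plate well: three fluorescence\n"
    "channels (cfp, yfp, fret_total) for ~1250 worms per well; traits and\n"
    "survival hold one row per individually scored worm."
)
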