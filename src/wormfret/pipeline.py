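"""End-to-end workflow binding simulation, FRET analysis and life-history
statistics, with a run manifest for reproducibility.

Stages write plain CSV/YAML outputs into an output directory:

* ``simulate``  -> plate_readings.csv, traits.csv, survival.csv
* ``calibrate`` -> crossover.yaml (alpha, beta, SEs, well counts)
* ``fret``      -> fret_summary.csv, aging_comparisons.csv
* ``traits``    -> anova.csv, dunnett.csv
* ``survival``  -> curves.csv, logrank.csv
* ``run-all``   -> all of the above plus manifest.yaml
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .config import (
    DEFAULT_CROSSOVER,
    TRAITS,
    ConfigError,
    CrossoverCoefficients,
    GeneratorConfig,
)
from .fret import compare_ages, estimate_crossover, summarize_group, yfp_expression_change
from .lifestats import (
    dunnett_test,
    logrank_test,
    one_way_anova,
    percent_alive_curve,
)
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    out_dir: Path
    plate_csv: Path | None = None
    traits_csv: Path | None = None
    survival_csv: Path | None = None
    #: "fixed" uses the packaged default constants; "calibrate" re-estimates
    #: alpha/beta from the control strains found in the plate table
    crossover_source: str = "fixed"
    donor_control: str = "C"
    acceptor_control: str = "SV"
    control_strain: str = "N2"
    baseline_age: str = "L4"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.crossover_source not in ("fixed", "calibrate"):
            raise ConfigError(
                f"crossover_source must be 'fixed' or 'calibrate'; got {self.crossover_source!r}"
            )


def simulate_stage(config: RunConfig) -> dict[str, Path]:
    """Generate the synthetic dataset and write the three input tables."""
    tables = simulate_dataset(config.generator, seed=config.seed)
    out = Path(config.out_dir)
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        io.write_csv(df, path)
        paths[name] = path
        logger.info("simulate: wrote %s (%d rows)", path, len(df))
    config.plate_csv = paths["plate_readings"]
    config.traits_csv = paths["traits"]
    config.survival_csv = paths["survival"]
    return paths


def calibrate_stage(config: RunConfig) -> CrossoverCoefficients:
    """Estimate cross-over coefficients from single-fluorophore controls."""
    plate = io.read_plate_csv(config.plate_csv)
    wells = io.wells_from_frame(plate)
    donor = [w for w in wells if w.strain == config.donor_control]
    acceptor = [w for w in wells if w.strain == config.acceptor_control]
    coeffs = estimate_crossover(donor, acceptor)
    out = Path(config.out_dir) / "crossover.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "alpha": coeffs.alpha,
                "beta": coeffs.beta,
                "alpha_se": coeffs.alpha_se,
                "beta_se": coeffs.beta_se,
                "n_donor_wells": len(donor),
                "n_acceptor_wells": len(acceptor),
            },
            fh,
            sort_keys=False,
        )
    logger.info(
        "calibrate: alpha=%.4f (SE %.4f, %d wells), beta=%.4f (SE %.4f, %d wells)",
        coeffs.alpha, coeffs.alpha_se, len(donor),
        coeffs.beta, coeffs.beta_se, len(acceptor),
    )
    return coeffs


def fret_stage(
    config: RunConfig, coeffs: CrossoverCoefficients | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group corrected net FRET summaries and aging comparisons."""
    if coeffs is None:
        coeffs = DEFAULT_CROSSOVER
    plate = io.read_plate_csv(config.plate_csv)
    wells = io.wells_from_frame(plate)

    summaries = {}
    for (strain, age), _ in plate.groupby(["strain", "age"], sort=True):
        group = [w for w in wells if w.strain == strain and w.age == age]
        summaries[(strain, age)] = summarize_group(group, coeffs)
    summary_df = pd.DataFrame(
        {
            "strain": [k[0] for k in summaries],
            "age": [k[1] for k in summaries],
            "n_wells": [s.n_wells for s in summaries.values()],
            "mean_corrected_net_fret": [s.mean for s in summaries.values()],
            "sem": [s.sem for s in summaries.values()],
        }
    )

    rows = []
    baseline_age = config.baseline_age
    for strain in sorted({k[0] for k in summaries}):
        ages = [a for (s, a) in summaries if s == strain and a != baseline_age]
        if (strain, baseline_age) not in summaries:
            logger.warning("fret: %s has no %s baseline group", strain, baseline_age)
            continue
        for aged in sorted(ages):
            cmp_ = compare_ages(summaries[(strain, baseline_age)], summaries[(strain, aged)])
            rows.append(
                {
                    "strain": strain,
                    "baseline_age": baseline_age,
                    "aged_age": aged,
                    "measure": "corrected_net_fret",
                    "pct_change": cmp_.pct_change,
                    "t_statistic": cmp_.t_statistic,
                    "df": cmp_.df,
                    "p_value": cmp_.p_value,
                }
            )
            # expression-control arm: raw acceptor channel of YFP-bearing strains
            base_wells = [w for w in wells if w.strain == strain and w.age == baseline_age]
            aged_wells = [w for w in wells if w.strain == strain and w.age == aged]
            if all(w.yfp > 0 for w in base_wells + aged_wells):
                expr = yfp_expression_change(base_wells, aged_wells)
                rows.append(
                    {
                        "strain": strain,
                        "baseline_age": baseline_age,
                        "aged_age": aged,
                        "measure": "raw_yfp",
                        "pct_change": expr.pct_change,
                        "t_statistic": expr.t_statistic,
                        "df": expr.df,
                        "p_value": expr.p_value,
                    }
                )
    aging_df = pd.DataFrame(rows)
    out = Path(config.out_dir)
    io.write_csv(summary_df, out / "fret_summary.csv")
    io.write_csv(aging_df, out / "aging_comparisons.csv")
    logger.info("fret: %d groups, %d aging comparisons", len(summary_df), len(aging_df))
    return summary_df, aging_df


def traits_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA plus Dunnett's test against the control strain per trait."""
    records = io.read_traits_csv(config.traits_csv)
    rng = np.random.default_rng(config.seed)
    anova_rows, dunnett_rows = [], []
    for trait in TRAITS:
        if not (records["trait"] == trait).any():
            continue
        res = one_way_anova(records, trait)
        anova_rows.append(
            {
                "trait": trait,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p_value": res.p_value,
                "ms_between": res.ms_between,
                "ms_within": res.ms_within,
            }
        )
        dres = dunnett_test(
            records,
            trait,
            control=config.control_strain,
            seed=int(rng.integers(2**31)),
        )
        for cmp_ in dres.comparisons:
            dunnett_rows.append(
                {
                    "trait": trait,
                    "control": dres.control,
                    "strain": cmp_.strain,
                    "mean_difference": cmp_.mean_difference,
                    "t_statistic": cmp_.t_statistic,
                    "p_adjusted": cmp_.p_adjusted,
                }
            )
        logger.info(
            "traits: %s F=%.3f (df %d,%d) p=%.3g",
            trait, res.F, res.df_between, res.df_within, res.p_value,
        )
    anova_df = pd.DataFrame(anova_rows)
    dunnett_df = pd.DataFrame(dunnett_rows)
    out = Path(config.out_dir)
    io.write_csv(anova_df, out / "anova.csv")
    io.write_csv(dunnett_df, out / "dunnett.csv")
    return anova_df, dunnett_df


def survival_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-alive curves and pairwise log-rank tests against the control."""
    records = io.read_survival_csv(config.survival_csv)
    strains = sorted(records["strain"].unique())
    if config.control_strain not in strains:
        raise ConfigError(
            f"control strain {config.control_strain!r} absent from survival table"
        )
    curve_rows = []
    for strain in strains:
        curve = percent_alive_curve(records, strain)
        for day, pct in zip(curve.days, curve.pct_alive):
            curve_rows.append({"strain": strain, "day": int(day), "pct_alive": pct})
    logrank_rows = []
    ctrl = records[records["strain"] == config.control_strain]
    for strain in strains:
        if strain == config.control_strain:
            continue
        res = logrank_test(ctrl, records[records["strain"] == strain])
        logrank_rows.append(
            {
                "control": config.control_strain,
                "strain": strain,
                "chi_square": res.chi_square,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
        logger.info(
            "survival: %s vs %s chi2=%.3f p=%.3g",
            config.control_strain, strain, res.chi_square, res.p_value,
        )
    curves_df = pd.DataFrame(curve_rows)
    logrank_df = pd.DataFrame(logrank_rows)
    out = Path(config.out_dir)
    io.write_csv(curves_df, out / "curves.csv")
    io.write_csv(logrank_df, out / "logrank.csv")
    return curves_df, logrank_df


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage in sequence and write a manifest.

    When no input tables are given, the synthetic generator produces them
    first.  Outputs are deterministic given the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.plate_csv is None:
        simulate_stage(config)
    for name in ("plate_csv", "traits_csv", "survival_csv"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise ConfigError(f"{name} does not exist: {path}")

    coeffs = None
    if config.crossover_source == "calibrate":
        coeffs = calibrate_stage(config)
    fret_stage(config, coeffs)
    traits_stage(config)
    survival_stage(config)

    cfg_dict = {
        "crossover_source": config.crossover_source,
        "control_strain": config.control_strain,
        "baseline_age": config.baseline_age,
        "generator": config.generator.to_dict(),
    }
    io.write_manifest(
        out / "manifest.yaml",
        config=cfg_dict,
        seed=config.seed,
        inputs={
            "plate_readings": config.plate_csv,
            "traits": config.traits_csv,
            "survival": config.survival_csv,
        },
    )
    produced = {
        p.name: p
        for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.yaml"))
    }
    return produced
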