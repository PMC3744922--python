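"""Synthetic plate-reader and life-history data generation.

The bulk fluorescence model treats a well as ``n_worms`` identical
emitters.  With per-worm donor output ``X_D`` (already including the
age-dependent expression factor), acceptor output ``X_A``, FRET yield
``phi`` (zero unless both fluorophores are synuclein fusions) and
bleed-through fractions ``alpha``, ``beta``, the expected channel
readings for a well of ``N`` worms are::

    E[cfp]        = N * X_D * (1 - phi)            # quenched donor
    E[yfp]        = N * X_A
    E[fret_total] = alpha * E[cfp] + beta * E[yfp] + N * X_D * phi

i.e. the FRET channel carries donor and acceptor bleed-through plus the
sensitized emission, which is the donor output diverted by FRET.  Each
channel reading is multiplied by independent lognormal noise with unit
mean and the configured coefficient of variation, mimicking plate-reader
measurement error that grows with signal.  Worm counts per well scatter
around a common dilution target, reflecting dispensing of a continuously
stirred suspension diluted to equalize worm numbers across the groups
being compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TRAITS, ConfigError, GeneratorConfig
from .strains import StrainSpec


@dataclass(frozen=True)
class WellReading:
    """One plate well's three-channel fluorescence measurement.

    ``cfp`` is read at ex 430/em 486 nm, ``yfp`` at ex 510/em 530 nm and
    ``fret_total`` at ex 430/em 530 nm (donor excitation, acceptor
    emission).  ``n_worms`` may be None when the count was not recorded.
    """

    strain: str
    age: str
    replicate: int
    cfp: float
    yfp: float
    fret_total: float
    n_worms: int | None = None

    def __post_init__(self) -> None:
        for channel in ("cfp", "yfp", "fret_total"):
            v = getattr(self, channel)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.strain}/{self.age} rep {self.replicate}: "
                    f"{channel} must be finite and >= 0; got {v}"
                )
        if self.n_worms is not None and self.n_worms <= 0:
            raise ValueError("n_worms must be positive when recorded")


@dataclass(frozen=True)
class TraitRecord:
    worm_id: str
    strain: str
    trait: str
    value: float


@dataclass(frozen=True)
class SurvivalRecord:
    worm_id: str
    strain: str
    lifespan_days: int
    censored: bool = False


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def simulate_plate(
    config: GeneratorConfig,
    strain: str | StrainSpec,
    age: str,
    seed: int,
    replicates: int | None = None,
) -> list[WellReading]:
    """Simulate one strain x age group of replicate plate wells.

    Returns ``config.replicates`` wells (or ``replicates`` when given).
    Raises :class:`~wormfret.config.ConfigError` for an unknown strain or
    age label.
    """
    spec = config.strain(strain)
    n_rep = config.replicates if replicates is None else int(replicates)
    if n_rep < 1:
        raise ValueError("replicates must be >= 1")
    x_d = config.donor_output(spec, age)
    x_a = config.acceptor_output(spec, age)
    phi = config.phi(spec, age)
    if not spec.fret_competent:
        # still validate the age label for non-competent strains
        config._growth(age)
    alpha = config.crossover_true.alpha
    beta = config.crossover_true.beta

    rng = np.random.default_rng(seed)
    n_worms = np.maximum(
        1,
        np.rint(
            config.worms_per_well_target
            * _lognormal_factors(rng, config.dispense_cv, n_rep)
        ).astype(int),
    )
    eps = _lognormal_factors(rng, config.channel_cv, (n_rep, 3))

    wells = []
    for i in range(n_rep):
        n = float(n_worms[i])
        mean_cfp = n * x_d * (1.0 - phi)
        mean_yfp = n * x_a
        mean_fret = alpha * mean_cfp + beta * mean_yfp + n * x_d * phi
        wells.append(
            WellReading(
                strain=spec.name,
                age=age,
                replicate=i + 1,
                n_worms=int(n_worms[i]),
                cfp=mean_cfp * eps[i, 0],
                yfp=mean_yfp * eps[i, 1],
                fret_total=mean_fret * eps[i, 2],
            )
        )
    return wells


def simulate_traits(
    config: GeneratorConfig,
    strain: str | StrainSpec,
    n_worms: int,
    seed: int,
    traits: tuple[str, ...] = TRAITS,
) -> list[TraitRecord]:
    """Simulate per-worm life-history trait measurements.

    Each trait value is drawn from a normal truncated at zero with the
    strain's mean (wild-type mean times the strain's effect multiplier)
    and the wild-type standard deviation.  A zero SD yields the mean for
    every worm.
    """
    if n_worms < 1:
        raise ValueError(f"n_worms must be >= 1; got {n_worms}")
    spec = config.strain(strain)
    rng = np.random.default_rng(seed)
    records: list[TraitRecord] = []
    for trait in traits:
        mu = config.trait_mean(spec, trait)
        sd = config.trait_sds[trait]
        if sd == 0:
            values = np.full(n_worms, mu)
        else:
            from scipy.stats import truncnorm

            a = (0.0 - mu) / sd
            values = truncnorm.rvs(
                a, np.inf, loc=mu, scale=sd, size=n_worms, random_state=rng
            )
        records.extend(
            TraitRecord(
                worm_id=f"{spec.name}-{i + 1}",
                strain=spec.name,
                trait=trait,
                value=float(v),
            )
            for i, v in enumerate(values)
        )
    return records


def simulate_survival(
    config: GeneratorConfig,
    strain: str | StrainSpec,
    n_worms: int,
    seed: int,
) -> list[SurvivalRecord]:
    """Simulate per-worm day-of-death records (egg-to-death, days).

    Lifespans are a normal (strain mean = wild-type baseline plus the
    strain's additive shift) discretized to the daily monitoring grid
    and floored at one day; no censoring is generated, matching a design
    in which every worm is followed to death.
    """
    if n_worms < 1:
        raise ValueError(f"n_worms must be >= 1; got {n_worms}")
    spec = config.strain(strain)
    rng = np.random.default_rng(seed)
    mu = config.lifespan_mean_days + config.lifespan_shift(spec)
    days = np.maximum(
        1, np.rint(rng.normal(mu, config.lifespan_sd_days, n_worms)).astype(int)
    )
    return [
        SurvivalRecord(
            worm_id=f"{spec.name}-{i + 1}",
            strain=spec.name,
            lifespan_days=int(d),
        )
        for i, d in enumerate(days)
    ]


# -- dataset-level helpers ------------------------------------------------


def wells_to_frame(wells: list[WellReading]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [w.strain for w in wells],
            "age": [w.age for w in wells],
            "replicate": [w.replicate for w in wells],
            "n_worms": [w.n_worms for w in wells],
            "cfp": [w.cfp for w in wells],
            "yfp": [w.yfp for w in wells],
            "fret_total": [w.fret_total for w in wells],
        }
    )


def traits_to_frame(records: list[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "worm_id": [r.worm_id for r in records],
            "strain": [r.strain for r in records],
            "trait": [r.trait for r in records],
            "value": [r.value for r in records],
        }
    )


def survival_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "worm_id": [r.worm_id for r in records],
            "strain": [r.strain for r in records],
            "lifespan_days": [r.lifespan_days for r in records],
            "censored": [r.censored for r in records],
        }
    )


def simulate_dataset(
    config: GeneratorConfig,
    seed: int,
    plate_strains: tuple[str, ...] = ("C", "SV", "SC+SV"),
    plate_ages: tuple[str, ...] = ("L4", "day6"),
    worms_per_strain: int = 50,
) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic study: plate readings, traits, survival.

    Seeds for each strain x measurement are derived deterministically from
    ``seed`` with a dedicated SeedSequence spawn, so the whole dataset is
    reproducible from one integer.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(4096))

    wells: list[WellReading] = []
    for strain in plate_strains:
        for age in plate_ages:
            wells.extend(simulate_plate(config, strain, age, seed=next(child_seeds)))

    traits: list[TraitRecord] = []
    survival: list[SurvivalRecord] = []
    for strain in config.strains:
        traits.extend(
            simulate_traits(config, strain, worms_per_strain, seed=next(child_seeds))
        )
        survival.extend(
            simulate_survival(config, strain, worms_per_strain, seed=next(child_seeds))
        )

    return {
        "plate_readings": wells_to_frame(wells),
        "traits": traits_to_frame(traits),
        "survival": survival_to_frame(survival),
    }
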