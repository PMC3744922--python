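"""CSV schemas, validated readers/writers, and the run manifest.

All tables are UTF-8 CSV with a header row and dot decimal separator.
Floats are written with 12 significant digits so a write-read round trip
preserves values to well below any tolerance used downstream.

Schemas (column -> meaning):

* ``plate_readings.csv`` — strain, age, replicate, n_worms, cfp, yfp,
  fret_total (fluorescence channels in arbitrary units, all >= 0).
* ``traits.csv`` — worm_id, strain, trait, value.
* ``survival.csv`` — worm_id, strain, lifespan_days (integer >= 1),
  censored (boolean).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .simulate import WellReading

FLOAT_FORMAT = "%.12g"

PLATE_COLUMNS = ("strain", "age", "replicate", "n_worms", "cfp", "yfp", "fret_total")
TRAIT_COLUMNS = ("worm_id", "strain", "trait", "value")
SURVIVAL_COLUMNS = ("worm_id", "strain", "lifespan_days", "censored")


class SchemaError(ValueError):
    """Raised for a malformed input table, naming the offending row."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, column: str, path, minimum: float | None = None):
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if df[column].isna().any():
        bad |= df[column].isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        row = int(bad.idxmax()) + 2
        raise SchemaError(f"{path}, line {row}: non-numeric value in {column!r}")
    if minimum is not None and (values < minimum).any():
        row = int((values < minimum).idxmax()) + 2
        raise SchemaError(
            f"{path}, line {row}: {column!r} must be >= {minimum}; got {values.iloc[row - 2]}"
        )
    return values


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    for channel in ("cfp", "yfp", "fret_total"):
        df[channel] = _check_numeric(df, channel, path, minimum=0.0)
    df["replicate"] = _check_numeric(df, "replicate", path).astype(int)
    if df["n_worms"].notna().any():
        nw = pd.to_numeric(df["n_worms"], errors="coerce")
        bad = (nw <= 0) & nw.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise SchemaError(f"{path}, line {row}: n_worms must be positive")
    return df[list(PLATE_COLUMNS)]


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, path)
    df["value"] = _check_numeric(df, "value", path)
    return df[list(TRAIT_COLUMNS)]


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVIVAL_COLUMNS, path)
    days = _check_numeric(df, "lifespan_days", path, minimum=1)
    df["lifespan_days"] = days.astype(int)
    df["censored"] = df["censored"].astype(bool)
    return df[list(SURVIVAL_COLUMNS)]


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def wells_from_frame(df: pd.DataFrame) -> list[WellReading]:
    wells = []
    for row in df.itertuples(index=False):
        n_worms = getattr(row, "n_worms", None)
        if n_worms is not None and pd.isna(n_worms):
            n_worms = None
        wells.append(
            WellReading(
                strain=row.strain,
                age=row.age,
                replicate=int(row.replicate),
                n_worms=int(n_worms) if n_worms is not None else None,
                cfp=float(row.cfp),
                yfp=float(row.yfp),
                fret_total=float(row.fret_total),
            )
        )
    return wells


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int | None,
    inputs: dict[str, str | Path],
) -> None:
    """Record the run configuration, package version and input checksums."""
    from . import __version__

    manifest = {
        "package": "wormfret",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items()
            if Path(p).exists()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
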