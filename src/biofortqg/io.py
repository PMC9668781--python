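"""Dataset container, CSV readers/writers and validation.

A dataset is three tables: trial metadata, the germplasm list (with the
check flag that drives the augmented-design model) and plot-level records.
Files are plain comma-delimited UTF-8 with '.' decimals; missing values
are empty fields, which keeps "not measured" distinct from zero (total
carotenoid content, for instance, exists only for a subset of trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("biofortqg")

TRIAL_COLUMNS = ["trial_id", "year", "location", "n_blocks"]
GERMPLASM_COLUMNS = ["genotype_id", "is_check"]
PLOT_KEY_COLUMNS = ["trial_id", "block_id", "genotype_id"]

#: per-trait valid ranges used by validation (percent traits must sit in [0,100])
PERCENT_TRAITS = ("DMC.Grav", "DMC.OD", "HI", "StC")
COUNT_COLUMNS = ("n_roots", "n_plants_harvested")


class ValidationError(ValueError):
    """Raised in strict mode when a dataset violates an invariant."""


@dataclass
class Dataset:
    """Multi-trial field dataset: trials, germplasm and plot records."""

    trials: pd.DataFrame
    germplasm: pd.DataFrame
    plots: pd.DataFrame

    def copy(self) -> "Dataset":
        return Dataset(self.trials.copy(), self.germplasm.copy(), self.plots.copy())

    @property
    def check_ids(self) -> set:
        g = self.germplasm
        return set(g.loc[g["is_check"].astype(bool), "genotype_id"])

    def trait_columns(self) -> list[str]:
        known = ["TCC", "DMC.Grav", "DMC.OD", "FRY", "ShY", "HI", "DRY",
                 "NRP", "StC", "PulpColor", "HCN"]
        return [c for c in known if c in self.plots.columns]


def validate_dataset(ds: Dataset, *, mode: str = "strict") -> Dataset:
    """Check referential and range invariants.

    strict (default): raise :class:`ValidationError` on the first problem.
    lenient: drop offending plot rows, logging each with its row number.
    Values are never altered, only whole rows dropped.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    if len(ds.plots) == 0:
        raise ValidationError("no records: the plot table is empty")
    if ds.trials["trial_id"].duplicated().any():
        raise ValidationError("duplicate trial_id in trials table")
    if ds.germplasm["genotype_id"].duplicated().any():
        raise ValidationError("duplicate genotype_id in germplasm table")

    plots = ds.plots.reset_index(drop=True)
    bad = pd.Series(False, index=plots.index)
    reasons: dict[int, str] = {}

    known_trials = set(ds.trials["trial_id"])
    m = ~plots["trial_id"].isin(known_trials)
    for i in plots.index[m]:
        reasons[i] = f"unknown trial_id {plots.at[i, 'trial_id']!r}"
    bad |= m
    known_geno = set(ds.germplasm["genotype_id"])
    m = ~plots["genotype_id"].isin(known_geno)
    for i in plots.index[m]:
        reasons.setdefault(i, f"unknown genotype_id {plots.at[i, 'genotype_id']!r}")
    bad |= m
    for col in PERCENT_TRAITS:
        if col in plots.columns:
            v = pd.to_numeric(plots[col], errors="coerce")
            m = plots[col].notna() & ((v < 0) | (v > 100))
            for i in plots.index[m]:
                reasons.setdefault(i, f"{col} outside [0, 100]")
            bad |= m
    for col in COUNT_COLUMNS:
        if col in plots.columns:
            v = pd.to_numeric(plots[col], errors="coerce")
            m = plots[col].notna() & (v < 0)
            for i in plots.index[m]:
                reasons.setdefault(i, f"negative count in {col}")
            bad |= m

    if bad.any():
        if mode == "strict":
            i = int(plots.index[bad][0])
            raise ValidationError(f"row {i}: {reasons[i]}")
        for i in plots.index[bad]:
            logger.warning("dropping plot row %d: %s", i, reasons[i])
        plots = plots.loc[~bad].reset_index(drop=True)
        if len(plots) == 0:
            raise ValidationError("no records: every plot row failed validation")
    return Dataset(ds.trials.copy(), ds.germplasm.copy(), plots)


def load_dataset(directory: str | Path, *, mode: str = "strict") -> Dataset:
    """Load trials.csv, germplasm.csv and plots.csv from a directory."""
    d = Path(directory)
    frames = {}
    for name, required in (
        ("trials", TRIAL_COLUMNS),
        ("germplasm", GERMPLASM_COLUMNS),
        ("plots", PLOT_KEY_COLUMNS),
    ):
        path = d / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        if path.stat().st_size == 0:
            raise ValidationError(f"no records: {path} is empty")
        df = pd.read_csv(path, dtype={c: str for c in PLOT_KEY_COLUMNS if c in required})
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path} missing mandatory columns {missing}")
        if name != "trials" and len(df) == 0:
            raise ValidationError(f"no records: {path} has a header but no rows")
        frames[name] = df
    frames["plots"]["block_id"] = frames["plots"]["block_id"].astype(str)
    return validate_dataset(Dataset(**frames), mode=mode)


def save_dataset(ds: Dataset, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_table(ds.trials, d / "trials.csv")
    write_table(ds.germplasm, d / "germplasm.csv")
    write_table(ds.plots, d / "plots.csv")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as comma-delimited UTF-8 with full precision."""
    if rows is None:
        raise ValueError("rows must not be None")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
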