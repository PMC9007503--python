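"""Readers and writers for every table the pipeline touches.

All tables are long ("tidy") delimited text: CSV, UTF-8, "." decimal.
Censoring is carried in an explicit boolean ``censored`` column; on read, a
``<RL`` text sentinel (``<RL`` or ``<0.003``-style) in the concentration
column is also accepted and converted.  Benchmarks printed with an open
bound (e.g. ``>95300``) are stored numerically with ``open_bound=True``.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("streamtox")


class SchemaError(ValueError):
    """A required column is missing or a table violates its schema."""


class TableValidationError(ValueError):
    """A cell value violates a schema invariant (reported with row index)."""


#: Names of the ten natural site covariates used in the field workflow.
COVARIATE_NAMES = [
    "latitude",
    "longitude",
    "site_elevation",
    "elevation_range",
    "basin_size",
    "air_temperature",
    "precipitation_longterm",
    "precipitation_summer",
    "soil_bulk_density",
    "soil_erodibility",
]

#: Column order per schema; the first entries are required on read.
SCHEMAS: dict[str, dict] = {
    "concentration": {
        "required": ["unit_id", "time", "compound", "concentration", "reporting_level"],
        "optional": ["censored"],
    },
    "benchmark": {
        "required": ["compound", "benchmark"],
        "optional": ["open_bound"],
    },
    "response": {
        "required": ["unit_id", "treatment_series", "nominal_dose", "metric", "value"],
        "optional": [],
    },
    "covariates": {
        "required": ["site_id"] + COVARIATE_NAMES,
        "optional": [],
    },
    "emergence": {
        "required": ["unit_id", "day", "count"],
        "optional": ["taxon"],
    },
    "lengths": {
        "required": ["unit_id", "taxon", "length_mm"],
        "optional": [],
    },
    "ssd": {
        "required": ["taxon", "group", "compound", "endpoint", "duration_days", "value"],
        "optional": ["source"],
    },
    "biology": {
        "required": ["site_id", "metric", "value"],
        "optional": [],
    },
    "cibq": {
        "required": ["site_id", "scope", "cibq", "n_samples_used"],
        "optional": [],
    },
    "truth": {
        "required": ["parameter", "true_value"],
        "optional": [],
    },
}

TREATMENT_SERIES = {"IMI", "CLO", "MIX", "CONTROL"}


def _parse_censored_column(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Convert a concentration column that may hold ``<RL`` sentinels.

    Returns (numeric concentration, censored flag).  A censored cell gets
    concentration 0.0 (the convention used for detection frequencies and
    quotient sums downstream).
    """
    values = np.zeros(len(raw), dtype=float)
    censored = np.zeros(len(raw), dtype=bool)
    for i, cell in enumerate(raw):
        if isinstance(cell, str):
            text = cell.strip()
            if text.startswith("<"):
                censored[i] = True
                continue
            if text == "" or text.lower() == "nan":
                values[i] = math.nan
                continue
            values[i] = float(text)
        elif cell is None or (isinstance(cell, float) and math.isnan(cell)):
            values[i] = math.nan
        else:
            values[i] = float(cell)
    return pd.Series(values, index=raw.index), pd.Series(censored, index=raw.index)


def _parse_open_bound(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    values = np.zeros(len(raw), dtype=float)
    open_bound = np.zeros(len(raw), dtype=bool)
    for i, cell in enumerate(raw):
        if isinstance(cell, str) and cell.strip().startswith(">"):
            open_bound[i] = True
            values[i] = float(cell.strip()[1:].replace(",", ""))
        else:
            values[i] = float(cell)
    return pd.Series(values, index=raw.index), pd.Series(open_bound, index=raw.index)


def read_table(path: str | Path, schema: str, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate one of the pipeline's delimited-text tables.

    Parameters
    ----------
    path : file path of a CSV file with a header row.
    schema : one of ``concentration, benchmark, response, covariates,
        emergence, lengths, ssd, biology, cibq, truth``.
    column_map : optional mapping ``{file column -> schema column}`` for
        externally produced files whose headers differ from ours.

    Returns
    -------
    A validated :class:`pandas.DataFrame` with the schema's column order.
    Censored concentration sentinels (``<RL``, ``<0.003``) are converted to
    ``censored=True`` rows with concentration 0.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema!r}")

    df = df[[c for c in spec["required"] + spec["optional"] if c in df.columns]].copy()
    return _coerce_and_validate(df, schema, str(path))


def _coerce_and_validate(df: pd.DataFrame, schema: str, source: str) -> pd.DataFrame:
    numeric_cols = {
        "concentration": ["time", "reporting_level"],
        "benchmark": [],
        "response": ["nominal_dose", "value"],
        "covariates": COVARIATE_NAMES,
        "emergence": ["day", "count"],
        "lengths": ["length_mm"],
        "ssd": ["duration_days", "value"],
        "biology": ["value"],
        "cibq": ["cibq", "n_samples_used"],
        "truth": ["true_value"],
    }[schema]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col].mask(df[col].astype(str).str.strip() == ""))

    if schema == "concentration":
        conc, censored_from_text = _parse_censored_column(df["concentration"])
        df["concentration"] = conc
        if "censored" in df.columns:
            explicit = df["censored"].astype(str).str.strip().str.lower().isin(["true", "1", "yes"])
            df["censored"] = explicit | censored_from_text
        else:
            df["censored"] = censored_from_text
        df.loc[df["censored"], "concentration"] = 0.0
        bad = df.index[(~df["censored"]) & (df["concentration"] < 0)]
        if len(bad):
            raise TableValidationError(
                f"{source}: negative concentration at row(s) {list(bad[:5])}"
            )
        bad_rl = df.index[df["reporting_level"] <= 0]
        if len(bad_rl):
            raise TableValidationError(
                f"{source}: nonpositive reporting_level at row(s) {list(bad_rl[:5])}"
            )
        dup = df.duplicated(subset=["unit_id", "time", "compound"])
        if dup.any():
            raise TableValidationError(
                f"{source}: duplicate (unit_id, time, compound) at row(s) {list(df.index[dup][:5])}"
            )
    elif schema == "benchmark":
        bench, open_bound = _parse_open_bound(df["benchmark"])
        df["benchmark"] = bench
        if "open_bound" in df.columns:
            explicit = df["open_bound"].astype(str).str.strip().str.lower().isin(["true", "1", "yes"])
            df["open_bound"] = explicit | open_bound
        else:
            df["open_bound"] = open_bound
        if (df["benchmark"] <= 0).any():
            raise TableValidationError(f"{source}: benchmarks must be positive")
        if df["compound"].duplicated().any():
            raise TableValidationError(f"{source}: duplicated compound in benchmark table")
    elif schema == "response":
        unknown = set(df["treatment_series"]) - TREATMENT_SERIES
        if unknown:
            raise TableValidationError(
                f"{source}: unknown treatment_series value(s) {sorted(unknown)}"
            )
        ctrl = df["treatment_series"] == "CONTROL"
        if (df.loc[ctrl, "nominal_dose"] != 0).any():
            raise TableValidationError(f"{source}: control rows must have nominal_dose 0")
    elif schema == "ssd":
        if (df["value"] <= 0).any():
            bad = df.index[df["value"] <= 0]
            raise TableValidationError(f"{source}: nonpositive effect value at row(s) {list(bad[:5])}")
        if "source" not in df.columns:
            df["source"] = ""
    elif schema == "emergence":
        if (df["count"] < 0).any():
            raise TableValidationError(f"{source}: negative emergence count")
    elif schema == "lengths":
        if (df["length_mm"] <= 0).any():
            raise TableValidationError(f"{source}: nonpositive length")
    return df.reset_index(drop=True)


def write_table(table: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Write a table as CSV with deterministic column order and formatting.

    Floats are written with 6 significant digits; NaN becomes the empty
    string (re-read as missing).  If ``schema`` is given its column order is
    applied; extra columns follow in sorted order.
    """
    path = Path(path)
    df = table.copy()
    if schema is not None:
        spec = SCHEMAS[schema]
        ordered = [c for c in spec["required"] + spec["optional"] if c in df.columns]
        extra = sorted(c for c in df.columns if c not in ordered)
        df = df[ordered + extra]
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")
    return path


def read_config(path: str | Path) -> dict:
    """Load a YAML configuration file (flat or nested keys per subcommand)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def setup_logging(log_file: str | Path | None = None, level: int = logging.INFO) -> logging.Logger:
    """Configure the package logger to stderr and optionally a file."""
    logger.setLevel(level)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, (logging.StreamHandler,))]
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
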