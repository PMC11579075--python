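"""Event-table data format: dosing and observation records for one trial.

The table is a flat CSV inspired by the event datasets used by population
PK/PD estimation tools. One row is either a dose (EVID=1) or an observation
(EVID=0). Units are fixed by the column and DVTYPE names — no silent unit
inference is performed; an explicit converter is provided for ACTH pg/mL.

Columns
-------
ID          subject identifier (int)
PERIOD      trial period index (int)
OCC         occasion index for between-occasion variability (int)
CLOCK       decimal clock hours after midnight of the study day
DAY         integer study day; absolute time = 24*DAY + CLOCK
EVID        0 = observation, 1 = dose
ROUTE       oral_granule | iv_bolus | dex_marker  (EVID=1 only)
AMT_MG      dose amount in mg (empty for dex_marker and observations)
DVTYPE      acth_pmolL | cortisol_total_nmolL | cortisol_unbound_nmolL
DV          observed value in the DVTYPE unit (EVID=0 only)
BW_KG       subject body weight, kg
AGE_Y       subject age, years
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ACTH_PG_PER_PMOL

__all__ = ["COLUMNS", "DVTYPES", "read_event_table", "write_event_table",
           "validate_event_table", "EventTableError", "acth_pg_ml_to_pmol_l"]

log = logging.getLogger(__name__)

COLUMNS = ["ID", "PERIOD", "OCC", "CLOCK", "DAY", "EVID", "ROUTE",
           "AMT_MG", "DVTYPE", "DV", "BW_KG", "AGE_Y"]
ROUTES = ("oral_granule", "iv_bolus", "dex_marker")
DVTYPES = ("acth_pmolL", "cortisol_total_nmolL", "cortisol_unbound_nmolL")

#: DVTYPE suffixes we explicitly refuse, with a conversion hint
_BAD_UNIT_HINTS = {
    "pgmL": "convert ACTH pg/mL to pmol/L with acth_pg_ml_to_pmol_l()",
    "pg_mL": "convert ACTH pg/mL to pmol/L with acth_pg_ml_to_pmol_l()",
    "ugdL": "convert cortisol ug/dL to nmol/L (x 27.59) before import",
    "ug_dL": "convert cortisol ug/dL to nmol/L (x 27.59) before import",
}


class EventTableError(ValueError):
    """Schema violation in an event table; message lists offending rows."""


def acth_pg_ml_to_pmol_l(values, pg_ml_per_pmol_l: float = ACTH_PG_PER_PMOL):
    """Convert ACTH pg/mL to pmol/L (default MW 4541.1 g/mol)."""
    return np.asarray(values, dtype=float) / pg_ml_per_pmol_l


def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and ordering; returns the table with typed columns.

    Unknown columns are preserved with a warning. Violations raise
    :class:`EventTableError` listing the offending row indices.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"missing required columns: {missing}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        log.warning("unknown columns preserved: %s", extra)

    df = df.copy()
    for c in ("ID", "PERIOD", "OCC", "DAY", "EVID"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    for c in ("CLOCK", "AMT_MG", "DV", "BW_KG", "AGE_Y"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    bad_evid = df.index[~df["EVID"].isin([0, 1])].tolist()
    if bad_evid:
        raise EventTableError(f"EVID must be 0 or 1; offending rows: {bad_evid}")

    obs = df["EVID"] == 0
    dose = df["EVID"] == 1

    bad_dvtype = df.index[obs & ~df["DVTYPE"].isin(DVTYPES)].tolist()
    if bad_dvtype:
        hints = []
        for i in bad_dvtype[:5]:
            dvt = str(df.loc[i, "DVTYPE"])
            for suffix, hint in _BAD_UNIT_HINTS.items():
                if dvt.endswith(suffix):
                    hints.append(f"row {i}: {dvt!r} -> {hint}")
        raise EventTableError(
            f"invalid DVTYPE on observation rows {bad_dvtype}"
            + ("; " + "; ".join(hints) if hints else ""))

    bad = df.index[obs & (df["DV"].isna() | (df["DV"] < 0))].tolist()
    if bad:
        raise EventTableError(f"EVID=0 rows need DV >= 0; offending rows: {bad}")
    bad = df.index[obs & df["AMT_MG"].notna()].tolist()
    if bad:
        raise EventTableError(f"EVID=0 rows must have empty AMT_MG; offending rows: {bad}")

    bad = df.index[dose & ~df["ROUTE"].isin(ROUTES)].tolist()
    if bad:
        raise EventTableError(f"EVID=1 rows need a valid ROUTE; offending rows: {bad}")
    need_amt = dose & (df["ROUTE"] != "dex_marker")
    bad = df.index[need_amt & (df["AMT_MG"].isna() | (df["AMT_MG"] <= 0))].tolist()
    if bad:
        raise EventTableError(f"EVID=1 dosing rows need AMT_MG > 0; offending rows: {bad}")
    bad = df.index[dose & df["DV"].notna()].tolist()
    if bad:
        raise EventTableError(f"EVID=1 rows must have empty DV; offending rows: {bad}")

    t_abs = 24.0 * df["DAY"] + df["CLOCK"]
    bad_rows = []
    for (_, _), g in df.assign(_t=t_abs).groupby(["ID", "PERIOD"], sort=False):
        dt = np.diff(g["_t"].values)
        bad_rows.extend(g.index.values[1:][dt < 0].tolist())
    if bad_rows:
        raise EventTableError(
            f"rows not sorted by absolute time within (ID, PERIOD): {bad_rows}")
    return df


def read_event_table(path) -> pd.DataFrame:
    """Read and validate an event-table CSV."""
    df = pd.read_csv(path)
    return validate_event_table(df)


def write_event_table(df: pd.DataFrame, path) -> None:
    """Validate and write an event table; ``read(write(t)) == t``."""
    df = validate_event_table(df)
    cols = COLUMNS + [c for c in df.columns if c not in COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=cols)
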