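"""Delimited-text readers/writers for the pipeline's tabular interfaces.

Three input tables, all plain delimited text (tab by default):

* fraction concentrations — tidy: sample_id, fraction_number, volume_ml,
  analyte, concentration, unit
* whole-serum totals — tidy: sample_id, analyte, concentration, unit
  (plus optional injected_volume_ml and category columns)
* DLS sizes — batch_id, sample_id, fraction_number, diameter_nm, qc_flag

Concentrations are converted to mol/L on read using each row's declared
unit (mg/dL rows use the class-average lipid molecular weights).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .analytes import Analyte, UnitError, VolumetricConstants, to_mol_per_l
from .volumetrics import SerumRecord


def read_fraction_table(
    path: str | Path,
    constants: VolumetricConstants = VolumetricConstants(),
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a tidy fraction-concentration table into wide per-sample form.

    Returns one row per (sample_id, fraction_number) with a ``volume_ml``
    column and one mol/L column per analyte.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "fraction_number", "volume_ml", "analyte",
                "concentration", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise UnitError(f"fraction table missing columns: {sorted(missing)}")
    df["mol_l"] = [
        to_mol_per_l(row.concentration, row.unit, row.analyte, constants)
        for row in df.itertuples()
    ]
    wide = df.pivot_table(
        index=["sample_id", "fraction_number", "volume_ml"],
        columns="analyte",
        values="mol_l",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={c: Analyte(c) for c in wide.columns
                                if c in {a.value for a in Analyte}})
    return wide


def read_serum_table(
    path: str | Path,
    constants: VolumetricConstants = VolumetricConstants(),
    sep: str = "\t",
    default_injected_volume_ml: float = 0.050,
) -> dict[str, SerumRecord]:
    """Read a tidy whole-serum totals table into SerumRecords by sample."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "analyte", "concentration", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise UnitError(f"serum table missing columns: {sorted(missing)}")
    records: dict[str, SerumRecord] = {}
    for sample_id, grp in df.groupby("sample_id"):
        totals = {
            Analyte(row.analyte): to_mol_per_l(
                row.concentration, row.unit, row.analyte, constants
            )
            for row in grp.itertuples()
        }
        injected = (
            float(grp["injected_volume_ml"].iloc[0])
            if "injected_volume_ml" in grp
            else default_injected_volume_ml
        )
        category = (
            str(grp["category"].iloc[0])
            if "category" in grp and pd.notna(grp["category"].iloc[0])
            else None
        )
        records[str(sample_id)] = SerumRecord(
            sample_id=str(sample_id),
            total_conc_mol_l=totals,
            injected_volume_ml=injected,
            category=category,
        )
    return records


def read_dls_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    required = {"batch_id", "sample_id", "fraction_number", "diameter_nm"}
    missing = required - set(df.columns)
    if missing:
        raise UnitError(f"DLS table missing columns: {sorted(missing)}")
    if "qc_flag" not in df:
        df["qc_flag"] = ""
    df["qc_flag"] = df["qc_flag"].fillna("")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def fractions_to_tidy(
    wide: pd.DataFrame, sample_id_col: str = "sample_id", unit: str = "mol/L"
) -> pd.DataFrame:
    """Inverse of :func:`read_fraction_table` for writing simulated data."""
    analyte_cols = [c for c in wide.columns if isinstance(c, Analyte)
                    or c in {a.value for a in Analyte}]
    tidy = wide.melt(
        id_vars=[c for c in (sample_id_col, "fraction_number", "volume_ml")
                 if c in wide.columns],
        value_vars=analyte_cols,
        var_name="analyte",
        value_name="concentration",
    )
    tidy["analyte"] = tidy["analyte"].astype(str)
    tidy["unit"] = unit
    return tidy


def serum_to_tidy(records: Mapping[str, SerumRecord], unit: str = "mol/L") -> pd.DataFrame:
    rows = []
    for sample_id, rec in records.items():
        for analyte, conc in rec.total_conc_mol_l.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "analyte": str(analyte),
                    "concentration": conc,
                    "unit": unit,
                    "injected_volume_ml": rec.injected_volume_ml,
                    "category": rec.category if rec.category else np.nan,
                }
            )
    return pd.DataFrame(rows)
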