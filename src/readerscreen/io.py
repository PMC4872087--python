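"""Canonical table readers/writers.

All tables are comma-separated text with mandatory header rows and explicit
units in column names (``conc_M``, ``temp_C``, ``time_s``, ``response_nm``).
Plate-reader exports vary wildly; this single dialect plus these adapters is
the package's I/O contract.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .bli import Sensorgram
from .cetsa import CetsaSeries
from .ftsa import MeltCurve

PLATE_ROLES = {"sample", "positive", "negative", "blank"}
FP_EXTRA_ROLES = {"probe_only", "protein_only", "saturated_competitor"}

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6,
                 "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def parse_concentration(text: str | float) -> float:
    """Parse a concentration with optional nM/uM/mM suffix into molar."""
    if isinstance(text, (int, float)):
        return float(text)
    m = re.fullmatch(r"\s*([\d.eE+-]+)\s*([A-Za-zμµ]*)\s*", str(text))
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    value, unit = float(m.group(1)), m.group(2) or "M"
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r} in {text!r}")
    return value * _UNIT_FACTORS[unit]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _check_roles(df: pd.DataFrame, allowed, path) -> None:
    bad = df.loc[~df["role"].isin(allowed)]
    if len(bad):
        lines = ", ".join(f"row {i}: {r!r}" for i, r in
                          bad["role"].head(5).items())
        raise ValueError(f"{path}: unknown roles ({lines})")


def read_plate_table(path) -> pd.DataFrame:
    """Alpha-style plate table: well, row, col, role, compound_id, conc_M, signal."""
    df = pd.read_csv(path)
    _require_columns(df, ["well", "role", "conc_M", "signal"], path)
    _check_roles(df, PLATE_ROLES, path)
    df["conc_M"] = df["conc_M"].map(parse_concentration)
    return df


def read_fp_plate_table(path) -> pd.DataFrame:
    """FP plate table with two signal channels (i_s, i_p) and extended roles."""
    df = pd.read_csv(path)
    _require_columns(df, ["well", "role", "conc_M", "i_s", "i_p"], path)
    _check_roles(df, PLATE_ROLES | FP_EXTRA_ROLES, path)
    df["conc_M"] = df["conc_M"].map(parse_concentration)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def melt_curves_to_table(curves) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(curves):
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append({"well": f"W{i + 1}", "label": c.label or f"curve{i + 1}",
                         "ligand_conc_M": c.ligand_total, "temp_C": t,
                         "fluorescence": f})
    return pd.DataFrame(rows)


def read_melt_table(path) -> list:
    """Melt table (well, label, ligand_conc_M, temp_C, fluorescence) -> MeltCurve list."""
    df = pd.read_csv(path)
    _require_columns(df, ["well", "label", "ligand_conc_M", "temp_C",
                          "fluorescence"], path)
    curves = []
    for (_, label, conc), grp in df.groupby(["well", "label", "ligand_conc_M"],
                                            sort=False):
        grp = grp.sort_values("temp_C")
        curves.append(MeltCurve(grp["temp_C"].to_numpy(),
                                grp["fluorescence"].to_numpy(),
                                ligand_total=parse_concentration(conc),
                                label=str(label)))
    return curves


def sensorgrams_to_table(sensorgrams) -> pd.DataFrame:
    rows = []
    for sg in sensorgrams:
        for t, r, p in zip(sg.time, sg.response, sg.phase):
            rows.append({"time_s": t, "response_nm": r, "phase": p,
                         "analyte_conc_M": sg.analyte_concentration,
                         "run_id": sg.run_id})
    return pd.DataFrame(rows)


def read_sensorgram_table(path) -> list:
    """Sensorgram table (time_s, response_nm, phase, analyte_conc_M, run_id)."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "response_nm", "phase", "analyte_conc_M",
                          "run_id"], path)
    out = []
    for run_id, grp in df.groupby("run_id", sort=False):
        grp = grp.sort_values("time_s")
        out.append(Sensorgram(grp["time_s"].to_numpy(),
                              grp["response_nm"].to_numpy(),
                              grp["phase"].tolist(),
                              float(grp["analyte_conc_M"].iloc[0]),
                              run_id=str(run_id)))
    return out


def cetsa_to_table(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, b in zip(s.temperatures, s.band_intensities):
            rows.append({"membrane_id": s.membrane_id, "condition": s.condition_label,
                         "temp_C": t, "band_intensity": b, "replicate": 1})
    return pd.DataFrame(rows)


def read_cetsa_table(path) -> list:
    """CETSA table (membrane_id, condition, temp_C, band_intensity, replicate)."""
    df = pd.read_csv(path)
    _require_columns(df, ["membrane_id", "condition", "temp_C",
                          "band_intensity"], path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    out = []
    for (mem, cond, _rep), grp in df.groupby(
            ["membrane_id", "condition", "replicate"], sort=False):
        grp = grp.sort_values("temp_C")
        out.append(CetsaSeries(grp["temp_C"].to_numpy(),
                               grp["band_intensity"].to_numpy(),
                               condition_label=str(cond), membrane_id=str(mem)))
    return out
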