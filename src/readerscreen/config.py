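"""Run configuration and run reports.

A :class:`RunConfig` is schema-validated (unknown keys rejected) before any
computation; concentrations may be given with nM/uM/mM suffixes and are
stored in molar.  :func:`run_screen` executes one configured stage and
returns a :class:`RunReport` whose every number was emitted by exactly one
pipeline operation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .io import parse_concentration

STAGES = ("qc", "alpha-ic50", "fp-kd", "fp-ic50", "ftsa", "bli-kinetics",
          "bli-displacement", "cetsa", "simulate")


class FTSAThermoOptions(BaseModel):
    """Fixed unfolding/binding thermodynamics for the dosing K_D fit."""

    model_config = ConfigDict(extra="forbid")

    protein_total: float
    dh_u: Optional[float] = None   # kJ/mol; None -> van't Hoff from reference curve
    dcp_u: float = 8.0
    dh_b: float = -42.0
    dcp_b: float = 0.0
    t0: float = 37.0

    @field_validator("protein_total", mode="before")
    @classmethod
    def _conc(cls, v):
        return parse_concentration(v)


class RunConfig(BaseModel):
    """One analysis (or simulation) stage with its inputs and options."""

    model_config = ConfigDict(extra="forbid")

    assay: Literal["qc", "alpha-ic50", "fp-kd", "fp-ic50", "ftsa",
                   "bli-kinetics", "bli-displacement", "cetsa", "simulate"]
    inputs: dict = {}
    out_dir: str = "results"
    seed: int = 0
    # FP options
    g_factor: float = 0.91
    p_dstar: float = 25.0
    p_dstar_r: float = 225.0
    probe_total: Optional[float] = None
    depletion_corrected: bool = False
    # QC / reporting options
    z_threshold: float = 0.5
    report_point_offset_s: float = 5.0
    normalization_mode: Literal["min_max", "relative_to_lowest_temp"] = "min_max"
    control_condition: str = "control"
    ftsa_thermo: Optional[FTSAThermoOptions] = None
    # simulate options
    sim_kind: Optional[str] = None
    sim_params: dict = {}

    @field_validator("probe_total", mode="before")
    @classmethod
    def _conc(cls, v):
        return None if v is None else parse_concentration(v)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class RunReport:
    """Structured results of one run: stage outputs, QC verdicts, provenance."""

    assay: str
    stages: dict
    qc: dict
    constants: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_jsonable)

    def to_text(self) -> str:
        lines = [f"assay = {self.assay}"]
        for section, data in (("qc", self.qc), ("constants", self.constants)):
            for k, v in data.items():
                lines.append(f"{section}.{k} = {v}")
        for k, v in self.provenance.items():
            lines.append(f"provenance.{k} = {v}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "report.txt").write_text(self.to_text())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
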