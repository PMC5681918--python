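"""Schema-validated run configuration and result serialization.

A run configuration is a YAML document with blocks for the cell phenotype,
drug-binding scheme, protocol, sweep and sensitivity settings, solver
tolerances, output directory and the global seed.  Configurations
round-trip losslessly through YAML; every stochastic operation receives an
explicit seed; a manifest (config hash, seeds, parameter-file version)
accompanies all outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError  # noqa: F401

from .markov import DrugSpec, KurScheme
from .params import PARAMETER_FILE_VERSION


class SchemeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["drug_free", "open", "open_inactivated", "closed"] \
        = "drug_free"
    bridged: bool = False
    kon: float = Field(0.0, ge=0)          # uM^-1 s^-1
    koff: float = Field(0.0, ge=0)         # s^-1
    kon_i: Optional[float] = Field(None, ge=0)
    koff_i: Optional[float] = Field(None, ge=0)
    concentration: float | Literal["IC50"] = 0.0

    def scheme(self) -> KurScheme:
        if self.kind == "drug_free":
            return KurScheme()
        if self.kind == "open":
            return KurScheme.open_blocker(self.kon, self.koff)
        if self.kind == "closed":
            return KurScheme.closed_blocker(self.kon, self.koff)
        return KurScheme.open_inactivated_blocker(
            self.kon, self.koff, self.kon_i, self.koff_i,
            bridged=self.bridged)

    def drug(self, ic50: float | None = None) -> DrugSpec:
        conc = self.concentration
        if conc == "IC50":
            if ic50 is None:
                raise ValueError("IC50 sentinel requires a computed IC50")
            conc = ic50
        return DrugSpec(scheme=self.scheme(), concentration=float(conc))


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["regular", "irregular", "s1s2", "voltage_ramp"] = "regular"
    rate_hz: float = Field(1.0, gt=0)
    n_beats: Optional[int] = Field(None, gt=0)
    stim_amplitude: Optional[float] = None   # A/F
    stim_duration: float = Field(5.0, gt=0)
    duration_s: float = Field(20.0, gt=0)
    cl_min: float = Field(285.7, gt=0)
    cl_max: float = Field(400.0, gt=0)
    s2_start: float = Field(700.0, gt=0)
    s2_decrement: float = Field(2.0, gt=0)


class SweepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scheme_family: Literal["open", "open_inactivated",
                           "open_inactivated_bridged", "closed"] \
        = "open_inactivated"
    grid_spec: Literal["diagonal", "full", "state_affinity"] = "full"
    phenotypes: list[Literal["nSR", "cAF"]] = ["cAF"]
    rates: list[float] = [1.0, 3.0]
    include_erp: bool = False


class SensitivityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_variants: int = Field(900, gt=1)
    sigma: float = Field(0.1, ge=0)
    n_subsets: int = Field(30, gt=0)
    subset_size: int = Field(300, gt=1)
    phenotypes: list[Literal["nSR", "cAF"]] = ["nSR", "cAF"]
    rates: list[float] = [1.0, 3.0]
    include_erp: bool = False
    erp_subsample: Optional[int] = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phenotype: Literal["nSR", "cAF"] = "nSR"
    scheme: SchemeConfig = SchemeConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    sweep: SweepConfig = SweepConfig()
    sensitivity: SensitivityConfig = SensitivityConfig()
    rtol: float = Field(1e-6, gt=0)
    out_dir: str = "results"
    seed: int = 0
    fast: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"),
                              sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: Path,
                   outputs: list[str], notes: dict | None = None) -> Path:
    """Write the reproducibility manifest next to the result files."""
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameter_file_version": PARAMETER_FILE_VERSION,
        "config": yaml.safe_load(config.to_yaml()),
        "outputs": outputs,
        "notes": notes or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
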