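"""Structured run configuration (YAML) with schema validation.

A run config has nested sections ``material``, ``bed``, ``transport`` and
``solver``; unknown keys are rejected.  Units are those declared by the
domain types: metres, minutes, grams, mL/min, mg/mL.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .equilibrium import BedSpec, DIS_POOLED_DEFAULT, MaterialBatch
from .fixtures import DEFF_POOLED
from .kinetics import MESH_SIZE_M
from .simulate import SimulationConfig, make_config
from .transport import (
    DAX_CORRELATIONS,
    KEXT_CORRELATIONS,
    TransportParams,
    combine_kx,
)

__all__ = ["RunConfig", "load_config", "build_simulation"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialSection(_Strict):
    M0: float = Field(ge=0, description="marker content, mg per g herb")
    D_is: float = Field(default=DIS_POOLED_DEFAULT, gt=0)
    D_eff: float = Field(default=DEFF_POOLED, gt=0, description="m^2/min")
    mesh_class: Optional[str] = None
    particle_size: Optional[float] = Field(default=None, gt=0, description="m")

    def resolved_particle_size(self) -> float:
        if self.particle_size is not None:
            return self.particle_size
        if self.mesh_class is not None:
            try:
                return MESH_SIZE_M[self.mesh_class]
            except KeyError:
                raise ValueError(
                    f"unknown mesh_class {self.mesh_class!r}; known: {list(MESH_SIZE_M)}"
                ) from None
        raise ValueError("material needs either particle_size or mesh_class")


class BedSection(_Strict):
    column_diameter: float = Field(gt=0, description="m")
    herb_mass: float = Field(gt=0, description="g")
    voidage: float = Field(gt=0, lt=1)
    expansion_coefficient: float = Field(default=3.81, gt=0, description="mL/g")
    bed_height: Optional[float] = Field(default=None, gt=0, description="m")
    flow_rate: float = Field(gt=0, description="mL/min")
    inlet_concentration: float = Field(default=0.0, ge=0, description="mg/mL")
    height_mode: str = "as_printed"


class TransportSection(_Strict):
    kext: str = "wilson_geankoplis"
    dax: str = "koch_brady"
    # explicit overrides (m/min, m^2/min); if all three are set the
    # correlations are bypassed entirely
    k_int: Optional[float] = Field(default=None, gt=0)
    k_ext: Optional[float] = Field(default=None, gt=0)
    D_ax: Optional[float] = Field(default=None, gt=0)


class SolverSection(_Strict):
    duration: float = Field(default=300.0, gt=0, description="min")
    n_cells: int = Field(default=200, ge=10)
    n_out: Optional[int] = Field(default=None, ge=2)
    rtol: float = Field(default=1e-6, gt=0)
    atol: float = Field(default=1e-9, gt=0)


class RunConfig(_Strict):
    material: MaterialSection
    bed: BedSection
    transport: TransportSection = TransportSection()
    solver: SolverSection = SolverSection()


def load_config(path) -> RunConfig:
    """Read and validate a YAML run config."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return RunConfig.model_validate(data)


def build_simulation(cfg: RunConfig) -> SimulationConfig:
    """Turn a validated config into a runnable :class:`SimulationConfig`."""
    material = MaterialBatch(
        M0=cfg.material.M0,
        D_is=cfg.material.D_is,
        D_eff=cfg.material.D_eff,
        particle_size=cfg.material.resolved_particle_size(),
        mesh_class=cfg.material.mesh_class,
    )
    bed = BedSpec(
        column_diameter=cfg.bed.column_diameter,
        herb_mass=cfg.bed.herb_mass,
        voidage=cfg.bed.voidage,
        expansion_coefficient=cfg.bed.expansion_coefficient,
        flow_rate=cfg.bed.flow_rate,
        bed_height=cfg.bed.bed_height,
        inlet_concentration=cfg.bed.inlet_concentration,
    )
    if cfg.transport.kext not in KEXT_CORRELATIONS:
        raise ValueError(f"unknown kext correlation {cfg.transport.kext!r}")
    if cfg.transport.dax not in DAX_CORRELATIONS:
        raise ValueError(f"unknown dax correlation {cfg.transport.dax!r}")
    transport = None
    t = cfg.transport
    if t.k_int is not None and t.k_ext is not None and t.D_ax is not None:
        transport = TransportParams(
            k_int=t.k_int,
            k_ext=t.k_ext,
            K_x=combine_kx(t.k_int, t.k_ext),
            D_ax=t.D_ax,
            kext_correlation="override",
            dax_correlation="override",
        )
    return make_config(
        material,
        bed,
        transport,
        kext_name=t.kext,
        dax_name=t.dax,
        height_mode=cfg.bed.height_mode,
        duration=cfg.solver.duration,
        n_cells=cfg.solver.n_cells,
        n_out=cfg.solver.n_out,
        rtol=cfg.solver.rtol,
        atol=cfg.solver.atol,
    )
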