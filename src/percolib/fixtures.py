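"""Built-in parameter sets mirroring the published experiment/batch tables.

These are the printed material batches (marker content M0, partition
coefficients, fitted diffusion parameters) and the nine single-factor
percolation experiments (batch, mesh class, flow, herb mass, measured
voidage and expansion coefficient).  They let every module be exercised
without any external data file.

Values are stored verbatim as printed; quantities the source does not
print (e.g. M0 of batch D3) are ``None`` and must be supplied explicitly
when building a run from such a batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional

from .equilibrium import BedSpec, DIS_POOLED_DEFAULT, MaterialBatch
from .kinetics import MESH_SIZE_M

__all__ = [
    "BatchFixture",
    "ExperimentFixture",
    "FixtureSet",
    "builtin_fixtures",
    "material_from_batch",
    "bed_from_experiment",
    "DEFF_BY_MESH",
    "DEFF_POOLED",
]

#: Mean apparent diffusivity per mesh class, m^2/min (Table-derived).
DEFF_BY_MESH = MappingProxyType({"5-10": 1.073e-8, "10-24": 1.104e-8})

#: Pooled apparent diffusivity (mean of the two class means), m^2/min.
DEFF_POOLED = 1.089e-8

#: Column diameter of the percolation cylinder used throughout, m.
COLUMN_DIAMETER_M = 0.05


@dataclass(frozen=True)
class BatchFixture:
    """One herb batch: printed contents and equilibrium measurements."""

    batch_id: str
    M0: Optional[float]                      # mg/g, ultrasonic method
    M0_multiple_impregnation: Optional[float]  # mg/g, exhaustive soaking
    dis_values: Mapping[str, tuple[float, ...]]  # mesh class -> replicates
    dis_mean: Optional[float]                # batch mean, 10-24 mesh

    def dis_or_default(self) -> float:
        return self.dis_mean if self.dis_mean is not None else DIS_POOLED_DEFAULT


@dataclass(frozen=True)
class ExperimentFixture:
    """One single-factor percolation experiment (columns of the tables)."""

    experiment_id: str
    batch_id: str
    mesh_class: str
    flow_rate: float          # mL/min
    herb_mass: float          # g
    voidage: float
    expansion_coefficient: float  # mL/g

    @property
    def particle_size(self) -> float:
        return MESH_SIZE_M[self.mesh_class]


@dataclass(frozen=True)
class FixtureSet:
    batches: Mapping[str, BatchFixture]
    experiments: Mapping[str, ExperimentFixture]

    #: Fitted diffusion-model parameters (C_eq mg/mL, D_eff/r^2 1/min)
    #: per (batch, mesh class).
    diffusion_fits: Mapping[tuple[str, str], tuple[float, float]]


_BATCHES = {
    "D1": BatchFixture(
        "D1",
        M0=43.83,
        M0_multiple_impregnation=45.80,
        dis_values=MappingProxyType({"10-24": (1.16, 1.32, 1.17)}),
        dis_mean=1.22,
    ),
    "D2": BatchFixture(
        "D2",
        M0=51.27,
        M0_multiple_impregnation=52.23,
        dis_values=MappingProxyType({"10-24": (1.18, 1.10, 1.17)}),
        dis_mean=1.15,
    ),
    "D3": BatchFixture(
        "D3",
        M0=None,
        M0_multiple_impregnation=None,
        dis_values=MappingProxyType({}),
        dis_mean=None,
    ),
    "D4": BatchFixture(
        "D4",
        M0=49.60,
        M0_multiple_impregnation=51.63,
        dis_values=MappingProxyType(
            {
                "5-10": (1.24, 1.30, 1.23, 1.23),
                "10-24": (1.26, 1.24, 1.31, 1.30),
                "24-50": (1.26, 1.23, 1.36, 1.30),
            }
        ),
        dis_mean=1.28,
    ),
    "D5": BatchFixture(
        "D5",
        M0=37.28,
        M0_multiple_impregnation=None,
        dis_values=MappingProxyType({}),
        dis_mean=None,
    ),
}

_EXPERIMENTS = {
    "E1": ExperimentFixture("E1", "D4", "10-24", 2.0, 50.0, 0.41, 3.89),
    "E2": ExperimentFixture("E2", "D4", "10-24", 2.0, 30.0, 0.35, 4.08),
    "E3": ExperimentFixture("E3", "D4", "10-24", 2.0, 70.0, 0.37, 3.80),
    "E4": ExperimentFixture("E4", "D4", "10-24", 3.0, 50.0, 0.36, 3.80),
    "E5": ExperimentFixture("E5", "D4", "10-24", 4.0, 50.0, 0.34, 3.97),
    "E6": ExperimentFixture("E6", "D4", "5-10", 2.0, 50.0, 0.41, 3.48),
    "E7": ExperimentFixture("E7", "D4", "24-50", 2.0, 50.0, 0.30, 4.40),
    "E8": ExperimentFixture("E8", "D1", "10-24", 2.0, 50.0, 0.41, 3.43),
    "E9": ExperimentFixture("E9", "D3", "10-24", 2.0, 50.0, 0.42, 3.42),
}

_DIFFUSION_FITS = {
    ("D1", "5-10"): (7.366, 0.00112),
    ("D1", "10-24"): (7.017, 0.00366),
    ("D2", "5-10"): (7.916, 0.00144),
    ("D2", "10-24"): (7.565, 0.00698),
    ("D3", "5-10"): (4.788, 0.00102),
    ("D3", "10-24"): (4.535, 0.00567),
}

_FIXTURES = FixtureSet(
    batches=MappingProxyType(_BATCHES),
    experiments=MappingProxyType(_EXPERIMENTS),
    diffusion_fits=MappingProxyType(_DIFFUSION_FITS),
)


def builtin_fixtures() -> FixtureSet:
    """The immutable built-in fixture set (5 batches, 9 experiments)."""
    return _FIXTURES


def material_from_batch(
    batch_id: str,
    mesh_class: str = "10-24",
    *,
    M0: float | None = None,
    D_is: float | None = None,
    D_eff: float | None = None,
) -> MaterialBatch:
    """Build a :class:`MaterialBatch` from a fixture batch.

    Overrides take precedence; otherwise M0 comes from the batch record
    (raising if unprinted), D_is from the batch mean (pooled default if
    absent) and D_eff from the mesh-class mean (pooled if the class has no
    printed mean).
    """
    batch = _FIXTURES.batches[batch_id]
    m0 = M0 if M0 is not None else batch.M0
    if m0 is None:
        raise ValueError(
            f"batch {batch_id} has no printed M0; pass an explicit override"
        )
    dis = D_is if D_is is not None else batch.dis_or_default()
    deff = D_eff if D_eff is not None else DEFF_BY_MESH.get(mesh_class, DEFF_POOLED)
    return MaterialBatch(
        M0=m0,
        D_is=dis,
        D_eff=deff,
        particle_size=MESH_SIZE_M[mesh_class],
        mesh_class=mesh_class,
        label=f"{batch_id} {mesh_class} mesh",
    )


def bed_from_experiment(experiment_id: str, **overrides) -> BedSpec:
    """Build a :class:`BedSpec` from a fixture experiment row."""
    exp = _FIXTURES.experiments[experiment_id]
    kw = dict(
        column_diameter=COLUMN_DIAMETER_M,
        herb_mass=exp.herb_mass,
        voidage=exp.voidage,
        expansion_coefficient=exp.expansion_coefficient,
        flow_rate=exp.flow_rate,
    )
    kw.update(overrides)
    return BedSpec(**kw)
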