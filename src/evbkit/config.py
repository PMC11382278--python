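"""Structured run configuration: YAML schema, validation, system building.

One config file describes a full pipeline run: the toy system, the lambda
schedule and sampling settings, the EVB parameters (explicit, or calibration
targets to fit them), and the kinetics context.  Validation is strict and
happens before any compute; pydantic reports the offending key path.
"""

from __future__ import annotations

from typing import List, Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import terms as _t
from .core import EVBParameters
from .systems import DiabaticSystem, RestraintSpec, make_marcus_system

__all__ = ["RunConfig", "load_config", "build_system"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HarmonicTerm(_Strict):
    type: Literal["harmonic"]
    k: float = Field(gt=0)
    x0: float
    coord: int = 0


class MorseTerm(_Strict):
    type: Literal["morse"]
    depth: float = Field(ge=0)
    a: float = Field(gt=0)
    x0: float
    coord: int = 0


class BuckinghamTerm(_Strict):
    """Exponential repulsion A exp(-b r); defaults are config-level choices."""

    type: Literal["buckingham"]
    a: float = Field(default=1e4, ge=0)
    b: float = Field(default=3.0, gt=0)
    coord: int = 0


class ConstantTerm(_Strict):
    type: Literal["constant"]
    value: float
    coord: int = 0


TermConfig = Union[HarmonicTerm, MorseTerm, BuckinghamTerm, ConstantTerm]


class RestraintConfig(_Strict):
    kind: Literal["flat_bottom_distance", "positional"]
    force_constant: float = Field(ge=0)
    lo: Optional[float] = None
    hi: Optional[float] = None
    target: float = 0.0
    coord: int = 0

    def build(self) -> RestraintSpec:
        return RestraintSpec(
            kind=self.kind,
            force_constant=self.force_constant,
            lo=self.lo,
            hi=self.hi,
            target=self.target,
            coord=self.coord,
        )


class MarcusSystemConfig(_Strict):
    """Default toy: two displaced harmonic diabats (Marcus-like surrogate)."""

    kind: Literal["marcus"] = "marcus"
    k1: float = Field(default=200.0, gt=0)
    k2: float = Field(default=200.0, gt=0)
    x1: float = 0.0
    x2: float = 1.0
    delta_e: float = 0.0
    mass: float = Field(default=12.0, gt=0)
    restraints: List[RestraintConfig] = []

    @model_validator(mode="after")
    def _distinct_minima(self):
        if self.x1 == self.x2:
            raise ValueError("x1 and x2 must be distinct")
        return self


class CustomSystemConfig(_Strict):
    kind: Literal["custom"]
    dimension: int = Field(ge=1, le=2)
    state1_terms: List[TermConfig] = Field(min_length=1)
    state2_terms: List[TermConfig] = Field(min_length=1)
    masses: List[float]
    restraints: List[RestraintConfig] = []

    @model_validator(mode="after")
    def _mass_per_coord(self):
        if len(self.masses) != self.dimension or any(m <= 0 for m in self.masses):
            raise ValueError("masses must be positive, one per coordinate")
        return self


class ScheduleConfig(_Strict):
    n_lambda: int = Field(default=51, ge=2)
    n_steps: int = Field(default=10_000, ge=0)
    dt: float = Field(default=1.0, gt=0)
    temperature: float = Field(default=310.0, gt=0)
    friction: float = Field(default=0.2, ge=0)
    n_replicas: int = Field(default=3, ge=1)
    seed: int = 2024
    stride: int = Field(default=10, ge=1)
    burn_in_frac: float = Field(default=0.2, ge=0, lt=1)
    equilibrate_first: bool = False


class CalibrationTargetsConfig(_Strict):
    dg_act_gas: float
    dg_rxn_gas: float


class EVBConfig(_Strict):
    """Exactly one of (h_ij, alpha) or calibration targets must be given."""

    h_ij: Optional[float] = Field(default=None, ge=0)
    alpha: Optional[float] = None
    targets: Optional[CalibrationTargetsConfig] = None

    @model_validator(mode="after")
    def _one_of(self):
        explicit = self.h_ij is not None or self.alpha is not None
        if explicit and self.targets is not None:
            raise ValueError("give either explicit (h_ij, alpha) or targets, not both")
        if explicit and (self.h_ij is None or self.alpha is None):
            raise ValueError("explicit parameters require both h_ij and alpha")
        if not explicit and self.targets is None:
            raise ValueError("either explicit (h_ij, alpha) or targets are required")
        return self


class KineticsConfig(_Strict):
    pKa_water: float = 15.7
    pKa_amine: float = 8.11
    pH: float = Field(default=7.4, ge=0, le=14)
    temperature: float = Field(default=310.15, gt=0)
    #: thermal energy: a number in kcal/mol, or "physical" for k_B*T
    kT: Union[float, Literal["physical"]] = 0.617
    rate_constant: Optional[float] = Field(default=None, gt=0)


class ProfileConfig(_Strict):
    bin_width: float = Field(default=2.0, gt=0)


class RunConfig(_Strict):
    system: Union[MarcusSystemConfig, CustomSystemConfig] = Field(
        default_factory=MarcusSystemConfig, discriminator="kind"
    )
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    evb: EVBConfig
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _build_term(cfg: TermConfig):
    if isinstance(cfg, HarmonicTerm):
        return _t.Harmonic(cfg.k, cfg.x0, cfg.coord)
    if isinstance(cfg, MorseTerm):
        return _t.Morse(cfg.depth, cfg.a, cfg.x0, cfg.coord)
    if isinstance(cfg, BuckinghamTerm):
        return _t.BuckinghamRepulsion(cfg.a, cfg.b, cfg.coord)
    return _t.Constant(cfg.value, cfg.coord)


def build_system(cfg: RunConfig, params: Optional[EVBParameters] = None) -> DiabaticSystem:
    """Construct the DiabaticSystem described by a validated config."""
    if params is None:
        params = EVBParameters(
            h_ij=cfg.evb.h_ij if cfg.evb.h_ij is not None else 0.0,
            alpha=cfg.evb.alpha if cfg.evb.alpha is not None else 0.0,
        )
    s = cfg.system
    restraints = tuple(r.build() for r in s.restraints)
    if isinstance(s, MarcusSystemConfig):
        return make_marcus_system(
            s.k1, s.k2, s.x1, s.x2, s.delta_e, params, mass=s.mass, restraints=restraints
        )
    return DiabaticSystem(
        dimension=s.dimension,
        state1_terms=tuple(_build_term(t) for t in s.state1_terms),
        state2_terms=tuple(_build_term(t) for t in s.state2_terms),
        masses=np.asarray(s.masses, dtype=float),
        params=params,
        restraints=restraints,
    )
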