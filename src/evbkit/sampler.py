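"""Langevin sampling on the lambda mapping potentials.

The sampler drives a :class:`~evbkit.systems.DiabaticSystem` along a ladder
of mapping potentials ``(1-lam)*eps1 + lam*eps2`` (plus restraints) with a
BAOAB-split Langevin integrator, emulating the production protocol of an EVB
free-energy calculation: an equilibration ramp (temperature 1 K -> target,
time-step 0.1 -> 1 fs, restraints released), then one trajectory per
lambda frame at the production temperature, several independent replicas.

Determinism contract: a master seed fully determines every trajectory.
Replica ``r`` uses seed ``base_seed + r``; per-frame streams are derived from
it with ``numpy.random.SeedSequence`` spawn keys, so frames and replicas are
statistically independent but exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _kernels
from .constants import ACCEL_UNIT, BOLTZMANN_KCAL, thermal_energy
from .core import EVBParameters, mapping_energy
from .systems import DiabaticSystem

__all__ = [
    "LambdaSchedule",
    "FrameResult",
    "EquilibrationResult",
    "SampleSet",
    "run_frame",
    "equilibrate",
    "default_ramp",
    "run_ladder",
]

log = logging.getLogger(__name__)

SeedLike = Union[int, np.random.SeedSequence]


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda values, strictly increasing from 0 to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("schedule needs at least two lambda values")
        if v[0] != 0.0 or v[-1] != 1.0 or np.any(np.diff(v) <= 0):
            raise ValueError("lambda values must increase strictly from 0 to 1")
        object.__setattr__(self, "values", v)

    @classmethod
    def uniform(cls, n: int = 51) -> "LambdaSchedule":
        """Evenly spaced schedule with `n` frames (default 51)."""
        return cls(np.linspace(0.0, 1.0, n))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass
class FrameResult:
    """Saved samples of one lambda frame."""

    lam: float
    eps1: np.ndarray
    eps2: np.ndarray  # includes the alpha shift
    e_map: np.ndarray
    steps: np.ndarray
    x: np.ndarray  # (n_saved, dim)
    x_final: np.ndarray
    v_final: np.ndarray
    kinetic_temperature: float


@dataclass
class EquilibrationResult:
    x: np.ndarray
    v: np.ndarray
    kinetic_temperature: float  # averaged over the last stage


def _rng(seed: SeedLike) -> np.random.Generator:
    return np.random.default_rng(seed)


def run_frame(
    system: DiabaticSystem,
    lam: float,
    n_steps: int,
    dt: float = 1.0,
    temperature: float = 310.0,
    friction: float = 0.2,
    seed: SeedLike = 0,
    x0: Optional[np.ndarray] = None,
    v0: Optional[np.ndarray] = None,
    stride: int = 10,
    burn_in_frac: float = 0.2,
    restraint_scale: float = 1.0,
    params: Optional[EVBParameters] = None,
) -> FrameResult:
    """Integrate one lambda frame and return the saved samples.

    The trajectory runs on ``mapping_energy(eps1, eps2, lam)`` plus the
    (scaled) restraints.  The first ``burn_in_frac`` of the steps is
    discarded; afterwards the configuration and both diabatic energies are
    recorded every `stride` steps.  ``n_steps == 0`` returns only the
    initial configuration.  Identical inputs and seed give bit-identical
    output arrays.

    Raises
    ------
    RuntimeError
        If a coordinate or force becomes non-finite (particle escaped the
        domain), with the frame and step count in the message.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if dt <= 0 or temperature <= 0:
        raise ValueError("dt and temperature must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if not 0.0 <= burn_in_frac < 1.0:
        raise ValueError("burn_in_frac must lie in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if friction < 0:
        raise ValueError("friction must be >= 0")

    p = params if params is not None else system.params
    rng = _rng(seed)
    dim = system.dimension
    kT = thermal_energy(temperature)
    sigma_v = np.sqrt(kT * ACCEL_UNIT / system.masses)  # A/fs per coordinate

    x = np.array(system.state1_minimum() if x0 is None else x0, dtype=float).reshape(dim)
    v = (
        rng.standard_normal(dim) * sigma_v
        if v0 is None
        else np.array(v0, dtype=float).reshape(dim)
    )

    def _eval(xc: np.ndarray):
        e1 = float(system.eps1(xc[None, :])[0])
        e2 = float(system.eps2(xc[None, :], p)[0])
        return e1, e2

    if n_steps == 0:
        e1, e2 = _eval(x)
        return FrameResult(
            lam=lam,
            eps1=np.array([e1]),
            eps2=np.array([e2]),
            e_map=np.array([mapping_energy(e1, e2, lam)]),
            steps=np.array([0]),
            x=x[None, :].copy(),
            x_final=x.copy(),
            v_final=v.copy(),
            kinetic_temperature=float("nan"),
        )

    burn_in = int(burn_in_frac * n_steps)
    n_save = (n_steps - burn_in) // stride
    eps1_out = np.empty(n_save)
    eps2_out = np.empty(n_save)
    x_out = np.empty((n_save, dim))
    noise = rng.standard_normal((n_steps, dim))
    c1 = float(np.exp(-friction * dt))
    c2 = sigma_v * np.sqrt(1.0 - c1 * c1)

    (k1, p1, cc1), (k2, p2, cc2), (kr, pr, ccr) = system.encoded()
    n_saved, ke_sum, ke_n, ok = _kernels.baoab_frame(
        x,
        v,
        float(lam),
        k1,
        p1,
        cc1,
        k2,
        p2,
        cc2,
        float(p.alpha),
        kr,
        pr,
        ccr,
        float(restraint_scale),
        ACCEL_UNIT / system.masses,
        float(dt),
        c1,
        c2,
        int(n_steps),
        int(burn_in),
        int(stride),
        noise,
        eps1_out,
        eps2_out,
        x_out,
    )
    if not ok:
        raise RuntimeError(
            f"frame at lambda={lam:g} diverged (non-finite coordinate or force "
            f"after ~{n_saved * stride + burn_in} steps); the particle escaped the domain"
        )
    steps = burn_in + stride * np.arange(1, n_saved + 1)
    tkin = (ke_sum / ke_n) / BOLTZMANN_KCAL if ke_n else float("nan")
    eps1_out = eps1_out[:n_saved]
    eps2_out = eps2_out[:n_saved]
    return FrameResult(
        lam=lam,
        eps1=eps1_out,
        eps2=eps2_out,
        e_map=np.asarray(mapping_energy(eps1_out, eps2_out, lam)),
        steps=steps,
        x=x_out[:n_saved],
        x_final=x.copy(),
        v_final=v.copy(),
        kinetic_temperature=tkin,
    )


def default_ramp(target_t: float, n_stages: int = 6) -> List[Tuple[float, float, float]]:
    """Equilibration ramp: stages of (temperature K, dt fs, restraint scale).

    Temperature rises from 1 K to the target while the time-step grows from
    0.1 to 1 fs and tightened restraints are released back to unit scale.
    """
    ts = np.linspace(1.0, target_t, n_stages)
    dts = np.linspace(0.1, 1.0, n_stages)
    scales = np.linspace(10.0, 1.0, n_stages)
    return [(float(t), float(d), float(s)) for t, d, s in zip(ts, dts, scales)]


def equilibrate(
    system: DiabaticSystem,
    target_t: float,
    ramp: Optional[Sequence[Tuple[float, float, float]]] = None,
    seed: SeedLike = 0,
    steps_per_stage: int = 2000,
    friction: float = 0.2,
    params: Optional[EVBParameters] = None,
) -> EquilibrationResult:
    """Staged warm-up on the lambda=0 (reactant) surface.

    Each stage starts from the previous stage's final configuration.  Stage
    temperatures must be non-decreasing and end at `target_t`.
    """
    stages = list(ramp) if ramp is not None else default_ramp(target_t)
    temps = [s[0] for s in stages]
    if any(b < a for a, b in zip(temps, temps[1:])):
        raise ValueError("ramp temperatures must be non-decreasing")
    if temps[-1] != target_t:
        raise ValueError("ramp must end at the target temperature")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    x = system.state1_minimum()
    v = np.zeros(system.dimension)
    tkin = float("nan")
    for i, (t, dt, scale) in enumerate(stages):
        frame = run_frame(
            system,
            lam=0.0,
            n_steps=steps_per_stage,
            dt=dt,
            temperature=t,
            friction=friction,
            seed=np.random.SeedSequence(entropy=ss.entropy, spawn_key=(int(1e6) + i,)),
            x0=x,
            v0=v,
            stride=steps_per_stage,  # no intermediate saves needed
            burn_in_frac=0.0,
            restraint_scale=scale,
            params=params,
        )
        x, v, tkin = frame.x_final, frame.v_final, frame.kinetic_temperature
    return EquilibrationResult(x=x, v=v, kinetic_temperature=tkin)


@dataclass
class SampleSet:
    """Per-(replica, lambda-frame) records of (eps1, eps2, mapping energy).

    ``data`` has one row per saved sample with columns
    ``(replica, frame, lam, step, eps1, eps2, e_map)``; ``meta`` records the
    run settings (seed, temperature, dt, steps, stride, ...) and any replicas
    that diverged.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    COLUMNS = ("replica", "frame", "lam", "step", "eps1", "eps2", "e_map")

    @property
    def replicas(self) -> List[int]:
        return sorted(int(r) for r in self.data["replica"].unique())

    @property
    def lambdas(self) -> np.ndarray:
        return np.sort(self.data["lam"].unique())

    def for_replica(self, r: int) -> pd.DataFrame:
        return self.data[self.data["replica"] == r]

    def validate(self, atol: float = 1e-8) -> None:
        """Check the internal consistency contract of the records."""
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.meta.get("temperature", 1.0) <= 0:
            raise ValueError("temperature must be positive")
        expected = mapping_energy_rows(self.data)
        if not np.allclose(self.data["e_map"].to_numpy(), expected, atol=atol, rtol=0):
            raise ValueError("e_map records are inconsistent with (eps1, eps2, lambda)")

    # ---- persistence ---------------------------------------------------

    def to_dir(self, path) -> None:
        """One TSV per replica plus a JSON metadata sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for r in self.replicas:
            sub = self.for_replica(r).drop(columns=["replica"])
            sub.to_csv(path / f"samples_replica{r}.tsv", sep="\t", index=False)
        with open(path / "samples_meta.json", "w") as fh:
            json.dump({**self.meta, "replicas": self.replicas}, fh, indent=2)

    @classmethod
    def from_dir(cls, path) -> "SampleSet":
        path = Path(path)
        with open(path / "samples_meta.json") as fh:
            meta = json.load(fh)
        parts = []
        for r in meta.pop("replicas"):
            sub = pd.read_csv(path / f"samples_replica{r}.tsv", sep="\t")
            sub.insert(0, "replica", r)
            parts.append(sub)
        return cls(data=pd.concat(parts, ignore_index=True), meta=meta)


def mapping_energy_rows(df: pd.DataFrame) -> np.ndarray:
    lam = df["lam"].to_numpy()
    return (1.0 - lam) * df["eps1"].to_numpy() + lam * df["eps2"].to_numpy()


def run_ladder(
    system: DiabaticSystem,
    schedule: LambdaSchedule,
    n_replicas: int,
    n_steps: int = 10_000,
    dt: float = 1.0,
    temperature: float = 310.0,
    friction: float = 0.2,
    base_seed: int = 0,
    stride: int = 10,
    burn_in_frac: float = 0.2,
    params: Optional[EVBParameters] = None,
    equilibrate_first: bool = False,
) -> SampleSet:
    """Run the full lambda ladder for `n_replicas` independent replicas.

    Frames run in schedule order; within a replica each frame starts from the
    previous frame's final configuration so adjacent windows stay overlapped.
    Replica ``r`` uses seed ``base_seed + r``.  A diverged frame invalidates
    its replica (recorded in ``meta['failed_replicas']``); the other replicas
    are kept.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    rows = []
    failed: List[int] = []
    for r in range(n_replicas):
        rep_seed = base_seed + r
        ss = np.random.SeedSequence(rep_seed)
        if equilibrate_first:
            eq = equilibrate(system, temperature, seed=ss, friction=friction, params=params)
            x, v = eq.x, eq.v
        else:
            x, v = system.state1_minimum(), None
        rep_rows = []
        try:
            for m, lam in enumerate(schedule):
                frame = run_frame(
                    system,
                    lam=float(lam),
                    n_steps=n_steps,
                    dt=dt,
                    temperature=temperature,
                    friction=friction,
                    seed=np.random.SeedSequence(entropy=rep_seed, spawn_key=(m,)),
                    x0=x,
                    v0=v,
                    stride=stride,
                    burn_in_frac=burn_in_frac,
                    params=params,
                )
                x, v = frame.x_final, frame.v_final
                rep_rows.append(
                    pd.DataFrame(
                        {
                            "replica": r,
                            "frame": m,
                            "lam": frame.lam,
                            "step": frame.steps,
                            "eps1": frame.eps1,
                            "eps2": frame.eps2,
                            "e_map": frame.e_map,
                        }
                    )
                )
        except RuntimeError as exc:
            warnings.warn(f"replica {r} invalidated: {exc}")
            failed.append(r)
            continue
        rows.extend(rep_rows)
        log.debug("replica %d finished (%d frames)", r, len(schedule))
    if not rows:
        raise RuntimeError("all replicas diverged; no samples collected")
    meta = {
        "seed": base_seed,
        "temperature": temperature,
        "dt": dt,
        "n_steps": n_steps,
        "stride": stride,
        "burn_in_frac": burn_in_frac,
        "friction": friction,
        "n_lambda": len(schedule),
        "n_replicas": n_replicas,
        "failed_replicas": failed,
        "h_ij": (params or system.params).h_ij,
        "alpha": (params or system.params).alpha,
    }
    return SampleSet(data=pd.concat(rows, ignore_index=True), meta=meta)
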