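"""Kinetics layer: pKa corrections, Eyring--Polanyi conversions, pH model.

The rate-limiting cyclization of dopaquinone consumes a hydroxide ion and
requires a neutral amino group, so the observable activation free energy at
a given pH decomposes into a pH-independent chemical barrier plus the free
energy of supplying those two species:

    dG_OH  = kT ln10 (pKa_water - pH)      (forming OH- from bulk water)
    dG_NH2 = kT ln10 (pKa_amine - pH)      (deprotonating the ammonium group)

    dG_obs(pH) = dG_chem + dG_OH + dG_NH2

Combined with transition-state theory, k = (k_B T / h) exp(-dG_obs/kT),
this gives log10 k affine in pH with slope exactly +2 over the range where
both pKa terms apply (the carboxyl group, pKa 2.3, stays deprotonated near
physiological pH and contributes no term).

Two thermal-energy conventions coexist: the physical k_B*T computed from
the temperature (0.6163 kcal/mol at 310.15 K) and the conventional rounded
0.617 kcal/mol used in experimental-kinetics arithmetic; the
:class:`KineticContext` records which is active, because the familiar
printed corrections (11.79 and 1.01 kcal/mol at pH 7.4) are only recovered
with the rounded value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import LN10, T_37C, eyring_prefactor, thermal_energy

__all__ = [
    "KineticContext",
    "PHRateModel",
    "hydroxide_correction",
    "amine_correction",
    "composite_barrier",
    "intrinsic_barrier",
    "barrier_from_rate",
    "rate_from_barrier",
    "half_life",
    "format_half_life",
    "ph_barrier",
    "ph_rate",
    "ph_scan",
]

#: pKa of a water molecule in bulk water (experimental).
PKA_WATER = 15.7
#: pKa of the L-DOPA amino group (experimental).
PKA_AMINE = 8.11
#: pKa of the L-DOPA carboxyl group; deprotonated throughout the modelled
#: pH range, hence contributing no correction term.
PKA_CARBOXYL = 2.3


@dataclass(frozen=True)
class KineticContext:
    """Temperature, thermal energy, acid-dissociation constants and pH.

    ``kT`` defaults to the physical ``k_B * temperature``; pass an explicit
    value (e.g. the conventional 0.617 kcal/mol at 37 degC) to reproduce
    rounded experimental arithmetic.
    """

    temperature: float = T_37C
    kT: Optional[float] = None
    pKa_water: float = PKA_WATER
    pKa_amine: float = PKA_AMINE
    pH: float = 7.4

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.kT is None:
            object.__setattr__(self, "kT", thermal_energy(self.temperature))
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")

    def at_ph(self, ph: float) -> "KineticContext":
        return replace(self, pH=ph)


def hydroxide_correction(ctx: KineticContext) -> float:
    """Free energy of forming a hydroxide ion at the context pH (kcal/mol).

    ``kT ln10 (pKa_water - pH)``: 11.79 kcal/mol at pH 7.4 with kT = 0.617.
    """
    return ctx.kT * LN10 * (ctx.pKa_water - ctx.pH)


def amine_correction(ctx: KineticContext) -> float:
    """Free energy of deprotonating the amino group at the context pH.

    ``kT ln10 (pKa_amine - pH)``: 1.01 kcal/mol at pH 7.4 with kT = 0.617.
    """
    return ctx.kT * LN10 * (ctx.pKa_amine - ctx.pH)


def composite_barrier(chemical_barrier: float, corrections: Iterable[float]) -> float:
    """Observable activation free energy: chemical barrier plus corrections."""
    total = chemical_barrier + sum(corrections)
    if not math.isfinite(total):
        raise ValueError("barrier and corrections must be finite")
    return total


def intrinsic_barrier(observed_barrier: float, corrections: Iterable[float]) -> float:
    """Chemical barrier left after removing the pKa corrections (inverse of
    :func:`composite_barrier`)."""
    total = observed_barrier - sum(corrections)
    if not math.isfinite(total):
        raise ValueError("barrier and corrections must be finite")
    return total


def barrier_from_rate(k_rate: float, ctx: KineticContext) -> float:
    """Eyring--Polanyi activation free energy from a rate constant.

    ``dG = kT ln((k_B T / h) / k_rate)`` with transmission coefficient 1.
    """
    if k_rate <= 0:
        raise ValueError("rate constant must be positive")
    return ctx.kT * math.log(eyring_prefactor(ctx.temperature) / k_rate)


def rate_from_barrier(dg_act: float, ctx: KineticContext) -> float:
    """Eyring--Polanyi rate constant (s^-1) from an activation free energy."""
    if not math.isfinite(dg_act):
        raise ValueError("barrier must be finite")
    return eyring_prefactor(ctx.temperature) * math.exp(-dg_act / ctx.kT)


def half_life(k_rate: float) -> float:
    """First-order half-life ln(2)/k in seconds."""
    if k_rate <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(2.0) / k_rate


def format_half_life(seconds: float) -> str:
    """Human-readable half-life: hours above an hour, otherwise seconds."""
    if seconds >= 3600.0:
        return f"{seconds / 3600.0:.0f} h"
    if seconds >= 0.1:
        return f"{seconds:.1f} s"
    return f"{seconds:.2g} s"


@dataclass(frozen=True)
class PHRateModel:
    """Analytic pH dependence of the rate constant.

    ``intrinsic_barrier`` is the chemical barrier with hydroxide and neutral
    amine already available; the pH-dependent barrier adds both pKa terms,
    making ``log10 k(pH) = c + 2 pH`` with the offset ``c`` collecting every
    pH-independent quantity.
    """

    intrinsic_barrier: float
    context: KineticContext = field(default_factory=KineticContext)

    @classmethod
    def anchored(cls, observed_barrier: float, ctx: KineticContext) -> "PHRateModel":
        """Build the model from a barrier observed at the context's pH."""
        corr = [hydroxide_correction(ctx), amine_correction(ctx)]
        return cls(intrinsic_barrier=intrinsic_barrier(observed_barrier, corr), context=ctx)

    @property
    def c(self) -> float:
        """log10-rate offset: ``log10 k = c + 2 pH``."""
        ctx = self.context
        return (
            math.log10(eyring_prefactor(ctx.temperature))
            - self.intrinsic_barrier / (ctx.kT * LN10)
            - (ctx.pKa_water + ctx.pKa_amine)
        )


def _check_ph(model: PHRateModel, ph: float) -> None:
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    if ph > model.context.pKa_amine:
        warnings.warn(
            f"pH {ph:g} exceeds the amine pKa {model.context.pKa_amine:g}; the "
            "amine term is favourable there and the two-term model is outside "
            "its intended range"
        )


def ph_barrier(model: PHRateModel, ph: float) -> float:
    """pH-dependent activation free energy (kcal/mol)."""
    _check_ph(model, ph)
    ctx = model.context.at_ph(ph)
    return composite_barrier(
        model.intrinsic_barrier, [hydroxide_correction(ctx), amine_correction(ctx)]
    )


def ph_rate(model: PHRateModel, ph: float) -> float:
    """pH-dependent rate constant (s^-1); log10 affine in pH with slope 2."""
    return rate_from_barrier(ph_barrier(model, ph), model.context)


def ph_scan(model: PHRateModel, ph_grid: Sequence[float]) -> pd.DataFrame:
    """Tabulate (pH, dG_act, k, half-life) over a pH grid.

    The rate constant increases strictly with pH across any grid within the
    model domain.
    """
    rows = []
    for ph in np.asarray(ph_grid, dtype=float):
        dg = ph_barrier(model, float(ph))
        k = rate_from_barrier(dg, model.context)
        rows.append(
            {
                "pH": float(ph),
                "dG_act_kcal_mol": dg,
                "k_per_s": k,
                "half_life_s": half_life(k),
            }
        )
    return pd.DataFrame(rows)
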