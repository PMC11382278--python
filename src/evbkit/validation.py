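"""Cross-validation of the stochastic estimator against the exact oracle.

For any 1-D toy system the FEP/US profile can be checked bin by bin against
the deterministic quadrature profile on the same bins.  The comparison is
restricted to the reaction region -- bins between (and including) the two
basin minima -- because outer-wall bins beyond the minima are reached only
by rare excursions whose shared finite-sampling bias is invisible to
replica scatter and irrelevant to the reactant-to-product profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EVBParameters
from .free_energy import extract_thermo, us_profile
from .quadrature import exact_profile_quadrature
from .sampler import SampleSet
from .systems import DiabaticSystem

__all__ = ["OracleComparison", "compare_to_oracle"]


@dataclass(frozen=True)
class OracleComparison:
    """Bin-wise agreement summary between FEP/US and the quadrature oracle."""

    n_bins: int
    max_abs_dev: float  # kcal/mol
    max_z: float  # deviation in units of the per-bin SEM
    rms_z: float
    n_violations: int  # bins outside max(n_sigma*SEM, sem_floor)
    oracle_dg_act: float
    oracle_dg_rxn: float

    @property
    def consistent(self) -> bool:
        """True if every compared bin agreed within its tolerance."""
        return self.n_violations == 0


def compare_to_oracle(
    system: DiabaticSystem,
    samples: SampleSet,
    params: EVBParameters,
    kT: float,
    bin_width: float = 2.0,
    min_count: float = 20.0,
    n_sigma: float = 3.0,
    sem_floor: float = 0.1,
) -> OracleComparison:
    """Bin-wise FEP/US vs quadrature comparison over the reaction region.

    Compared bins must be populated in every replica with a pooled count of
    at least `min_count`.  A bin violates if its absolute deviation exceeds
    ``max(n_sigma * SEM, sem_floor)``; the floor (default 0.1 kcal/mol)
    keeps a simultaneous comparison over ~100 bins meaningful when
    individual SEMs, estimated from a handful of replicas, fluctuate low.
    """
    n_rep = len(samples.replicas)
    profile = us_profile(samples, params, kT, bin_width=bin_width, min_replicas=n_rep)
    oracle = exact_profile_quadrature(system, kT, profile.bin_edges, params=params)
    thermo = extract_thermo(oracle)
    lo, hi = sorted((thermo.reactant_gap, thermo.product_gap))
    sel = (
        profile.populated
        & oracle.populated
        & np.isfinite(profile.sem)
        & (profile.counts >= min_count)
        & (profile.centers >= lo)
        & (profile.centers <= hi)
    )
    if not sel.any():
        raise ValueError("no bins eligible for comparison")
    dev = profile.dg[sel] - oracle.dg[sel]
    z = dev / profile.sem[sel]
    tol = np.maximum(n_sigma * profile.sem[sel], sem_floor)
    return OracleComparison(
        n_bins=int(sel.sum()),
        max_abs_dev=float(np.abs(dev).max()),
        max_z=float(np.abs(z).max()),
        rms_z=float(np.sqrt(np.mean(z**2))),
        n_violations=int(np.sum(np.abs(dev) > tol)),
        oracle_dg_act=thermo.dg_act,
        oracle_dg_rxn=thermo.dg_rxn,
    )
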