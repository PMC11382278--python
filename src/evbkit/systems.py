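"""Desk-scale two-state reactive model systems.

A :class:`DiabaticSystem` holds two diabatic force fields (term lists over a
low-dimensional configuration), per-coordinate masses, a set of restraints
shared by both states, and the EVB parameters (coupling ``h_ij`` and
gas-phase shift ``alpha``).  The canonical toy is a Marcus-like pair of
harmonic diabats built by :func:`make_marcus_system`, a one-dimensional
surrogate for a proton-transfer/cyclization step.

Restraints follow the two kinds used for reactive anion pairs in explicit
simulation setups:

* flat-bottom distance restraint -- zero inside a window ``[lo, hi]``,
  harmonic ``1/2 k (r - bound)^2`` outside (continuously differentiable at
  the bounds);
* soft positional restraint -- ``1/2 k (x - target)^2``.

``alpha`` is applied to the state-2 energy in exactly one place,
:meth:`DiabaticSystem.eps2`; estimators downstream consume shifted energies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from . import terms as _t
from .core import EVBParameters, energy_gap, ground_state_energy

__all__ = [
    "RestraintSpec",
    "flat_bottom_energy",
    "DiabaticSystem",
    "make_marcus_system",
    "export_xyz",
]

FLAT_BOTTOM = "flat_bottom_distance"
POSITIONAL = "positional"


@dataclass(frozen=True)
class RestraintSpec:
    """A restraint acting on one coordinate.

    ``kind`` is ``"flat_bottom_distance"`` (needs ``lo < hi``) or
    ``"positional"`` (harmonic about ``target``).  ``force_constant`` is in
    kcal mol^-1 A^-2 under the 1/2 k dx^2 convention.
    """

    kind: str
    force_constant: float
    lo: Optional[float] = None
    hi: Optional[float] = None
    target: float = 0.0
    coord: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (FLAT_BOTTOM, POSITIONAL):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.kind == FLAT_BOTTOM:
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError("flat-bottom restraint requires lo < hi")

    def encode(self):
        if self.kind == FLAT_BOTTOM:
            return _t.KIND_FLAT_BOTTOM, (self.force_constant, self.lo, self.hi), self.coord
        return _t.KIND_HARMONIC, (self.force_constant, self.target, 0.0), self.coord


def flat_bottom_energy(r, spec: RestraintSpec):
    """Flat-bottom distance-restraint energy at distance(s) ``r`` (A).

    Zero inside ``[spec.lo, spec.hi]``; ``1/2 k (r - nearest bound)^2``
    outside.  Continuous with continuous derivative at both bounds.
    """
    if spec.kind != FLAT_BOTTOM:
        raise ValueError("spec must be a flat_bottom_distance restraint")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distances must be positive")
    below = np.minimum(r_arr - spec.lo, 0.0)
    above = np.maximum(r_arr - spec.hi, 0.0)
    out = 0.5 * spec.force_constant * (below**2 + above**2)
    return out if out.ndim else float(out)


def _restraint_energy_vec(x: np.ndarray, restraints: Sequence[RestraintSpec]) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    e = np.zeros(x.shape[0])
    for spec in restraints:
        xi = x[:, spec.coord]
        if spec.kind == FLAT_BOTTOM:
            below = np.minimum(xi - spec.lo, 0.0)
            above = np.maximum(xi - spec.hi, 0.0)
            e += 0.5 * spec.force_constant * (below**2 + above**2)
        else:
            e += 0.5 * spec.force_constant * (xi - spec.target) ** 2
    return e


@dataclass(frozen=True)
class DiabaticSystem:
    """Two diabatic potential surfaces over a low-dimensional configuration."""

    dimension: int
    state1_terms: Tuple
    state2_terms: Tuple
    masses: np.ndarray
    params: EVBParameters
    restraints: Tuple[RestraintSpec, ...] = ()
    #: optional sampling/integration box per coordinate, (lo, hi) pairs
    domain: Optional[Tuple[Tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        masses = np.asarray(self.masses, dtype=float)
        if masses.shape != (self.dimension,) or np.any(masses <= 0):
            raise ValueError("masses must be positive, one per coordinate")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "state1_terms", tuple(self.state1_terms))
        object.__setattr__(self, "state2_terms", tuple(self.state2_terms))
        object.__setattr__(self, "restraints", tuple(self.restraints))

    # ---- energy evaluation (batch, numpy path) -------------------------

    def eps1(self, x) -> np.ndarray:
        """State-1 (reactant) diabatic energy at configurations ``x[n, dim]``."""
        return _t.terms_energy(x, self.state1_terms)

    def eps2(self, x, params: Optional[EVBParameters] = None) -> np.ndarray:
        """State-2 (product) diabatic energy including the alpha shift."""
        p = params if params is not None else self.params
        return _t.terms_energy(x, self.state2_terms) + p.alpha

    def gap(self, x, params: Optional[EVBParameters] = None) -> np.ndarray:
        """Energy-gap coordinate eps2 - eps1 at ``x``."""
        return energy_gap(self.eps1(x), self.eps2(x, params))

    def ground_state(self, x, params: Optional[EVBParameters] = None) -> np.ndarray:
        p = params if params is not None else self.params
        return ground_state_energy(self.eps1(x), self.eps2(x, p), p)

    def restraint_energy(self, x, scale: float = 1.0) -> np.ndarray:
        return scale * _restraint_energy_vec(x, self.restraints)

    def with_params(self, params: EVBParameters) -> "DiabaticSystem":
        return replace(self, params=params)

    # ---- geometry ------------------------------------------------------

    def _minimize(self, term_lists, x0: np.ndarray) -> np.ndarray:
        def f(x):
            e = sum(float(_t.terms_energy(x, tl)[0]) for tl in term_lists)
            return e + float(self.restraint_energy(x)[0])

        res = optimize.minimize(f, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        return np.asarray(res.x, dtype=float)

    def _grid_start(self, term_lists) -> np.ndarray:
        box = self.domain or ((-10.0, 10.0),) * self.dimension
        axes = [np.linspace(lo, hi, 201) for lo, hi in box]
        grid = np.stack([a.ravel() for a in np.meshgrid(*axes, indexing="ij")], axis=1)
        e = sum(_t.terms_energy(grid, tl) for tl in term_lists) + self.restraint_energy(grid)
        return grid[int(np.argmin(e))]

    def state1_minimum(self) -> np.ndarray:
        """Location of the restrained state-1 minimum (the reactant start)."""
        tl = [self.state1_terms]
        return self._minimize(tl, self._grid_start(tl))

    def state2_minimum(self) -> np.ndarray:
        tl = [self.state2_terms]
        return self._minimize(tl, self._grid_start(tl))

    def default_domain(self) -> Tuple[Tuple[float, float], ...]:
        """Integration box: [-5, +6] A around the span of the two minima."""
        if self.domain is not None:
            return self.domain
        m1 = self.state1_minimum()
        m2 = self.state2_minimum()
        lo = np.minimum(m1, m2) - 5.0
        hi = np.maximum(m1, m2) + 6.0
        return tuple((float(a), float(b)) for a, b in zip(lo, hi))

    # ---- kernel encoding -----------------------------------------------

    def encoded(self):
        """Flat-array encoding of both states and the restraints for the kernels."""
        k1, p1, c1 = _t.encode_terms(self.state1_terms)
        k2, p2, c2 = _t.encode_terms(self.state2_terms)
        if self.restraints:
            kr = np.array([s.encode()[0] for s in self.restraints], dtype=np.int64)
            pr = np.array([s.encode()[1] for s in self.restraints], dtype=np.float64)
            cr = np.array([s.encode()[2] for s in self.restraints], dtype=np.int64)
        else:
            kr = np.zeros(0, dtype=np.int64)
            pr = np.zeros((0, 3), dtype=np.float64)
            cr = np.zeros(0, dtype=np.int64)
        return (k1, p1, c1), (k2, p2, c2), (kr, pr, cr)


def make_marcus_system(
    k1: float,
    k2: float,
    x1: float,
    x2: float,
    delta_e: float,
    params: EVBParameters,
    mass: float = 12.0,
    restraints: Sequence[RestraintSpec] = (),
) -> DiabaticSystem:
    """One-dimensional Marcus-like pair of harmonic diabats.

    eps1 = 1/2 k1 (x - x1)^2 and eps2 = 1/2 k2 (x - x2)^2 + delta_e + alpha,
    a surrogate for a proton-transfer surface: two displaced wells whose
    crossing is lowered by the off-diagonal coupling.  ``delta_e`` is the bare
    diabatic asymmetry; the calibrated shift alpha comes from ``params``.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("force constants must be positive")
    if x1 == x2:
        raise ValueError("the two minima must be distinct")
    return DiabaticSystem(
        dimension=1,
        state1_terms=(_t.Harmonic(k1, x1),),
        state2_terms=(_t.Harmonic(k2, x2), _t.Constant(delta_e)),
        masses=np.array([mass], dtype=float),
        params=params,
        restraints=tuple(restraints),
    )


def export_xyz(system: DiabaticSystem, x: np.ndarray, path, comment: str = "evbkit toy geometry") -> None:
    """Write a toy configuration as XYZ (one dummy atom per coordinate, on the x-axis)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"{system.dimension}\n{comment}\n")
        for xi in x:
            fh.write(f"X {xi:.6f} 0.000000 0.000000\n")
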