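"""Two-state empirical valence bond (EVB) Hamiltonian kernel.

A reactive event is represented as resonance between two diabatic valence
states: state 1 carries the bonding pattern of the reactants with force-field
energy ``eps1``, state 2 that of the products with energy ``eps2``.  The
adiabatic ground state is the lower eigenvalue of the 2x2 matrix

.. math::

    H = \\begin{pmatrix} \\varepsilon_1 & H_{ij} \\\\
                         H_{ij} & \\varepsilon_2 \\end{pmatrix}

so that

.. math::

    E_g = \\tfrac12(\\varepsilon_1+\\varepsilon_2)
        - \\tfrac12\\sqrt{(\\varepsilon_1-\\varepsilon_2)^2 + 4 H_{ij}^2}.

Sampling is driven on the *mapping potential*, the linear mix
``(1-lam)*eps1 + lam*eps2`` that carries the system from reactants (``lam=0``)
to products (``lam=1``), and free-energy profiles are resolved on the
*energy-gap* reaction coordinate ``eps2 - eps1``.

Conventions fixed here and used everywhere else:

* the gap is ``eps2 - eps1`` (state 2 minus state 1), so the reactant basin,
  where state 1 is the lower diabat, sits at positive gap;
* the gas-phase shift ``alpha`` is a property of :class:`EVBParameters` and
  is added to the state-2 energy by the *system* at evaluation time
  (see :mod:`evbkit.systems`); estimators receive ``eps2`` already shifted
  and never apply ``alpha`` themselves.

All energies are in kcal mol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "EVBParameters",
    "DiabaticPair",
    "mapping_energy",
    "ground_state_energy",
    "energy_gap",
]


@dataclass(frozen=True)
class EVBParameters:
    """Empirical parameters of the two-state Hamiltonian.

    Parameters
    ----------
    h_ij:
        Off-diagonal coupling element, kcal mol^-1.  Only ``h_ij**2`` enters
        the ground-state energy, so the sign convention is ``h_ij >= 0``.
    alpha:
        Gas-phase shift added to the state-2 (product) diabatic energy,
        kcal mol^-1.  Calibrated so the surface reproduces reference
        quantum-chemical energetics.
    """

    h_ij: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.h_ij) and np.isfinite(self.alpha)):
            raise ValueError("EVB parameters must be finite")
        if self.h_ij < 0:
            raise ValueError(f"h_ij must be non-negative, got {self.h_ij}")


class DiabaticPair(NamedTuple):
    """A pair of diabatic energies at one configuration (state 2 includes alpha)."""

    eps1: float
    eps2: float


ArrayLike = Union[float, np.ndarray]


def mapping_energy(eps1: ArrayLike, eps2: ArrayLike, lam: float) -> ArrayLike:
    """Linear mapping potential ``(1 - lam) * eps1 + lam * eps2``.

    Parameters
    ----------
    eps1, eps2:
        Diabatic energies (scalars or broadcastable arrays), kcal mol^-1.
    lam:
        Coupling parameter in [0, 1]; 0 is the pure reactant force field,
        1 the pure product force field.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return (1.0 - lam) * np.asarray(eps1) + lam * np.asarray(eps2)


def ground_state_energy(
    eps1: ArrayLike, eps2: ArrayLike, params: Union[EVBParameters, float]
) -> ArrayLike:
    """Adiabatic ground-state energy: lower eigenvalue of the 2x2 EVB matrix.

    ``params`` may be an :class:`EVBParameters` (only ``h_ij`` is used; the
    shift is assumed to be already contained in ``eps2``) or a bare coupling
    value.  Satisfies ``E_g <= min(eps1, eps2)`` with equality iff
    ``h_ij == 0``, and is symmetric under ``eps1 <-> eps2``.
    """
    h = params.h_ij if isinstance(params, EVBParameters) else float(params)
    if h < 0:
        raise ValueError(f"h_ij must be non-negative, got {h}")
    e1 = np.asarray(eps1, dtype=float)
    e2 = np.asarray(eps2, dtype=float)
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))):
        raise ValueError("diabatic energies must be finite")
    out = 0.5 * (e1 + e2) - 0.5 * np.hypot(e1 - e2, 2.0 * h)
    return out if out.ndim else float(out)


def energy_gap(eps1: ArrayLike, eps2: ArrayLike) -> ArrayLike:
    """Energy-gap reaction coordinate ``eps2 - eps1`` (state 2 minus state 1)."""
    out = np.asarray(eps2, dtype=float) - np.asarray(eps1, dtype=float)
    return out if out.ndim else float(out)
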