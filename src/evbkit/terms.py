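"""Potential-energy terms for the diabatic force fields.

Each term acts on one coordinate of a low-dimensional configuration vector.
Coordinates are distance-like (angstrom); terms are the building blocks the
toy reactive systems are assembled from:

* :class:`Harmonic` -- bond/well term ``1/2 k (x - x0)^2``
* :class:`Morse` -- anharmonic well ``D (1 - exp(-a (x - x0)))^2``
* :class:`BuckinghamRepulsion` -- exponential wall ``A exp(-b x)`` replacing
  the r^-12 repulsion for close reactive contacts
* :class:`Constant` -- energy offset (e.g. a diabatic asymmetry)

The harmonic prefactor convention is ``1/2 k (dx)^2`` everywhere, including
restraints; force constants quoted in kcal mol^-1 A^-2 are interpreted under
this convention.

Terms are compiled to flat arrays (`encode_terms`) consumed by the jitted
dynamics kernels in :mod:`evbkit._kernels`; the vectorized reference
implementation here (`terms_energy`) is used by the quadrature oracle and in
tests that cross-check the two paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "Harmonic",
    "Morse",
    "BuckinghamRepulsion",
    "Constant",
    "encode_terms",
    "terms_energy",
    "terms_gradient",
]

# integer kind codes shared with the jitted kernels
KIND_HARMONIC = 0
KIND_MORSE = 1
KIND_BUCKINGHAM = 2
KIND_FLAT_BOTTOM = 3  # used by restraints (systems.py)
KIND_CONSTANT = 4


@dataclass(frozen=True)
class Harmonic:
    """``1/2 k (x - x0)^2`` on coordinate `coord`."""

    k: float
    x0: float
    coord: int = 0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError(f"harmonic force constant must be >= 0, got {self.k}")

    def encode(self) -> Tuple[int, Tuple[float, float, float], int]:
        return KIND_HARMONIC, (self.k, self.x0, 0.0), self.coord


@dataclass(frozen=True)
class Morse:
    """``D (1 - exp(-a (x - x0)))^2`` on coordinate `coord`."""

    depth: float
    a: float
    x0: float
    coord: int = 0

    def __post_init__(self):
        if self.depth < 0 or self.a <= 0:
            raise ValueError("Morse well requires depth >= 0 and a > 0")

    def encode(self):
        return KIND_MORSE, (self.depth, self.a, self.x0), self.coord


@dataclass(frozen=True)
class BuckinghamRepulsion:
    """``A exp(-b x)`` on coordinate `coord` (x treated as a distance, x > 0)."""

    a: float
    b: float
    coord: int = 0

    def __post_init__(self):
        if self.a < 0 or self.b <= 0:
            raise ValueError("Buckingham repulsion requires A >= 0 and b > 0")

    def encode(self):
        return KIND_BUCKINGHAM, (self.a, self.b, 0.0), self.coord


@dataclass(frozen=True)
class Constant:
    """Constant energy offset (kcal mol^-1)."""

    value: float
    coord: int = 0

    def encode(self):
        return KIND_CONSTANT, (self.value, 0.0, 0.0), self.coord


def encode_terms(terms: Sequence) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack a term list into (kinds, params[n,3], coords) arrays for the kernels."""
    n = len(terms)
    kinds = np.zeros(n, dtype=np.int64)
    params = np.zeros((n, 3), dtype=np.float64)
    coords = np.zeros(n, dtype=np.int64)
    for i, t in enumerate(terms):
        kind, p, c = t.encode()
        kinds[i] = kind
        params[i] = p
        coords[i] = c
    return kinds, params, coords


def terms_energy(x: np.ndarray, terms: Sequence) -> np.ndarray:
    """Vectorized total energy of `terms` at configurations ``x[n, dim]``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    e = np.zeros(x.shape[0])
    for t in terms:
        xi = x[:, t.coord]
        if isinstance(t, Harmonic):
            e += 0.5 * t.k * (xi - t.x0) ** 2
        elif isinstance(t, Morse):
            e += t.depth * (1.0 - np.exp(-t.a * (xi - t.x0))) ** 2
        elif isinstance(t, BuckinghamRepulsion):
            e += t.a * np.exp(-t.b * xi)
        elif isinstance(t, Constant):
            e += t.value
        else:  # pragma: no cover
            raise TypeError(f"unknown term {t!r}")
    return e


def terms_gradient(x: np.ndarray, terms: Sequence) -> np.ndarray:
    """Vectorized gradient dE/dx of `terms` at configurations ``x[n, dim]``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    g = np.zeros_like(x)
    for t in terms:
        xi = x[:, t.coord]
        if isinstance(t, Harmonic):
            g[:, t.coord] += t.k * (xi - t.x0)
        elif isinstance(t, Morse):
            ex = np.exp(-t.a * (xi - t.x0))
            g[:, t.coord] += 2.0 * t.depth * t.a * ex * (1.0 - ex)
        elif isinstance(t, BuckinghamRepulsion):
            g[:, t.coord] += -t.a * t.b * np.exp(-t.b * xi)
        elif isinstance(t, Constant):
            pass
        else:  # pragma: no cover
            raise TypeError(f"unknown term {t!r}")
    return g
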