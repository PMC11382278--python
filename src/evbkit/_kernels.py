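"""Jitted scalar kernels for Langevin dynamics on the mapping potential.

These loops are compiled with numba when available and fall back to plain
Python otherwise (same code path, much slower).  The vectorized reference
implementation of the same term energies lives in :mod:`evbkit.terms`;
agreement between the two paths is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


# kind codes; must match evbkit.terms
_HARMONIC = 0
_MORSE = 1
_BUCKINGHAM = 2
_FLAT_BOTTOM = 3
_CONSTANT = 4


@njit(cache=False)
def _energy(x, kinds, params, coords):
    e = 0.0
    for i in range(kinds.shape[0]):
        xi = x[coords[i]]
        k = kinds[i]
        if k == _HARMONIC:
            d = xi - params[i, 1]
            e += 0.5 * params[i, 0] * d * d
        elif k == _MORSE:
            ex = math.exp(-params[i, 1] * (xi - params[i, 2]))
            e += params[i, 0] * (1.0 - ex) * (1.0 - ex)
        elif k == _BUCKINGHAM:
            e += params[i, 0] * math.exp(-params[i, 1] * xi)
        elif k == _FLAT_BOTTOM:
            lo = params[i, 1]
            hi = params[i, 2]
            if xi < lo:
                d = xi - lo
                e += 0.5 * params[i, 0] * d * d
            elif xi > hi:
                d = xi - hi
                e += 0.5 * params[i, 0] * d * d
        elif k == _CONSTANT:
            e += params[i, 0]
    return e


@njit(cache=False)
def _grad_accum(x, kinds, params, coords, scale, g):
    for i in range(kinds.shape[0]):
        c = coords[i]
        xi = x[c]
        k = kinds[i]
        if k == _HARMONIC:
            g[c] += scale * params[i, 0] * (xi - params[i, 1])
        elif k == _MORSE:
            ex = math.exp(-params[i, 1] * (xi - params[i, 2]))
            g[c] += scale * 2.0 * params[i, 0] * params[i, 1] * ex * (1.0 - ex)
        elif k == _BUCKINGHAM:
            g[c] += -scale * params[i, 0] * params[i, 1] * math.exp(-params[i, 1] * xi)
        elif k == _FLAT_BOTTOM:
            lo = params[i, 1]
            hi = params[i, 2]
            if xi < lo:
                g[c] += scale * params[i, 0] * (xi - lo)
            elif xi > hi:
                g[c] += scale * params[i, 0] * (xi - hi)
        # constants carry no force
    return g


@njit(cache=False)
def baoab_frame(
    x,
    v,
    lam,
    kinds1,
    params1,
    coords1,
    kinds2,
    params2,
    coords2,
    alpha,
    kinds_r,
    params_r,
    coords_r,
    restraint_scale,
    inv_mass_acc,  # ACCEL_UNIT / mass, per coordinate
    dt,
    c1,
    c2,  # OU coefficients: v <- c1*v + c2*xi, per coordinate
    n_steps,
    burn_in,
    stride,
    noise,  # (n_steps, dim) standard normals
    eps1_out,
    eps2_out,
    x_out,  # (n_save, dim)
):
    """BAOAB Langevin integration of one lambda frame.

    Mutates ``x`` and ``v`` in place; fills the output arrays with the
    diabatic energies and configurations saved every `stride` steps after
    the first `burn_in` steps.  Returns ``(n_saved, kinetic_temperature_sum,
    kinetic_samples, ok)`` where ``ok`` is False if the trajectory diverged
    (non-finite coordinate or force).
    """
    dim = x.shape[0]
    g = np.zeros(dim)
    g[:] = 0.0
    _grad_accum(x, kinds1, params1, coords1, 1.0 - lam, g)
    _grad_accum(x, kinds2, params2, coords2, lam, g)
    _grad_accum(x, kinds_r, params_r, coords_r, restraint_scale, g)
    n_saved = 0
    ke_sum = 0.0
    ke_n = 0
    for step in range(n_steps):
        for d in range(dim):
            v[d] -= 0.5 * dt * g[d] * inv_mass_acc[d]
            x[d] += 0.5 * dt * v[d]
            v[d] = c1 * v[d] + c2[d] * noise[step, d]
            x[d] += 0.5 * dt * v[d]
        for d in range(dim):
            g[d] = 0.0
        _grad_accum(x, kinds1, params1, coords1, 1.0 - lam, g)
        _grad_accum(x, kinds2, params2, coords2, lam, g)
        _grad_accum(x, kinds_r, params_r, coords_r, restraint_scale, g)
        ok = True
        for d in range(dim):
            v[d] -= 0.5 * dt * g[d] * inv_mass_acc[d]
            if not (np.isfinite(x[d]) and np.isfinite(g[d])):
                ok = False
        if not ok:
            return n_saved, ke_sum, ke_n, False
        if step >= burn_in:
            for d in range(dim):
                # v**2 / (ACCEL_UNIT/m) = m v**2 / ACCEL_UNIT, in kcal/mol
                ke_sum += v[d] * v[d] / inv_mass_acc[d]
            ke_n += dim
            if (step - burn_in + 1) % stride == 0 and n_saved < eps1_out.shape[0]:
                eps1_out[n_saved] = _energy(x, kinds1, params1, coords1)
                eps2_out[n_saved] = _energy(x, kinds2, params2, coords2) + alpha
                for d in range(dim):
                    x_out[n_saved, d] = x[d]
                n_saved += 1
    return n_saved, ke_sum, ke_n, True
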