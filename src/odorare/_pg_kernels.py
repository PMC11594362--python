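"""Scalar Devroye kernels for PG(1, z), JIT-compiled when numba is present.

Same algorithm as :mod:`odorare.pg`'s vectorized sampler; the scalar loop
compiled with numba is substantially faster for the batch sizes a
community-model update needs, and both implementations share the numpy
Generator bit stream, so either path is deterministic under a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


_T = 0.64
_SQRT_T = math.sqrt(_T)


@njit(cache=True)
def _phi(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss_cdf(c: float) -> float:
    # CDF at t of inverse-Gaussian(1/c, 1); c = 0 is the Levy limit
    a = 1.0 / _SQRT_T
    if c <= 0.0:
        return 2.0 * _phi(-a)
    arg = 2.0 * c
    if arg > 700.0:
        return _phi(a * (_T * c - 1.0))
    return _phi(a * (_T * c - 1.0)) + math.exp(arg) * _phi(-a * (_T * c + 1.0))


@njit(cache=True)
def _trunc_invgauss(gen, c: float) -> float:
    if c < 1.0 / _T:
        while True:
            e1 = gen.exponential()
            e2 = gen.exponential()
            if e1 * e1 <= 2.0 * e2 / _T:
                x = _T / (1.0 + _T * e1) ** 2
                if gen.random() <= math.exp(-c * c * x / 2.0):
                    return x
    else:
        mu = 1.0 / c
        while True:
            y = gen.standard_normal() ** 2
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if gen.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= _T:
                return x


@njit(cache=True)
def _a_n(n: int, x: float) -> float:
    nph = n + 0.5
    if x <= _T:
        return math.pi * nph * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * nph * nph / x)
    return math.pi * nph * math.exp(-nph * nph * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _jstar_single(gen, c: float) -> float:
    k = math.pi * math.pi / 8.0 + c * c / 2.0
    p_right = (math.pi / (2.0 * k)) * math.exp(-k * _T)
    mass_left = 2.0 * math.exp(-c) * _pigauss_cdf(c)
    ratio = p_right / (p_right + mass_left)
    while True:
        if gen.random() < ratio:
            x = _T + gen.exponential() / k
        else:
            x = _trunc_invgauss(gen, c)
        s = _a_n(0, x)
        y = gen.random() * s
        n = 0
        accept = False
        decided = False
        while not decided:
            n += 1
            if n > 200:
                accept = True
                break
            term = _a_n(n, x)
            if n % 2 == 1:
                s -= term
                if y <= s:
                    accept = True
                    decided = True
            else:
                s += term
                if y > s:
                    decided = True
        if accept:
            return x


@njit(cache=True)
def pg1_batch(gen, z: np.ndarray, out: np.ndarray) -> None:
    for i in range(z.shape[0]):
        out[i] = _jstar_single(gen, abs(z[i]) / 2.0) / 4.0
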