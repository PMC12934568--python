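"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they check: the spherical-harmonic
basis is rebuilt from associated-Legendre recurrences, trilinear sampling
as a literal eight-corner weighted sum, and the Mann-Whitney test by full
enumeration of group assignments with direct pair counting.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def legendre_assoc(l: int, m: int, x: float) -> float:
    """Associated Legendre P_l^m(x) with the Condon-Shortley phase, from the
    standard recurrences (no library call)."""
    pmm = 1.0
    if m > 0:
        somx2 = math.sqrt((1.0 - x) * (1.0 + x))
        fact = 1.0
        for _ in range(m):
            pmm *= -fact * somx2
            fact += 2.0
    if l == m:
        return pmm
    pmmp1 = x * (2.0 * m + 1.0) * pmm
    if l == m + 1:
        return pmmp1
    pll = 0.0
    for ll in range(m + 2, l + 1):
        pll = (x * (2.0 * ll - 1.0) * pmmp1 - (ll + m - 1.0) * pmm) / (ll - m)
        pmm, pmmp1 = pmmp1, pll
    return pll


def real_sh_oracle(sh_order: int, direction: np.ndarray) -> np.ndarray:
    """Row of the real symmetric SH basis at one unit direction.

    Convention mirrored from the package's documented basis: complex
    Y_l^m = N_lm P_l^m(cos theta) e^{i m phi} with the Condon-Shortley
    phase inside P; entries are sqrt(2) Re(Y_l^|m|) for m < 0, Y_l^0 for
    m = 0, sqrt(2) Im(Y_l^m) for m > 0; even degrees only.
    """
    x, y, z = direction / np.linalg.norm(direction)
    theta = math.acos(max(-1.0, min(1.0, z)))
    phi = math.atan2(y, x)
    out = []
    for l in range(0, sh_order + 1, 2):
        for m in range(-l, l + 1):
            am = abs(m)
            norm = math.sqrt(
                (2 * l + 1) / (4 * math.pi) * math.factorial(l - am) / math.factorial(l + am)
            )
            p = legendre_assoc(l, am, math.cos(theta))
            if m < 0:
                out.append(math.sqrt(2.0) * norm * p * math.cos(am * phi))
            elif m == 0:
                out.append(norm * p)
            else:
                out.append(math.sqrt(2.0) * norm * p * math.sin(am * phi))
    return np.asarray(out)


def trilinear_oracle(values: np.ndarray, index: np.ndarray) -> float:
    """Literal eight-corner weighted sum at a continuous voxel index."""
    base = np.floor(index).astype(int)
    base = np.minimum(base, np.asarray(values.shape[:3]) - 2)
    base = np.maximum(base, 0)
    f = index - base
    total = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (f[0] if di else 1 - f[0])
                    * (f[1] if dj else 1 - f[1])
                    * (f[2] if dk else 1 - f[2])
                )
                total += w * values[base[0] + di, base[1] + dj, base[2] + dk]
    return total


def mwu_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U statistic by direct pair counting; exact two-sided p by enumerating
    every assignment of the pooled values into groups of sizes (n_a, n_b)."""

    def u_of(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    u_obs = u_of(a, b)
    mu = n1 * n2 / 2.0
    hits = total = 0
    idx_all = set(range(n1 + n2))
    for combo in itertools.combinations(range(n1 + n2), n1):
        ga = pooled[list(combo)]
        gb = pooled[sorted(idx_all - set(combo))]
        u = u_of(ga, gb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total
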