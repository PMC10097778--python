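"""Symmetric quadrature rules on the reference tetrahedron and triangle.

Tetrahedron rules are Grundmann–Möller cones rules of odd degree 2s+1,
generated programmatically; they are exact for polynomials of that degree
on the simplex (some weights are negative, which is harmless here).
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np


def _compositions(total: int, parts: int):
    """All multi-indices beta with |beta| = total and len(beta) = parts."""
    for cuts in combinations_with_replacement(range(total + 1), parts - 1):
        prev = 0
        comp = []
        for c in cuts:
            comp.append(c - prev)
            prev = c
        comp.append(total - prev)
        yield tuple(comp)


@lru_cache(maxsize=None)
def grundmann_moller(s: int, dim: int = 3):
    """Points (barycentric) and weights of the GM rule of degree 2s+1.

    Weights are scaled so that they sum to the reference-simplex volume
    1/dim!.
    """
    n = dim
    d = 2 * s + 1
    pts, wts = [], []
    for i in range(s + 1):
        w = ((-1) ** i * 2.0 ** (-2 * s) * (d + n - 2 * i) ** d
             / (math.factorial(i) * math.factorial(d + n - i)))
        denom = d + n - 2 * i
        for beta in _compositions(s - i, n + 1):
            pts.append([(2 * b + 1) / denom for b in beta])
            wts.append(w)
    pts = np.array(pts)
    wts = np.array(wts)
    wts *= (1.0 / math.factorial(n)) / wts.sum()
    return pts, wts


# 14-point degree-5 rule on the tetrahedron (two vertex-type orbits plus
# one edge-type orbit); all weights positive, unlike the GM family, which
# matters for the stability of stiffness assembly
_A1 = 0.31088591926330060980
_A2 = 0.09273525031089122640
_B3 = 0.04550370412564964949
_W1 = 0.11268792571801585080
_W2 = 0.07349304311636194954
_W3 = 0.04254602077708146643


def _tet14():
    pts, wts = [], []
    for a, w in ((_A1, _W1), (_A2, _W2)):
        for i in range(4):
            lam = [a] * 4
            lam[i] = 1.0 - 3.0 * a
            pts.append(lam)
            wts.append(w)
    seen = set()
    for i in range(4):
        for j in range(i + 1, 4):
            lam = [0.5 - _B3] * 4
            lam[i] = _B3
            lam[j] = _B3
            pts.append(lam)
            wts.append(_W3)
    pts = np.array(pts)
    wts = np.array(wts)
    wts *= (1.0 / 6.0) / wts.sum()
    return pts, wts


_TET14 = _tet14()


def tet_rule(degree: int = 5):
    """(points, weights): barycentric points on the reference tetrahedron.

    Degrees up to 5 use the positive-weight 14-point rule; higher degrees
    fall back to Grundmann–Möller.
    """
    if degree <= 5:
        return _TET14[0].copy(), _TET14[1].copy()
    return grundmann_moller(math.ceil((degree - 1) / 2), 3)


# 6-point degree-4 Dunavant rule on the reference triangle (barycentric)
_TRI4_BARY = np.array([
    [0.816847572980459, 0.091576213509771, 0.091576213509771],
    [0.091576213509771, 0.816847572980459, 0.091576213509771],
    [0.091576213509771, 0.091576213509771, 0.816847572980459],
    [0.108103018168070, 0.445948490915965, 0.445948490915965],
    [0.445948490915965, 0.108103018168070, 0.445948490915965],
    [0.445948490915965, 0.445948490915965, 0.108103018168070],
])
_TRI4_W = np.array([0.109951743655322, 0.109951743655322, 0.109951743655322,
                    0.223381589678011, 0.223381589678011, 0.223381589678011]) / 2.0


def triangle_rule():
    """(barycentric points, weights) of a degree-4 rule; weights sum to 1/2."""
    return _TRI4_BARY.copy(), _TRI4_W.copy()
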