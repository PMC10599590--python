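"""Design-quality metrics: spread and wrap-around L2 discrepancy.

The wrap-around L2 discrepancy measures non-uniformity of a point set on the
torus-wrapped unit cube and has the closed form

    W2^2 = -(4/3)^k + (1/N^2) sum_n sum_m prod_i (3/2 - |d_i|(1 - |d_i|)),

with d_i the coordinate difference between points n and m. Both the spread D
of a design's blocks and W2^2 of its points are also reported in scaled form
so values are comparable across (k, r): D is divided by the number of terms
in its definition times the scale of a squared block distance, and W2^2 by
(k+1) times the expected squared discrepancy of a uniform random sample of
the same size, E[W2^2(U_N)] = ((3/2)^k - (4/3)^k)/N.
"""

from __future__ import annotations

import math

import numpy as np

from .designs import Design, set_spread

__all__ = [
    "wrap_around_discrepancy",
    "scaled_discrepancy",
    "scaled_spread",
    "design_diagnostics",
]


def wrap_around_discrepancy(points: np.ndarray) -> float:
    """Closed-form W2^2 of an (N, k) unit-cube point set."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    if np.any(pts < 0) or np.any(pts > 1):
        raise ValueError("all coordinates must lie in [0, 1]")
    N, k = pts.shape
    # |x_n - x_m| per pair and coordinate, in manageable chunks for large N
    total = 0.0
    chunk = max(1, int(2e7) // (N * k) or 1)
    for start in range(0, N, chunk):
        d = np.abs(pts[start : start + chunk, None, :] - pts[None, :, :])
        total += np.prod(1.5 - d * (1.0 - d), axis=2).sum()
    return float(-((4.0 / 3.0) ** k) + total / N**2)


def scaled_discrepancy(design: Design) -> float:
    """W2^2 of the design's points over (k+1) x expected random-sample W2^2."""
    k = design.k
    w2 = wrap_around_discrepancy(design.unit_matrix())
    return design.r * w2 / ((1.5) ** k - (4.0 / 3.0) ** k)


def scaled_spread(design: Design) -> float:
    """Spread D scaled by the number of elements in its expression:
    D / (C(r,2) * k * ((k+1)^4 + (k+1)^2))."""
    r, k = design.r, design.k
    if r < 2:
        raise ValueError("spread requires at least 2 blocks")
    D = set_spread(design.blocks)
    return D / (math.comb(r, 2) * k * ((k + 1) ** 4 + (k + 1) ** 2))


def design_diagnostics(design: Design) -> dict:
    """The four quality metrics of a design: D, scaled D, W2^2 and scaled W2^2."""
    D = set_spread(design.blocks) if design.r >= 2 else 0.0
    w2 = wrap_around_discrepancy(design.unit_matrix())
    return {
        "strategy": design.strategy,
        "k": design.k,
        "r": design.r,
        "spread": D,
        "scaled_spread": scaled_spread(design) if design.r >= 2 else 0.0,
        "w2": w2,
        "scaled_w2": scaled_discrepancy(design),
    }
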