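"""Quasi-random point streams: Sobol sequences and the additive-recurrence R_d sequence.

Sobol generation is delegated to :class:`scipy.stats.qmc.Sobol` (Joe-Kuo
direction numbers, unscrambled by default so replicate protocols are
bit-reproducible). The R_d sequence in ``k`` dimensions is

    z_n = alpha_0 + n * (1/phi_k, 1/phi_k^2, ..., 1/phi_k^k)  mod 1,

where ``phi_k`` is the unique positive root of ``x^(k+1) = x + 1`` (the
generalized golden ratio) and ``alpha_0`` defaults to 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = ["QRStream", "sobol_points", "golden_root", "rd_points"]


def sobol_points(n: int, dim: int, skip: int = 0, scramble_seed: int | None = None) -> np.ndarray:
    """First ``n`` Sobol points in ``dim`` dimensions after skipping ``skip``.

    The all-zeros initial point of the unscrambled sequence is always skipped
    (it sits on the corner of the space and degenerates radial blocks), so
    ``skip=0`` starts at the point (0.5, 0.5, ...).
    """
    if n < 1 or dim < 1:
        raise ValueError("n and dim must be >= 1")
    try:
        gen = qmc.Sobol(d=dim, scramble=scramble_seed is not None, seed=scramble_seed)
    except ValueError as e:  # dimension beyond the direction-number table
        raise ValueError(f"unsupported Sobol dimension {dim}: {e}") from e
    offset = skip if scramble_seed is not None else skip + 1
    if offset:
        gen.fast_forward(offset)
    return gen.random(n)


def golden_root(k: int) -> float:
    """Unique positive root of the generalized golden-ratio equation x^(k+1) = x + 1.

    The root lies in (1, 2]; it is bracketed by bisection (brentq) and
    polished with two Newton steps so the residual is at the rounding floor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from scipy.optimize import brentq

    x = brentq(lambda t: t ** (k + 1) - t - 1, 1.0, 2.0, xtol=1e-15, rtol=8.9e-16)
    for _ in range(2):
        f = x ** (k + 1) - x - 1
        fp = (k + 1) * x**k - 1
        x -= f / fp
    return x


def rd_points(n: int, k: int, alpha0: float = 0.5, skip: int = 0) -> np.ndarray:
    """Rows 1..n (after ``skip``) of the k-dimensional R_d sequence."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    phi = golden_root(k)
    alpha = 1.0 / phi ** np.arange(1, k + 1)
    idx = np.arange(skip + 1, skip + n + 1)[:, None]
    return (alpha0 + idx * alpha) % 1.0


@dataclass
class QRStream:
    """A resumable, serializable point stream.

    ``kind`` is one of ``"sobol"``, ``"rd"`` or ``"pseudo_random"``; ``cursor``
    counts points already drawn, so successive :meth:`draw` calls advance
    deterministically and two streams with equal state produce identical
    points.
    """

    kind: str
    dim: int
    cursor: int = 0
    alpha0: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sobol", "rd", "pseudo_random"):
            raise ValueError(f"unknown stream kind {self.kind!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.kind == "pseudo_random" and self.seed is None:
            raise ValueError("pseudo_random streams require a seed")

    def draw(self, n: int) -> np.ndarray:
        """Next ``n`` points; advances the cursor."""
        if self.kind == "sobol":
            pts = sobol_points(n, self.dim, skip=self.cursor)
        elif self.kind == "rd":
            pts = rd_points(n, self.dim, alpha0=self.alpha0, skip=self.cursor)
        else:
            rng = np.random.default_rng(self.seed)
            # re-derive the stream prefix so state is (seed, cursor) only
            pts = rng.random((self.cursor + n, self.dim))[self.cursor :]
        self.cursor += n
        return pts

    def state(self) -> dict:
        return {
            "kind": self.kind,
            "dim": self.dim,
            "cursor": self.cursor,
            "alpha0": self.alpha0,
            "seed": self.seed,
        }

    @classmethod
    def from_state(cls, state: dict) -> "QRStream":
        return cls(**state)
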