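"""Sampling-design construction for elementary effects.

Two families of design are built on the discrete unit hypercube and then
transformed to actual parameter space:

* **winding stairs** — a semi-random walk of k+1 points changing exactly one
  coordinate per step, so each interior point serves two effects;
* **radial** — a star: k perturbed points each differing from a shared base
  point in exactly one coordinate.

Base/perturbation points come either from pseudo-random sampling (the
classic optimized-trajectories pool) or from a quasi-random stream (Sobol or
R_d), with the perturbation vector shifted ``q`` stream rows ahead of its
base. Discrete (integer/boolean) coordinates are always *pinned* to the level
grid and stepped by the fixed |delta_i|; ``pinned=True`` extends that
treatment to every input, reproducing the large-step fixed-grid designs.

The optimized-trajectory selectors (greedy EOT and exact brute force)
maximize the spread D, the sum over ordered block pairs of squared
inter-block distances, where the distance between two blocks is the sum of
Euclidean distances between all couples of their points.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .qr import QRStream
from .space import ParameterSpace, optimal_step

__all__ = [
    "StepRecord",
    "Block",
    "Design",
    "CoincidenceError",
    "pin_coordinate",
    "build_winding_block",
    "build_radial_block",
    "generate_winding_design",
    "generate_radial_design",
    "generate_design",
    "trajectory_distance",
    "set_spread",
    "select_eot",
    "select_ot_bruteforce",
    "count_total_effects",
    "STRATEGIES",
]


class CoincidenceError(ValueError):
    """A perturbation coordinate coincides with its base-point counterpart."""


@dataclass(frozen=True)
class StepRecord:
    """Bookkeeping for one elementary-effect step inside a block."""

    param_index: int
    from_row: int
    to_row: int
    delta: float  # signed step in unit space
    Delta: float  # signed step in actual units


@dataclass
class Block:
    """k+1 design points plus the k step records that pair them into effects."""

    unit_points: np.ndarray  # (k+1, k)
    actual_points: np.ndarray  # (k+1, k)
    step_records: tuple[StepRecord, ...]
    design_kind: str  # "winding" | "radial"

    @property
    def k(self) -> int:
        return self.unit_points.shape[1]

    def validate(self) -> None:
        """Check the defining structural property of the block kind."""
        pts = self.unit_points
        k = self.k
        if pts.shape != (k + 1, k):
            raise ValueError(f"block must have k+1={k + 1} points, got {pts.shape}")
        stepped = sorted(r.param_index for r in self.step_records)
        if stepped != list(range(k)):
            raise ValueError("each parameter must step exactly once per block")
        if any(r.delta == 0 for r in self.step_records):
            raise ValueError("zero unit step recorded")
        if self.design_kind == "winding":
            for t in range(1, k + 1):
                diff = np.nonzero(pts[t] != pts[t - 1])[0]
                if len(diff) != 1:
                    raise ValueError(
                        f"winding rows {t - 1}->{t} differ in {len(diff)} coordinates"
                    )
        elif self.design_kind == "radial":
            seen = set()
            for t in range(1, k + 1):
                diff = np.nonzero(pts[t] != pts[0])[0]
                if len(diff) != 1 or diff[0] in seen:
                    raise ValueError(
                        f"radial row {t} must differ from the base in exactly one "
                        f"new coordinate"
                    )
                seen.add(int(diff[0]))


@dataclass
class Design:
    """An ordered set of r blocks over a parameter space, with provenance."""

    blocks: list[Block]
    space: ParameterSpace
    strategy: str
    provenance: dict = field(default_factory=dict)

    @property
    def r(self) -> int:
        return len(self.blocks)

    @property
    def k(self) -> int:
        return self.space.k

    @property
    def n_points(self) -> int:
        return self.r * (self.k + 1)

    def unit_matrix(self) -> np.ndarray:
        """All points stacked block-by-block, shape (r(k+1), k), unit space."""
        return np.vstack([b.unit_points for b in self.blocks])

    def actual_matrix(self) -> np.ndarray:
        return np.vstack([b.actual_points for b in self.blocks])


def pin_coordinate(x: float, levels: int) -> float:
    """Snap a unit coordinate onto the level grid: 1 -> 1, else floor(p*x)/(p-1)."""
    if not 0 <= x <= 1:
        raise ValueError(f"unit coordinate {x} outside [0, 1]")
    if x == 1:
        return 1.0
    return math.floor(levels * x) / (levels - 1)


def _restricted_grid(levels: int, delta: float) -> np.ndarray:
    """Admissible start values {0, 1/(p-1), ..., 1-|delta|} for an up-step."""
    c = round(delta * (levels - 1))
    if not math.isclose(c / (levels - 1), delta, rel_tol=0, abs_tol=1e-9) or c < 1:
        raise ValueError(f"step {delta} is not a positive multiple of 1/(p-1)")
    return np.arange(levels - c) / (levels - 1)


def _check_on_restricted_grid(x_init, space: ParameterSpace, deltas) -> None:
    for i, (p, x, d) in enumerate(zip(space, x_init, deltas)):
        grid = _restricted_grid(p.levels, d)
        if not np.any(np.isclose(grid, x, atol=1e-9)):
            raise ValueError(
                f"start coordinate {x} for parameter {p.name!r} is off the "
                f"restricted grid {grid}"
            )


def build_winding_block(
    x_init: np.ndarray,
    deltas: np.ndarray,
    signs: np.ndarray,
    perm: np.ndarray,
    space: ParameterSpace,
) -> Block:
    """Construct one fixed-step winding-stairs block.

    ``x_init`` must lie on the restricted grid ``{0, ..., 1-|delta_i|}`` per
    coordinate. Parameter ``i`` walks from ``x_init[i]`` up to
    ``x_init[i]+|delta_i|`` when ``signs[i] > 0``, or starts at the top and
    steps down when ``signs[i] < 0``; ``perm[t]`` names the parameter changed
    at step ``t+1``. A permutation may only exchange parameters with the same
    number of levels (and step size).
    """
    k = space.k
    x_init = np.asarray(x_init, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    signs = np.asarray(signs)
    perm = np.asarray(perm, dtype=int)
    _check_on_restricted_grid(x_init, space, deltas)
    if sorted(perm) != list(range(k)):
        raise ValueError(f"perm must be a permutation of 0..{k - 1}")
    for t in range(k):
        i = perm[t]
        if space[i].levels != space[t].levels or not math.isclose(
            deltas[i], deltas[t], abs_tol=1e-12
        ):
            raise ValueError(
                "illegal permutation: parameters may only exchange step order "
                "when they share the same number of levels and step size "
                f"(position {t} <- parameter {space[i].name!r})"
            )

    start = np.where(signs > 0, x_init, x_init + deltas)
    pts = np.empty((k + 1, k))
    pts[0] = start
    records = []
    for t in range(1, k + 1):
        i = int(perm[t - 1])
        pts[t] = pts[t - 1]
        pts[t, i] = x_init[i] + deltas[i] if signs[i] > 0 else x_init[i]
        records.append((i, t - 1, t, float(signs[i]) * deltas[i]))
    return _finish_block(pts, records, space, "winding")


def _finish_block(pts, raw_records, space, kind) -> Block:
    actual = space.from_unit(pts)
    records = tuple(
        StepRecord(
            param_index=i,
            from_row=fr,
            to_row=to,
            delta=d,
            Delta=float(actual[to, i] - actual[fr, i]),
        )
        for (i, fr, to, d) in raw_records
    )
    return Block(unit_points=pts, actual_points=actual, step_records=records, design_kind=kind)


def _process_base(a, b, space, pinned, deltas):
    """Resolve base coordinates and signed fixed steps for discrete/pinned inputs.

    Returns (base, fixed_step) where fixed_step[i] is the signed |delta_i| for
    coordinates using the fixed-step rule and NaN for 'standard' real
    coordinates (which step to b[i] instead).
    """
    k = space.k
    base = np.array(a, dtype=float)
    fixed = np.full(k, np.nan)
    for i, p in enumerate(space):
        if pinned or p.is_discrete:
            xi = pin_coordinate(base[i], p.levels)
            base[i] = xi
            d = deltas[i]
            up_ok = xi + d <= 1 + 1e-12
            down_ok = xi - d >= -1e-12
            if up_ok and down_ok:
                sign = 1.0 if b[i] >= a[i] else -1.0
            elif up_ok:
                sign = 1.0
            elif down_ok:
                sign = -1.0
            else:
                raise ValueError(
                    f"step {d} infeasible in both directions for parameter "
                    f"{p.name!r} at {xi}"
                )
            fixed[i] = sign * d
    return base, fixed


def build_radial_block(
    a: np.ndarray,
    b: np.ndarray,
    space: ParameterSpace,
    pinned: bool = False,
    deltas: np.ndarray | None = None,
) -> Block:
    """Construct one radial (star) block from base point ``a`` and perturbation ``b``.

    Row 1 is the base; row i+1 replaces coordinate i. 'Standard' real
    coordinates step to ``b[i]`` (step calculated a posteriori); discrete
    coordinates — and all coordinates when ``pinned`` — are pinned to the
    level grid and stepped by the fixed |delta_i| in a direction that keeps
    the point inside the unit cube.

    Raises
    ------
    CoincidenceError
        If a standard coordinate has ``a[i] == b[i]`` (zero step); callers
        regenerate the perturbation row.
    """
    k = space.k
    if deltas is None:
        deltas = space.default_deltas()
    base, fixed = _process_base(a, b, space, pinned, deltas)
    pts = np.empty((k + 1, k))
    pts[0] = base
    records = []
    for i in range(k):
        pts[i + 1] = base
        if np.isnan(fixed[i]):
            if b[i] == a[i]:
                raise CoincidenceError(
                    f"perturbation coincides with base in coordinate {i}"
                )
            pts[i + 1, i] = b[i]
            records.append((i, 0, i + 1, float(b[i] - a[i])))
        else:
            pts[i + 1, i] = base[i] + fixed[i]
            records.append((i, 0, i + 1, float(fixed[i])))
    return _finish_block(pts, records, space, "radial")


def _build_qr_winding_block(a, b, space, pinned, deltas) -> Block:
    """Winding analogue of :func:`build_radial_block`: coordinate i moves from its
    base value to its perturbed value at step i and stays there."""
    k = space.k
    base, fixed = _process_base(a, b, space, pinned, deltas)
    target = np.empty(k)
    records_raw = []
    for i in range(k):
        if np.isnan(fixed[i]):
            if b[i] == a[i]:
                raise CoincidenceError(
                    f"perturbation coincides with base in coordinate {i}"
                )
            target[i] = b[i]
            records_raw.append((i, i, i + 1, float(b[i] - a[i])))
        else:
            target[i] = base[i] + fixed[i]
            records_raw.append((i, i, i + 1, float(fixed[i])))
    pts = np.empty((k + 1, k))
    pts[0] = base
    for t in range(1, k + 1):
        pts[t] = pts[t - 1]
        pts[t, t - 1] = target[t - 1]
    return _finish_block(pts, records_raw, space, "winding")


def resolve_coincidences(
    rows: np.ndarray, r: int, q: int, k: int, free_idx: np.ndarray, stream, cap: int
) -> int:
    """Discard-and-regenerate pass over a (r+q) x 2k stream matrix.

    Whenever a free (standard real) coordinate of base row i coincides with
    its perturbation counterpart in row i+q, the whole row i+q is replaced by
    the next stream element; the scan continues from block i so cascades
    (a replaced row also serves as a later base) are rechecked. Returns the
    number of regenerations.
    """
    retries = 0
    i = 0
    while i < r:
        if free_idx.size and np.any(rows[i, free_idx] == rows[i + q, k + free_idx]):
            retries += 1
            if retries > cap:
                raise RuntimeError(
                    f"exceeded {cap} regenerations while avoiding coincident "
                    f"base/perturbation coordinates"
                )
            rows[i + q] = stream.draw(1)[0]
            continue
        i += 1
    return retries


def _qr_blocks(space, r, seq, q, pinned, skip, deltas, retry_cap, kind, alpha0=0.5):
    """Shared QR machinery: draw an (r+q) x 2k stream, pair A_i with B_{i+q},
    discard and regenerate perturbation rows with coincident standard
    coordinates by extending the stream."""
    k = space.k
    stream = QRStream(kind=seq, dim=2 * k, cursor=skip, alpha0=alpha0)
    rows = stream.draw(r + q)
    free_idx = np.array(
        [i for i, p in enumerate(space) if not (pinned or p.is_discrete)], dtype=int
    )
    retries = resolve_coincidences(rows, r, q, k, free_idx, stream, retry_cap)
    builder = build_radial_block if kind == "radial" else _build_qr_winding_block
    blocks = [
        builder(rows[i][:k], rows[i + q][k:], space, pinned=pinned, deltas=deltas)
        for i in range(r)
    ]
    provenance = {
        "seq": seq,
        "skip": skip,
        "q": q,
        "pinned": pinned,
        "cursor_end": stream.cursor,
        "regenerations": retries,
    }
    return blocks, provenance


def generate_radial_design(
    space: ParameterSpace,
    r: int,
    seq: str = "sobol",
    q: int = 4,
    pinned: bool = False,
    skip: int = 0,
    deltas: np.ndarray | None = None,
    retry_cap: int | None = None,
    alpha0: float = 0.5,
) -> Design:
    """Radial design from a 2k-dimensional quasi-random stream.

    A single (r+q) x 2k matrix is drawn; the left half supplies base points
    A_i and the right half perturbation vectors, with block i pairing A_i
    with B_{i+q} (the q-shift decorrelates base and perturbation). ``skip``
    offsets into the stream so replicates can use disjoint segments.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if q < 0:
        raise ValueError("q must be >= 0")
    if deltas is None:
        deltas = space.default_deltas()
    cap = retry_cap if retry_cap is not None else 100 * r
    blocks, prov = _qr_blocks(space, r, seq, q, pinned, skip, deltas, cap, "radial", alpha0)
    name = f"{'pinned' if pinned else 'standard'}-{seq}-radial"
    return Design(blocks=blocks, space=space, strategy=name, provenance=prov)


def generate_winding_design(
    space: ParameterSpace,
    r: int,
    base_source: str = "random",
    pinned: bool = False,
    rng: np.random.Generator | int | None = None,
    q: int = 4,
    skip: int = 0,
    deltas: np.ndarray | None = None,
    retry_cap: int | None = None,
    alpha0: float = 0.5,
) -> Design:
    """Winding-stairs design.

    ``base_source="random"`` gives classic fixed-step trajectories: start
    points uniform on the restricted grid, step directions and (level-group
    respecting) step order randomized — the pool generator for (E)OT.
    ``base_source in {"sobol", "rd"}`` walks each coordinate from its base
    value to its perturbation value using the same 2k-dimensional stream and
    q-shift as the radial designs; fixed steps apply to all inputs when
    ``pinned`` and to integer/boolean inputs otherwise.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if deltas is None:
        deltas = space.default_deltas()
    if base_source == "random":
        rng = np.random.default_rng(rng)
        blocks = [_random_winding_block(space, deltas, rng) for _ in range(r)]
        prov = {"base_source": "random"}
        name = "random-winding"
    elif base_source in ("sobol", "rd"):
        cap = retry_cap if retry_cap is not None else 100 * r
        blocks, prov = _qr_blocks(
            space, r, base_source, q, pinned, skip, deltas, cap, "winding", alpha0
        )
        name = f"{'pinned' if pinned else 'standard'}-{base_source}-winding"
    else:
        raise ValueError(f"unknown base_source {base_source!r}")
    return Design(blocks=blocks, space=space, strategy=name, provenance=prov)


def _random_winding_block(space, deltas, rng) -> Block:
    k = space.k
    x_init = np.array(
        [rng.choice(_restricted_grid(p.levels, d)) for p, d in zip(space, deltas)]
    )
    signs = rng.choice([-1.0, 1.0], size=k)
    # random step order, permuting only within equal-(levels, delta) groups
    perm = np.arange(k)
    groups: dict[tuple, list[int]] = {}
    for i, p in enumerate(space):
        groups.setdefault((p.levels, round(deltas[i] * 1e12)), []).append(i)
    for idxs in groups.values():
        perm[idxs] = rng.permutation(idxs)
    return build_winding_block(x_init, deltas, signs, perm, space)


# ---------------------------------------------------------------------------
# spread and optimized-trajectory selection


def trajectory_distance(block_m: Block, block_l: Block) -> float:
    """Sum of Euclidean distances between all couples of points of two blocks
    (unit space); zero for a block paired with itself."""
    if block_m is block_l:
        return 0.0
    if block_m.k != block_l.k:
        raise ValueError("blocks live in different dimensions")
    return float(cdist(block_m.unit_points, block_l.unit_points).sum())


def set_spread(blocks: list[Block]) -> float:
    """Spread D: sum over *ordered* pairs of squared inter-block distances
    (each unordered pair counted twice, as the defining formula is printed)."""
    if len(blocks) < 2:
        raise ValueError("spread requires at least 2 blocks")
    d2 = _pairwise_sq(blocks)
    return float(d2.sum())


def _pairwise_sq(blocks) -> np.ndarray:
    m = len(blocks)
    d2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = trajectory_distance(blocks[i], blocks[j])
            d2[i, j] = d2[j, i] = d * d
    return d2


def select_eot(pool: list[Block], r: int, space: ParameterSpace | None = None) -> Design:
    """Greedy optimized-trajectory selection.

    For each of the M pool blocks as a seed, grow a set to size r by
    repeatedly adding the unused block that maximizes the spread of the
    enlarged set; return the best of the M resulting sets. Ties break toward
    the lowest pool index.
    """
    M = len(pool)
    if not (M >= r >= 2):
        raise ValueError(f"need M >= r >= 2, got M={M}, r={r}")
    d2 = _pairwise_sq(pool)
    best_spread = -np.inf
    best_sel: list[int] | None = None
    for start in range(M):
        sel = [start]
        in_set = np.zeros(M, dtype=bool)
        in_set[start] = True
        # cross[n] = sum of d^2 between candidate n and the current set
        cross = d2[start].copy()
        total = 0.0
        for _ in range(r - 1):
            cand = np.where(~in_set, cross, -np.inf)
            n = int(np.argmax(cand))  # argmax takes the first (lowest) index on ties
            sel.append(n)
            in_set[n] = True
            total += cross[n]
            cross = cross + d2[n]
        spread = 2.0 * total
        if spread > best_spread:
            best_spread = spread
            best_sel = sel
    assert best_sel is not None
    blocks = [pool[i] for i in best_sel]
    return Design(
        blocks=blocks,
        space=space,
        strategy="eot",
        provenance={"M": M, "selected": best_sel, "spread": best_spread},
    )


def select_ot_bruteforce(
    pool: list[Block], r: int, space: ParameterSpace | None = None, cap: int = 10**6
) -> Design:
    """Exact spread maximization over all C(M, r) subsets (small pools only)."""
    M = len(pool)
    n_comb = math.comb(M, r)
    if n_comb > cap:
        raise ValueError(
            f"C({M},{r}) = {n_comb} exceeds the brute-force cap {cap}; "
            f"use select_eot instead"
        )
    d2 = _pairwise_sq(pool)
    best = -np.inf
    best_combo: tuple[int, ...] | None = None
    for combo in itertools.combinations(range(M), r):
        idx = np.array(combo)
        spread = float(d2[np.ix_(idx, idx)].sum())
        if spread > best:  # strict: keeps the lexicographically smallest tuple
            best = spread
            best_combo = combo
    assert best_combo is not None
    return Design(
        blocks=[pool[i] for i in best_combo],
        space=space,
        strategy="ot",
        provenance={"M": M, "selected": list(best_combo), "spread": best},
    )


def generate_eot_design(
    space: ParameterSpace,
    r: int,
    M: int = 200,
    rng: np.random.Generator | int | None = None,
    deltas: np.ndarray | None = None,
) -> Design:
    """EOT: greedy spread-maximizing selection of r blocks from a pool of M
    random fixed-step winding trajectories."""
    rng = np.random.default_rng(rng)
    if deltas is None:
        deltas = space.default_deltas()
    pool = [_random_winding_block(space, deltas, rng) for _ in range(M)]
    design = select_eot(pool, r, space=space)
    design.provenance["pool_size"] = M
    return design


def count_total_effects(space: ParameterSpace, deltas=None) -> list[int]:
    """Exact number of elementary effects available per input on the full grid:
    (p_i - |delta_i|(p_i - 1)) * prod_{j != i} p_j."""
    if deltas is None:
        deltas = space.default_deltas()
    counts = []
    all_p = [p.levels for p in space]
    for i, (p, d) in enumerate(zip(space, deltas)):
        c = round(d * (p.levels - 1))
        if not math.isclose(c / (p.levels - 1), d, rel_tol=0, abs_tol=1e-9) or c < 1:
            raise ValueError(
                f"step {d} for parameter {p.name!r} is not a grid multiple"
            )
        n = p.levels - c
        for j, pj in enumerate(all_p):
            if j != i:
                n *= pj
        counts.append(n)
    return counts


# ---------------------------------------------------------------------------
# strategy registry (names as exposed by the CLI and benchmarks)

STRATEGIES = (
    "eot",
    "ot",
    "sobol-radial",
    "rd-radial",
    "sobol-winding",
    "rd-winding",
    "pinned-sobol-radial",
    "pinned-rd-radial",
    "pinned-sobol-winding",
    "pinned-rd-winding",
)


def generate_design(
    space: ParameterSpace,
    strategy: str,
    r: int,
    q: int = 4,
    M: int = 200,
    skip: int = 0,
    rng: np.random.Generator | int | None = None,
    deltas: np.ndarray | None = None,
) -> Design:
    """Dispatch a strategy name to the matching generator."""
    if strategy == "eot":
        return generate_eot_design(space, r, M=M, rng=rng, deltas=deltas)
    if strategy == "ot":
        rng = np.random.default_rng(rng)
        if deltas is None:
            deltas = space.default_deltas()
        pool = [_random_winding_block(space, deltas, rng) for _ in range(M)]
        return select_ot_bruteforce(pool, r, space=space)
    pinned = strategy.startswith("pinned-")
    rest = strategy.removeprefix("pinned-")
    try:
        seq, kind = rest.split("-")
    except ValueError:
        raise ValueError(f"unknown strategy {strategy!r}") from None
    if seq not in ("sobol", "rd") or kind not in ("radial", "winding"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if kind == "radial":
        return generate_radial_design(
            space, r, seq=seq, q=q, pinned=pinned, skip=skip, deltas=deltas
        )
    return generate_winding_design(
        space, r, base_source=seq, pinned=pinned, q=q, skip=skip, deltas=deltas
    )
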