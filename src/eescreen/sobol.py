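"""Jansen estimation of Sobol total-order indices from radial/winding samples.

With base points A_j, fully perturbed points B_j and single-coordinate
perturbations AB_j^(i), the Jansen estimator is

    S_Ti = (1/2r) sum_j [Y(A_j) - Y(AB_j^(i))]^2 / V,

where the total variance V is estimated from the base and fully perturbed
points only (perturbed points would bias it):

    V = 1/(2r-1) * (sum_j [Y(A_j) - Y0]^2 + sum_j [Y(B_j) - Y0]^2),
    Y0 = mean of all Y(A_j) and Y(B_j).

For a winding sample the squared numerator difference for input i is taken
between the two consecutive walk points that step coordinate i; the walk's
first and last points play the roles of A_j and B_j.

Reference (ground-truth) total indices are provided per benchmark function:
semi-analytic variance decompositions for the K- and G*-functions, 1-D
quadrature for the additive f6, and a high-precision scrambled-QMC Jansen
oracle for the Penman-Monteith equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import qmc

from .designs import Design, resolve_coincidences
from .effects import evaluate_design
from .qr import QRStream
from .space import ParameterSpace

__all__ = [
    "SobolEstimate",
    "jansen_total_indices",
    "radial_sample_matrices",
    "estimate_total_indices",
    "jansen_from_design",
    "reference_total_indices",
    "mae_against_reference",
]


@dataclass
class SobolEstimate:
    """Estimated total-order indices and the variance bookkeeping behind them."""

    st: np.ndarray  # (k,) total-order indices
    vhat: float  # estimated total variance, units [Y]^2
    y0: float  # sample mean over base + fully perturbed points
    r: int  # base sample size


def jansen_total_indices(YA: np.ndarray, YB: np.ndarray, YAB: np.ndarray) -> SobolEstimate:
    """Jansen estimator from output values at A (r,), B (r,) and AB (r, k) points."""
    YA = np.asarray(YA, dtype=float).ravel()
    YB = np.asarray(YB, dtype=float).ravel()
    YAB = np.atleast_2d(np.asarray(YAB, dtype=float))
    r = YA.size
    if YB.size != r or YAB.shape[0] != r:
        raise ValueError("YA, YB and YAB must share the base sample size r")
    if r < 2:
        raise ValueError("need r >= 2")
    sq = (YA[:, None] - YAB) ** 2
    return _finish_jansen(sq, YA, YB, r)


def _finish_jansen(sq_diffs: np.ndarray, YA, YB, r: int) -> SobolEstimate:
    y0 = float((YA.sum() + YB.sum()) / (2 * r))
    vhat = float((((YA - y0) ** 2).sum() + ((YB - y0) ** 2).sum()) / (2 * r - 1))
    if vhat == 0:
        raise ZeroDivisionError("estimated total variance is zero; indices undefined")
    st = sq_diffs.sum(axis=0) / (2 * r * vhat)
    return SobolEstimate(st=st, vhat=vhat, y0=y0, r=r)


def _pin_columns(x: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Vectorized grid pinning of an (n, k) matrix, column-wise levels."""
    pinned = np.floor(levels * x) / (levels - 1)
    return np.where(x == 1.0, 1.0, pinned)


def radial_sample_matrices(
    space: ParameterSpace,
    r: int,
    seq: str = "sobol",
    q: int = 4,
    pinned: bool = False,
    skip: int = 0,
    deltas: np.ndarray | None = None,
    retry_cap: int | None = None,
):
    """Vectorized A/B base and perturbation matrices for radial/winding sampling.

    Draws an (r+q) x 2k quasi-random matrix, takes base rows from the left
    half and perturbation rows — shifted q rows ahead — from the right half,
    applies grid pinning and fixed steps to discrete (or, when ``pinned``,
    all) coordinates, and regenerates perturbation rows whose free
    coordinates coincide with the base. Returns (A, B) in unit space, each
    (r, k).
    """
    k = space.k
    if deltas is None:
        deltas = space.default_deltas()
    stream = QRStream(kind=seq, dim=2 * k, cursor=skip)
    rows = stream.draw(r + q)
    fixed_mask = np.array([pinned or p.is_discrete for p in space])
    free_idx = np.where(~fixed_mask)[0]
    cap = retry_cap if retry_cap is not None else 100 * r
    resolve_coincidences(rows, r, q, k, free_idx, stream, cap)
    A_raw = rows[:r, :k]
    B_raw = rows[q : r + q, k:]
    A = A_raw.copy()
    B = B_raw.copy()
    if fixed_mask.any():
        levels = np.array([p.levels for p in space], dtype=float)[fixed_mask]
        d = np.asarray(deltas, dtype=float)[fixed_mask]
        Af = _pin_columns(A_raw[:, fixed_mask], levels)
        sign = np.where(B_raw[:, fixed_mask] >= A_raw[:, fixed_mask], 1.0, -1.0)
        up_ok = Af + d <= 1.0 + 1e-12
        down_ok = Af - d >= -1e-12
        sign = np.where(up_ok & down_ok, sign, np.where(up_ok, 1.0, -1.0))
        A[:, fixed_mask] = Af
        B[:, fixed_mask] = Af + sign * d
    return A, B


def estimate_total_indices(
    model,
    space: ParameterSpace,
    r: int,
    strategy: str = "sobol-radial",
    q: int = 4,
    skip: int = 0,
    deltas: np.ndarray | None = None,
) -> SobolEstimate:
    """Jansen total indices using a named QR sampling strategy (vectorized model).

    ``strategy`` is ``[pinned-]{sobol|rd}-{radial|winding}``. A radial sample
    evaluates the r base points, the r fully perturbed points and the r*k
    single-coordinate perturbations; a winding sample reuses the walk points,
    pairing consecutive steps.
    """
    pinned = strategy.startswith("pinned-")
    seq, kind = strategy.removeprefix("pinned-").split("-")
    k = space.k
    A, B = radial_sample_matrices(
        space, r, seq=seq, q=q, pinned=pinned, skip=skip, deltas=deltas
    )
    XA = space.from_unit(A)
    XB = space.from_unit(B)
    YA = np.asarray(model(XA), dtype=float).ravel()
    YB = np.asarray(model(XB), dtype=float).ravel()
    if kind == "radial":
        YAB = np.empty((r, k))
        for i in range(k):
            ABi = A.copy()
            ABi[:, i] = B[:, i]
            YAB[:, i] = np.asarray(model(space.from_unit(ABi)), dtype=float).ravel()
        return jansen_total_indices(YA, YB, YAB)
    # winding: walk coordinate i from A to B at step i; consecutive diffs
    sq = np.empty((r, k))
    prev = YA
    W = A.copy()
    for i in range(k):
        W[:, i] = B[:, i]
        Yi = np.asarray(model(space.from_unit(W)), dtype=float).ravel()
        sq[:, i] = (Yi - prev) ** 2
        prev = Yi
    return _finish_jansen(sq, YA, prev, r)


def jansen_from_design(design: Design, model, vectorized: bool = False) -> SobolEstimate:
    """Jansen total indices from an existing Design plus model evaluations.

    Works for any winding or radial design: squared numerator differences
    come from the step records. For a winding block the first and last points
    serve as base and fully perturbed points; for a radial block the fully
    perturbed point is assembled from the per-coordinate perturbations and
    evaluated in addition to the design points.
    """
    outputs = evaluate_design(design, model, vectorized=vectorized)
    Y = outputs.values[:, 0]
    r, k, kp1 = design.r, design.k, design.k + 1
    sq = np.empty((r, k))
    YA = np.empty(r)
    YB = np.empty(r)
    extra = []
    for n, block in enumerate(design.blocks):
        base = n * kp1
        YA[n] = Y[base]
        for rec in block.step_records:
            dy = Y[base + rec.to_row] - Y[base + rec.from_row]
            sq[n, rec.param_index] = dy * dy
        if block.design_kind == "winding":
            YB[n] = Y[base + k]
        else:
            b_pt = block.unit_points[0].copy()
            for rec in block.step_records:
                b_pt[rec.param_index] = block.unit_points[rec.to_row, rec.param_index]
            extra.append(b_pt)
    if extra:
        XB = design.space.from_unit(np.vstack(extra))
        vals = (
            np.asarray(model(XB), dtype=float).ravel()
            if vectorized
            else np.array([float(np.atleast_1d(model(x))[0]) for x in XB])
        )
        radial_idx = [
            n for n, b in enumerate(design.blocks) if b.design_kind == "radial"
        ]
        YB[radial_idx] = vals
    return _finish_jansen(sq, YA, YB, r)


# ---------------------------------------------------------------------------
# reference (ground-truth) indices


def _k_function_reference(k: int) -> np.ndarray:
    """Exact total indices of the K-function by analytic variance decomposition.

    K is linear in each x_i with coefficient B_i = prod_{j<i} x_j *
    sum_{m>=i} (-1)^m prod_{i<j<=m} x_j, so E_{x_-i}[Var_i(K|x_-i)] =
    E[B_i^2]/12; moments of products of iid U(0,1) give closed sums.
    """
    half = 0.5 ** np.arange(0, k + 2)
    third = (1.0 / 3.0) ** np.arange(0, k + 2)
    ey = sum((-1.0) ** m * half[m] for m in range(1, k + 1))
    ey2 = 0.0
    for m in range(1, k + 1):
        for mp in range(1, k + 1):
            lo, hi = min(m, mp), max(m, mp)
            ey2 += (-1.0) ** (m + mp) * third[lo] * half[hi - lo]
    var = ey2 - ey * ey
    st = np.empty(k)
    for i in range(1, k + 1):
        ed2 = 0.0
        for m in range(i, k + 1):
            for mp in range(i, k + 1):
                lo, hi = min(m, mp), max(m, mp)
                ed2 += (-1.0) ** (m + mp) * third[lo - i] * half[hi - lo]
        st[i - 1] = third[i - 1] * ed2 / 12.0 / var
    return st


def _gstar_reference(k: int) -> np.ndarray:
    """Closed-form G* total indices: with per-factor variance
    V_i = alpha_i^2 / ((1 + 2 alpha_i)(1 + a_i)^2) and unit factor means,
    S_Ti = V_i prod_{j != i}(1 + V_j) / (prod_j (1 + V_j) - 1)."""
    from .testfuncs import default_gstar_constants

    a, alpha = default_gstar_constants(k)
    v = alpha**2 / ((1.0 + 2.0 * alpha) * (1.0 + a) ** 2)
    prod_all = np.prod(1.0 + v)
    total_var = prod_all - 1.0
    return v * (prod_all / (1.0 + v)) / total_var


def _f6_reference() -> np.ndarray:
    """f6 total indices: the model is additive, so S_Ti = Var(g_i)/sum Var(g_j),
    with the 1-D variances computed by adaptive quadrature."""
    from .testfuncs import _f6_terms

    variances = np.empty(6)
    for i in range(6):

        def gi(t, i=i):
            x = np.zeros((1, 6))
            x[0, i] = t
            return float(_f6_terms(x)[0, i])

        m, _ = integrate.quad(gi, 0.0, 1.0, limit=200)
        m2, _ = integrate.quad(lambda t: gi(t) ** 2, 0.0, 1.0, limit=200)
        variances[i] = m2 - m * m
    variances[5] = 0.0  # constant term; quadrature round-off guard
    return variances / variances.sum()


def _qmc_oracle_reference(
    model, space: ParameterSpace, base_log2: int = 17, n_seeds: int = 3, tol: float = 0.005
) -> np.ndarray:
    """High-precision Jansen oracle with scrambled Sobol replicates.

    Averages ``n_seeds`` independent scrambled estimates at base sample
    2**base_log2 and warns if the replicates disagree by more than ``tol``.
    """
    k = space.k
    n = 2**base_log2
    reps = []
    for seed in range(n_seeds):
        gen = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
        rows = gen.random(n)
        A, B = rows[:, :k], rows[:, k:]
        YA = np.asarray(model(space.from_unit(A)), dtype=float).ravel()
        YB = np.asarray(model(space.from_unit(B)), dtype=float).ravel()
        YAB = np.empty((n, k))
        for i in range(k):
            ABi = A.copy()
            ABi[:, i] = B[:, i]
            YAB[:, i] = np.asarray(model(space.from_unit(ABi)), dtype=float).ravel()
        reps.append(jansen_total_indices(YA, YB, YAB).st)
    reps = np.array(reps)
    disagreement = float(np.max(reps.max(axis=0) - reps.min(axis=0)))
    if disagreement > tol:
        warnings.warn(
            f"QMC oracle replicates disagree by {disagreement:.4f} (> {tol}); "
            "consider increasing base_log2",
            stacklevel=2,
        )
    return reps.mean(axis=0)


def reference_total_indices(
    func_id: str, k: int | None = None, base_log2: int = 17, n_seeds: int = 3
) -> np.ndarray:
    """Ground-truth total-order indices for a benchmark function id."""
    from .testfuncs import default_space, penman_monteith

    if func_id == "K":
        if k is None:
            raise ValueError("k required for the K-function")
        return _k_function_reference(k)
    if func_id == "G*":
        if k is None:
            raise ValueError("k required for the G*-function")
        return _gstar_reference(k)
    if func_id == "f6":
        return _f6_reference()
    if func_id == "PM":
        space = default_space("PM")
        return _qmc_oracle_reference(
            penman_monteith, space, base_log2=base_log2, n_seeds=n_seeds
        )
    raise ValueError(f"unknown test function {func_id!r}")


def mae_against_reference(estimates: np.ndarray, reference: np.ndarray) -> float:
    """Mean absolute error over replicates and inputs: (1/(Rk)) sum |St_hat - St|."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    reference = np.asarray(reference, dtype=float).ravel()
    if estimates.shape[1] != reference.size:
        raise ValueError("estimate width does not match reference length")
    return float(np.mean(np.abs(estimates - reference[None, :])))
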