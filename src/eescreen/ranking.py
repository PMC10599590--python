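"""Rank-correlation scoring of screening results against Sobol-total references,
plus the benchmark harnesses comparing trajectory-generation strategies.

Rankings (1 = most important) are compared with Kendall tau-a,

    rho = 2/(k(k-1)) * sum_{i<j} sign(x_i - x_j) sign(y_i - y_j),

which weighs all ranks equally, and with the Pearson correlation of Savage
scores s_j = sum_{i=j..k} 1/i, which up-weights agreement on the most
important inputs. Both require tie-free rankings; estimated-index ties are
broken by input order and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import generate_design
from .effects import compute_effects, evaluate_design
from .measures import normalized_index, summarize_effects
from .sobol import estimate_total_indices, mae_against_reference, reference_total_indices
from .testfuncs import get_test_function

__all__ = [
    "kendall_tau_a",
    "savage_scores",
    "pearson_savage",
    "ranking_from_values",
    "BenchmarkReport",
    "run_ranking_benchmark",
    "run_sobol_benchmark",
]


def _check_permutation(rank: np.ndarray) -> np.ndarray:
    rank = np.asarray(rank)
    k = rank.size
    if sorted(rank) != list(range(1, k + 1)):
        raise ValueError(f"ranks must be a tie-free permutation of 1..{k}")
    return rank


def kendall_tau_a(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Kendall tau-a between two tie-free rankings."""
    x = _check_permutation(rank_x)
    y = _check_permutation(rank_y)
    k = x.size
    if y.size != k:
        raise ValueError("rankings differ in length")
    if k < 2:
        raise ValueError("need at least two items")
    s = 0
    for i in range(k):
        for j in range(i + 1, k):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return float(2.0 * s / (k * (k - 1)))


def savage_scores(rank: np.ndarray) -> np.ndarray:
    """Savage score s_j = sum_{i=j..k} 1/i for the item holding rank j."""
    rank = _check_permutation(rank)
    k = rank.size
    tail = np.cumsum(1.0 / np.arange(k, 0, -1))[::-1]  # tail[j-1] = sum_{i=j..k} 1/i
    return tail[rank - 1]


def pearson_savage(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Pearson correlation of the Savage-score transforms of two rankings."""
    sx = savage_scores(rank_x)
    sy = savage_scores(rank_y)
    if sx.size < 2:
        raise ValueError("Savage-Pearson correlation undefined for a single item")
    return float(np.corrcoef(sx, sy)[0, 1])


def ranking_from_values(values: np.ndarray) -> np.ndarray:
    """Ranks (1 = largest value); ties broken by input order."""
    values = np.asarray(values, dtype=float).ravel()
    order = np.argsort(-values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


@dataclass
class BenchmarkReport:
    """Aggregated benchmark results plus per-replicate records."""

    summary: pd.DataFrame
    records: pd.DataFrame
    reference: np.ndarray
    high_variance: bool = False


def _replicate_design(strategy, space, r, rep, q, M, rng, deltas=None):
    """Replicate rep uses stream elements rep*r+1 onward (QR strategies) or a
    replicate-specific pseudo-random substream (pool strategies)."""
    if strategy in ("eot", "ot"):
        return generate_design(space, strategy, r, M=M, rng=rng.spawn(1)[0])
    return generate_design(space, strategy, r, q=q, skip=rep * r, deltas=deltas)


def run_ranking_benchmark(
    func_id: str,
    k: int | None,
    strategies: list[str],
    measure: str = "S_mu_star",
    r_list: list[int] = (10, 25, 100),
    replicates: int = 50,
    q: int = 4,
    M: int = 200,
    seed: int = 0,
    c_x: str = "range",
    reference: np.ndarray | None = None,
    ref_base_log2: int = 15,
) -> BenchmarkReport:
    """Mean rank correlations of screening-based rankings vs the Sobol reference.

    Per (strategy, r), ``replicates`` designs are generated on disjoint QR
    segments (G* additionally resamples its eta offsets per replicate), the
    chosen normalized index is computed, and Kendall tau-a / Savage-Pearson
    correlations against the reference ranking (descending ground-truth total
    indices) are averaged.
    """
    if measure not in ("S_mu_star", "S_chi"):
        raise ValueError("measure must be S_mu_star or S_chi")
    which = "mu_star" if measure == "S_mu_star" else "chi"
    rng = np.random.default_rng(seed)
    tf0 = get_test_function(func_id, k)
    if reference is None:
        reference = reference_total_indices(func_id, tf0.k, base_log2=ref_base_log2)
    ref_rank = ranking_from_values(reference)
    rows = []
    for strategy in strategies:
        for r in r_list:
            for rep in range(replicates):
                tf = (
                    get_test_function(func_id, k, rng=rng.spawn(1)[0])
                    if func_id == "G*"
                    else tf0
                )
                design = _replicate_design(strategy, tf.space, r, rep, q, M, rng)
                outputs = evaluate_design(design, tf.evaluator, vectorized=True)
                table = compute_effects(design, outputs)
                meas = summarize_effects(table)
                S = normalized_index(meas, which=which, space=tf.space, c_x=c_x)[:, 0]
                est_rank = ranking_from_values(S)
                rows.append(
                    {
                        "strategy": strategy,
                        "measure": measure,
                        "r": r,
                        "replicate": rep,
                        "rho_kendall": kendall_tau_a(est_rank, ref_rank),
                        "rho_pearson": pearson_savage(est_rank, ref_rank),
                        "ties_broken": int(len(np.unique(S)) < S.size),
                    }
                )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["strategy", "measure", "r"], as_index=False)[
            ["rho_kendall", "rho_pearson"]
        ]
        .mean()
        .sort_values(["strategy", "r"], ignore_index=True)
    )
    return BenchmarkReport(
        summary=summary,
        records=records,
        reference=reference,
        high_variance=replicates == 1,
    )


def run_sobol_benchmark(
    func_id: str,
    k: int | None,
    strategies: list[str],
    r_list: list[int] = (10, 25, 100),
    replicates: int = 50,
    q: int = 4,
    M: int = 200,
    seed: int = 0,
    reference: np.ndarray | None = None,
    ref_base_log2: int = 15,
) -> BenchmarkReport:
    """MAE of Jansen total-index estimates per (strategy, r)."""
    from .sobol import jansen_from_design

    rng = np.random.default_rng(seed)
    tf0 = get_test_function(func_id, k)
    if reference is None:
        reference = reference_total_indices(func_id, tf0.k, base_log2=ref_base_log2)
    rows = []
    for strategy in strategies:
        for r in r_list:
            ests = []
            for rep in range(replicates):
                tf = (
                    get_test_function(func_id, k, rng=rng.spawn(1)[0])
                    if func_id == "G*"
                    else tf0
                )
                if strategy in ("eot", "ot"):
                    design = _replicate_design(strategy, tf.space, r, rep, q, M, rng)
                    est = jansen_from_design(design, tf.evaluator, vectorized=True)
                else:
                    est = estimate_total_indices(
                        tf.evaluator, tf.space, r, strategy=strategy, q=q, skip=rep * r
                    )
                ests.append(est.st)
                rows.append(
                    {
                        "strategy": strategy,
                        "r": r,
                        "replicate": rep,
                        "mae": mae_against_reference(est.st[None, :], reference),
                    }
                )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["strategy", "r"], as_index=False)["mae"]
        .mean()
        .sort_values(["strategy", "r"], ignore_index=True)
    )
    return BenchmarkReport(
        summary=summary,
        records=records,
        reference=reference,
        high_variance=replicates == 1,
    )
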