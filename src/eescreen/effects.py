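"""Model evaluation over a design and dimensional elementary effects.

An elementary effect is the finite-difference slope

    EE_ij = (Y_j(to point) - Y_j(from point)) / Delta_i,

where the two points differ only in input i and Delta_i is the *signed*
actual-space step, so the effect carries units [Y_j]/[X_i] and its sign
matches the derivative's regardless of step direction. Effects are made
comparable across inputs by the separable scaling EE * c_x_i / c_y_j; the
default input scaling is the range max_i - min_i and the default output
scaling is 1 (output-direction scalings are sample-dependent and avoided).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .designs import Design

__all__ = [
    "ModelOutputs",
    "EffectTable",
    "evaluate_design",
    "compute_effects",
    "scale_effects",
    "input_scaling",
]


@dataclass
class ModelOutputs:
    """Model output matrix aligned row-for-row with the design points."""

    values: np.ndarray  # (r(k+1), q)
    output_names: tuple[str, ...]
    output_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.output_names) == 1:
            self.values = self.values.reshape(-1, 1)
        if not self.output_units:
            self.output_units = tuple("" for _ in self.output_names)

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass
class EffectTable:
    """Elementary effects indexed (input i, output j, block n).

    ``effects`` has shape (k, q, r). ``scaled`` flags whether the c_x/c_y
    scaling has been applied; ``c_x``/``c_y`` record the factors used.
    """

    effects: np.ndarray
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    scaled: bool = False
    c_x: np.ndarray | None = None
    c_y: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.effects.shape[0]

    @property
    def q(self) -> int:
        return self.effects.shape[1]

    @property
    def r(self) -> int:
        return self.effects.shape[2]


class ModelEvaluationError(RuntimeError):
    """Raised when the model fails on a point; carries block and row indices."""

    def __init__(self, block: int, row: int, cause: Exception):
        self.block = block
        self.row = row
        super().__init__(f"model failed on block {block}, row {row}: {cause}")


def evaluate_design(
    design: Design,
    model: Callable,
    output_names: tuple[str, ...] | None = None,
    vectorized: bool = False,
) -> ModelOutputs:
    """Run a model over every design point (actual-space coordinates, config order).

    ``model`` maps a length-k vector to a scalar or length-q vector; pass
    ``vectorized=True`` for models accepting an (n, k) matrix and returning
    (n,) or (n, q). No partial result is ever returned: a failure on any
    point aborts with the offending block and row.
    """
    X = design.actual_matrix()
    kp1 = design.k + 1
    if vectorized:
        try:
            vals = np.asarray(model(X), dtype=float)
        except Exception as e:  # pragma: no cover - model-specific
            raise ModelEvaluationError(-1, -1, e) from e
        if vals.ndim == 1:
            vals = vals[:, None]
        if not np.all(np.isfinite(vals)):
            bad = int(np.argwhere(~np.isfinite(vals))[0, 0])
            raise ModelEvaluationError(bad // kp1, bad % kp1, ValueError("non-finite output"))
    else:
        rows = []
        for idx, x in enumerate(X):
            try:
                y = np.atleast_1d(np.asarray(model(x), dtype=float))
            except Exception as e:
                raise ModelEvaluationError(idx // kp1, idx % kp1, e) from e
            if not np.all(np.isfinite(y)):
                raise ModelEvaluationError(
                    idx // kp1, idx % kp1, ValueError("non-finite output")
                )
            rows.append(y)
        vals = np.vstack(rows)
    if output_names is None:
        output_names = tuple(
            f"Y{j + 1}" for j in range(vals.shape[1])
        ) if vals.shape[1] > 1 else ("Y",)
    if len(output_names) != vals.shape[1]:
        raise ValueError("output_names length does not match model output width")
    return ModelOutputs(values=vals, output_names=tuple(output_names))


def compute_effects(design: Design, outputs: ModelOutputs) -> EffectTable:
    """Dimensional elementary effects from a design's step records.

    Exactly one effect per (input, block); the signed actual step Delta_i is
    taken from the step record, so winding and radial bookkeeping are handled
    uniformly.
    """
    r, k, kp1 = design.r, design.k, design.k + 1
    if outputs.values.shape[0] != r * kp1:
        raise ValueError(
            f"outputs have {outputs.values.shape[0]} rows, design has {r * kp1} points"
        )
    eff = np.empty((k, outputs.q, r))
    for n, block in enumerate(design.blocks):
        base = n * kp1
        for rec in block.step_records:
            if rec.Delta == 0:
                raise ZeroDivisionError(
                    f"zero actual step for input {rec.param_index} in block {n}: "
                    "elementary effect undefined"
                )
            dy = outputs.values[base + rec.to_row] - outputs.values[base + rec.from_row]
            eff[rec.param_index, :, n] = dy / rec.Delta
    return EffectTable(
        effects=eff,
        input_names=tuple(design.space.names),
        output_names=outputs.output_names,
    )


def input_scaling(space, rule: str = "range") -> np.ndarray:
    """Named input-direction scaling factors c_x_i.

    ``range``: max - min (the recommended default);
    ``std``: sqrt(((max - min + 1)^2 - 1)/12), the standard deviation of a
    discrete uniform variable on the integer range;
    ``mean``: (max + min)/2;
    ``none``: 1.
    """
    if rule == "range":
        return np.array([p.range for p in space])
    if rule == "std":
        return np.array([np.sqrt(((p.range + 1) ** 2 - 1) / 12) for p in space])
    if rule == "mean":
        return np.array([(p.max + p.min) / 2 for p in space])
    if rule == "none":
        return np.ones(space.k)
    raise ValueError(f"unknown input scaling rule {rule!r}")


def scale_effects(
    table: EffectTable,
    c_x: np.ndarray | str = "range",
    c_y: np.ndarray | float = 1.0,
    space=None,
) -> EffectTable:
    """Apply the separable scaling EE * c_x_i / c_y_j.

    ``c_x`` may be a named rule (resolved against ``space``) or an explicit
    positive length-k vector; ``c_y`` a scalar or length-q vector (default 1).
    """
    if table.scaled:
        raise ValueError("table is already scaled")
    if isinstance(c_x, str):
        if space is None:
            raise ValueError("a ParameterSpace is required to resolve a named c_x rule")
        c_x = input_scaling(space, c_x)
    c_x = np.asarray(c_x, dtype=float)
    c_y = np.broadcast_to(np.asarray(c_y, dtype=float), (table.q,)).copy()
    if np.any(c_x <= 0) or np.any(c_y <= 0):
        raise ValueError("scaling factors must be positive")
    scaled = table.effects * c_x[:, None, None] / c_y[None, :, None]
    return replace(table, effects=scaled, scaled=True, c_x=c_x, c_y=c_y)
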