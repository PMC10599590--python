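"""Config parsing and CSV/JSON exchange for file-based model coupling.

The file-exchange workflow: a design is exported as a CSV of actual-space
points (one row per point, blocks in order, header = parameter names in
config order, units in a ``# units:`` comment line) plus a sidecar JSON that
carries everything needed to reconstruct the design bit-exactly — unit
coordinates at full precision, step records, strategy and provenance. The
user runs their model on the CSV and returns an outputs CSV in the same row
order; effects computation refuses to proceed without the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .designs import Block, Design, StepRecord
from .effects import ModelOutputs
from .space import ParameterSpace, ParameterSpec, validate_space

__all__ = [
    "read_space_config",
    "space_to_config",
    "write_design_csv",
    "read_design_csv",
    "write_outputs_csv",
    "read_outputs_csv",
    "write_measures_csv",
]

_TYPE_ALIASES = {"real": "real", "float": "real", "int": "integer", "integer": "integer",
                 "bool": "boolean", "boolean": "boolean"}


def read_space_config(path: str | Path) -> ParameterSpace:
    """Load a parameter space from a JSON or YAML list of
    {name, type, min, max, levels, units}; file order defines column order."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: config must be a non-empty list of parameter entries")
    specs = []
    for idx, entry in enumerate(raw):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ValueError(f"{path}: entry {idx} is not a parameter mapping with a name")
        vtype = _TYPE_ALIASES.get(str(entry.get("type", "real")).lower())
        if vtype is None:
            raise ValueError(
                f"{path}: entry {idx} ({entry['name']}): unknown type {entry.get('type')!r}"
            )
        try:
            specs.append(
                ParameterSpec(
                    name=str(entry["name"]),
                    vtype=vtype,
                    min=float(entry.get("min", 0.0)),
                    max=float(entry.get("max", 1.0)),
                    levels=int(entry.get("levels", 2 if vtype == "boolean" else 4)),
                    units=str(entry.get("units", "")),
                )
            )
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}: entry {idx} ({entry['name']}): {e}") from e
    space = ParameterSpace(specs)
    problems = validate_space(space)
    if problems:
        raise ValueError(f"{path}: invalid parameter space:\n  " + "\n  ".join(problems))
    return space


def space_to_config(space: ParameterSpace) -> list[dict]:
    return [
        {
            "name": p.name,
            "type": p.vtype,
            "min": p.min,
            "max": p.max,
            "levels": p.levels,
            "units": p.units,
        }
        for p in space
    ]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".json")


def write_design_csv(design: Design, path: str | Path) -> None:
    """Write the actual-space design CSV plus the reconstruction sidecar JSON."""
    path = Path(path)
    names = design.space.names
    units = [p.units for p in design.space]
    with path.open("w") as fh:
        fh.write("# units: " + ",".join(units) + "\n")
        fh.write(",".join(names) + "\n")
        for row in design.actual_matrix():
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "strategy": design.strategy,
        "provenance": design.provenance,
        "space": space_to_config(design.space),
        "blocks": [
            {
                "design_kind": b.design_kind,
                "unit_points": [[repr(float(v)) for v in row] for row in b.unit_points],
                "step_records": [
                    {
                        "param_index": r.param_index,
                        "from_row": r.from_row,
                        "to_row": r.to_row,
                        "delta": repr(r.delta),
                        "Delta": repr(r.Delta),
                    }
                    for r in b.step_records
                ],
            }
            for b in design.blocks
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_design_csv(path: str | Path) -> Design:
    """Reconstruct a design from its CSV + sidecar; refuses if the sidecar is missing."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"design sidecar {side} not found; effects computation requires the "
            "step records it carries"
        )
    meta = json.loads(side.read_text())
    space = ParameterSpace(
        [
            ParameterSpec(
                name=e["name"], vtype=e["type"], min=e["min"], max=e["max"],
                levels=e["levels"], units=e["units"],
            )
            for e in meta["space"]
        ]
    )
    blocks = []
    for b in meta["blocks"]:
        unit = np.array([[float(v) for v in row] for row in b["unit_points"]])
        records = tuple(
            StepRecord(
                param_index=r["param_index"],
                from_row=r["from_row"],
                to_row=r["to_row"],
                delta=float(r["delta"]),
                Delta=float(r["Delta"]),
            )
            for r in b["step_records"]
        )
        blocks.append(
            Block(
                unit_points=unit,
                actual_points=space.from_unit(unit),
                step_records=records,
                design_kind=b["design_kind"],
            )
        )
    design = Design(
        blocks=blocks, space=space, strategy=meta["strategy"], provenance=meta["provenance"]
    )
    n_csv = sum(1 for line in path.read_text().splitlines() if line and not line.startswith("#")) - 1
    if n_csv != design.n_points:
        raise ValueError(
            f"design CSV has {n_csv} points but sidecar describes {design.n_points}"
        )
    return design


def write_outputs_csv(outputs: ModelOutputs, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(outputs.output_names) + "\n")
        for row in outputs.values:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_outputs_csv(path: str | Path, design: Design | None = None) -> ModelOutputs:
    """Read a model-outputs CSV (one column per output, rows aligned with the design)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    outputs = ModelOutputs(
        values=df.to_numpy(dtype=float), output_names=tuple(df.columns)
    )
    if design is not None and outputs.values.shape[0] != design.n_points:
        raise ValueError(
            f"outputs file has {outputs.values.shape[0]} rows but the design has "
            f"{design.n_points} points: row alignment cannot be guaranteed"
        )
    return outputs


def write_measures_csv(
    measures, S_mu_star, S_chi, S_sigma, classifications, path: str | Path, h: float
) -> None:
    """Per-(input, output) results CSV plus a JSON summary with thresholds."""
    path = Path(path)
    rows = []
    for j, out in enumerate(measures.output_names):
        cls = classifications[j]
        labels = {}
        for i in cls.unimportant:
            labels[i] = "unimportant"
        for i in cls.important:
            labels[i] = "important"
        for i in cls.neither:
            labels[i] = "neither"
        for i, name in enumerate(measures.input_names):
            rows.append(
                {
                    "input": name,
                    "output": out,
                    "mu": measures.mu[i, j],
                    "sigma": measures.sigma[i, j] if measures.sigma is not None else np.nan,
                    "mu_star": measures.mu_star[i, j],
                    "chi": measures.chi[i, j],
                    "S_mu_star": S_mu_star[i, j],
                    "S_chi": S_chi[i, j],
                    "S_sigma": S_sigma[i, j] if S_sigma is not None else np.nan,
                    "class": labels[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    summary = {
        "h": h,
        "outputs": {
            out: {
                "threshold_S0": classifications[j].threshold,
                "n_unimportant": classifications[j].q_unimportant,
                "important": [measures.input_names[i] for i in classifications[j].important],
                "unimportant": [measures.input_names[i] for i in classifications[j].unimportant],
                "neither": [measures.input_names[i] for i in classifications[j].neither],
            }
            for j, out in enumerate(measures.output_names)
        },
    }
    _sidecar_path(path).write_text(json.dumps(summary, indent=1))
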