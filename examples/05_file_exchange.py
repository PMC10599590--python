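"""File-based model coupling: design CSV out, outputs CSV back in.

For models that cannot be called from Python, the design is exported as a
CSV of actual-space points (with a sidecar JSON carrying the step records);
the external model fills in an outputs CSV in the same row order, and the
analysis proceeds from the two files. Here the 'external model' is a
one-line stand-in.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import eescreen as ee
from eescreen.effects import ModelOutputs
from eescreen.io import read_design_csv, read_outputs_csv, write_design_csv, write_outputs_csv

workdir = Path(tempfile.mkdtemp())
tf = ee.get_test_function("PM")

design = ee.generate_radial_design(tf.space, r=20, seq="sobol")
design_csv = workdir / "design.csv"
write_design_csv(design, design_csv)
print(f"wrote {design.n_points} simulation points to {design_csv}")

# --- external step: the model consumes design.csv and produces outputs.csv
points = pd.read_csv(design_csv, comment="#", float_precision="round_trip")
et = tf.evaluator(points.to_numpy())
write_outputs_csv(
    ModelOutputs(values=et[:, None], output_names=("ET",)), workdir / "outputs.csv"
)

# --- back in Python: reload both files and analyze
design2 = read_design_csv(design_csv)
outputs = read_outputs_csv(workdir / "outputs.csv", design2)
table = ee.compute_effects(design2, outputs)
S = ee.normalized_index(ee.summarize_effects(table), "mu_star", space=design2.space)
for name, s in sorted(zip(design2.space.names, S[:, 0]), key=lambda t: -t[1]):
    print(f"  {name:>9}: S_mu* = {s:.3f}")
print("round-trip preserved coordinates bit-exactly:",
      bool(np.array_equal(design2.unit_matrix(), design.unit_matrix())))
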