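"""Full screening of the Penman-Monteith evapotranspiration equation.

Eight dimensional inputs (energy, humidity and conductance terms on very
different ranges and units) are screened with a standard Sobol radial design.
The normalized indices S_mu* and S_chi rank the inputs; the Wu rule splits
them into important / unimportant / neither at an unimportance level h.
"""

import numpy as np

import eescreen as ee

tf = ee.get_test_function("PM")
design = ee.generate_radial_design(tf.space, r=50, seq="sobol")
outputs = ee.evaluate_design(design, tf.evaluator, vectorized=True)
table = ee.compute_effects(design, outputs)
measures = ee.summarize_effects(table)

S_mu = ee.normalized_index(measures, "mu_star", space=tf.space)[:, 0]
S_chi = ee.normalized_index(measures, "chi", space=tf.space)[:, 0]

print(f"{'input':>9} {'units':>11} {'S_mu*':>7} {'S_chi':>7}")
for i in np.argsort(-S_mu):
    p = tf.space[i]
    print(f"{p.name:>9} {p.units:>11} {S_mu[i]:7.3f} {S_chi[i]:7.3f}")

cls = ee.classify_wu(S_mu, h=10.0)
names = tf.space.names
print("\nWu classification at h = 10%:")
print("  important:  ", [names[i] for i in cls.important])
print("  unimportant:", [names[i] for i in cls.unimportant])
print("  neither:    ", [names[i] for i in cls.neither])
print(f"  threshold S_0 = {cls.threshold:.4f}")
print(
    "\nVapor pressure deficit and stomatal conductance dominate;"
    "\nair density, heat capacity and the psychrometric constant can be fixed."
)
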