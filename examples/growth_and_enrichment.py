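"""Growth-rate curves and target-set enrichment.

Two evaluation utilities: the instantaneous growth rate d(ln A595)/dt from an
optical-density time course, and the one-tailed hypergeometric (Fisher's
exact) enrichment of a predicted target set in reported binding targets.
"""

import numpy as np

from rewirescope import evaluate

# exponential growth at 0.9/h slowing into saturation
t = np.linspace(0.0, 8.0, 17)
a595 = 0.02 * np.exp(0.9 * t) / (1 + 0.02 * (np.exp(0.9 * t) - 1) / 1.4)
rates = evaluate.growth_rate(t, a595)
print("growth rates (h^-1) along the curve:")
print("  early:", f"{rates[1]:.2f}", " mid:", f"{rates[8]:.2f}", " late:", f"{rates[-2]:.2f}")
print(f"  peak rate {rates.max():.2f}/h at t = {t[rates.argmax()]:.1f} h")

universe = [f"g{i:03d}" for i in range(500)]
reported = universe[:40]                      # binding-assay targets
predicted = universe[:12] + universe[450:456]  # 12 hits + 6 misses
res = evaluate.enrichment_of_sets(universe, reported, predicted)
print(f"\nenrichment: {res.overlap}/{res.predicted} predictions among "
      f"{res.reported} reported targets in a {res.universe}-gene universe")
print(f"one-tailed p = {res.p:.3g}")
# The early-phase rate approaches the true exponential constant and the
# overlap of 12/18 predictions is far beyond chance (p << 0.001).
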