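"""Score a gene-set state and rank candidate regulators by correlation.

The ribosomal-like state score of a construct is the summed log2 fold change
over the state's member genes. Correlating every other gene's profile with
the score ranks candidate regulators; an additive linear model of the top
drivers quantifies how much of the state they explain together.
"""

import pandas as pd

from rewirescope import diffexpr, scores, simulate
from rewirescope.datatypes import GeneSet

network, designs, params, info = simulate.default_study(seed=0)
matrix, _, _ = simulate.simulate_rewired_experiment(network, designs, params)
fc = pd.DataFrame(
    {c: diffexpr.de_analysis(matrix, c).table["log2fc"] for c in matrix.constructs()}
)

ribo = info["ribosomal"]
geneset = GeneSet("ribosomal", members=ribo.members, excluded=ribo.drivers)
score = scores.geneset_score(fc, geneset)
ranked = scores.rank_regulators(fc, score, candidates=set(fc.index) - set(ribo.members))

print("top candidate regulators by |R| with the ribosomal score:")
print(ranked.head(5).to_string(float_format=lambda v: f"{v:.3g}"))

drivers = list(info["ribosomal_drivers"])
r2 = scores.variance_explained(score, fc.loc[drivers].T)
print(f"\nplanted drivers: {', '.join(drivers)}")
print(f"additive variance explained by the drivers: {100 * r2:.0f}%")

flag_member = sorted(info["flagellar"].members)[0]
r, p = scores.antagonism(fc, drivers[0], flag_member)
print(f"driver vs flagellar member: R = {r:.2f} (p = {p:.2g})")
# The planted drivers top the ranking, explain most of the score variance
# additively, and anti-correlate with the antagonistic flagellar state.
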