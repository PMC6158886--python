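"""Decompose a fitness lattice into overall and net epistatic deviations.

Builds a 16-strain fitness table that is exactly multiplicative except for
one injected pairwise interaction, then runs the deviation decomposition
with Holm-corrected Z-tests. Only the injected pair should be flagged.
"""

import numpy as np
import pandas as pd

import galdose as gd

factors = {"GAL2": 0.92, "GAL3": 1.02, "GAL4": 0.97, "GAL80": 0.90}
rows = []
for g in gd.enumerate_genotypes():
    w = float(np.prod([factors[x] for x in g.reduced]))
    if g.reduced == frozenset({"GAL2", "GAL80"}):
        w -= 0.08  # synthetic negative interaction between permease & inhibitor
    rows.append({"genotype": g.code, "fitness_mean": w, "fitness_sem": 0.01})
summary = pd.DataFrame(rows)

table = gd.epistasis_table(summary)
cols = ["genes", "kind", "value", "se", "z", "p_holm", "stars"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v: .4f}"))
print()
print("eps (kind=overall) compares each multi-reduced strain with the product")
print("of its single-reduction fitness values; eps' (kind=net) removes all")
print("lower-order interactions. The injected GAL2+GAL80 deviation of -0.08")
print("is recovered exactly and is the only flagged deviation after Holm")
print("correction. The triple strains were left exactly multiplicative, so")
print("their overall deviations vanish and their net deviations carry the")
print("compensating +0.08 term that the reconstruction identity")
print("(sum of eps' over subsets = eps) requires; with the propagated")
print("uncertainty those terms are not significant.")
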