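"""Simulate one competition sample and apply the FSC-SSC density gate.

Generates a single flow-cytometry sample for the GAL80-halved strain
competing against the reference in 1% galactose, then gates to the densest
35% of events in scatter space and classifies the survivors by mCherry.
"""

import galdose as gd

truth = gd.default_ground_truth("D")
strain = gd.Genotype.from_reduced(["GAL80"])
experiment = gd.simulate_competition(strain, "D", truth, seed=42, n_events=25_000)

sample = experiment.tables[48.0]
gate = gd.density_gate(sample, target_fraction=0.35)
quant = gd.classify_events(gate.apply(sample))

print(f"strain {strain} in environment D (1% galactose), 48 h sample")
print(f"events recorded: {gate.n_total}, retained by gate: {gate.n_retained} "
      f"({gate.fraction:.0%} of total)")
print(f"query cells: {quant.n_query}, reference cells: {quant.n_reference}")
print(f"query fraction: {quant.query_fraction:.3f}")
print(f"normalized expression (query YFP / reference mCherry): "
      f"{gd.normalized_expression(quant):.3f}")
print()
print("The gate keeps the dense healthy-cell cluster and discards debris;")
print("the query fraction and the reference-normalized expression are the")
print("raw ingredients of the fitness and expression estimates.")
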