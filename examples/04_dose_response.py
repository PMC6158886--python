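"""Fit the expression-fitness dose-response model and diagnose saturation.

Runs the full synthetic study, trains the linear model
w = b0 + (b1 + b2 ln g) E on the 0.3% and 1% pure-galactose environments,
and evaluates it on the held-out 2% environment, where galactose import
saturates.
"""

import galdose as gd
from galdose.environments import get_environment

result = gd.run_study(gd.StudyConfig(seed=1))
model = result.dose_response
points = result.dose_response_points

print(f"model (trained on environments E and D, {model.n_points} strain means):")
print(f"  w = {model.intercept:.3f} + ({model.expression_slope:.3f} "
      f"+ {model.interaction:.3f} ln g) E")
print(f"  residual s.d. {model.resid_sd:.4f}")
for conc in (0.1, 0.3, 1.0, 2.0):
    print(f"  slope at {conc}% galactose: {model.slope_at(conc):+.4f}")

held = points[points["environment"] == "F"]
gap = gd.saturation_gap(
    model, held["expression_mean"], held["fitness_mean"],
    galactose=get_environment("F").galactose, substitute_galactose=1.0,
)
print()
print(f"held-out 2% galactose environment ({gap.n_points} strains):")
print(f"  mean residual vs the model's own 2% line:      {gap.mean_residual:+.4f}")
print(f"  mean residual vs the substitute 1% line:       {gap.substitute_residual:+.4f}")
print()
print("The model extrapolated to 2% predicts a steeper expression-fitness")
print("line than observed (negative mean residual), while the 1% line fits")
print("the 2% data far better: the benefit of extra expression saturates")
print("above roughly 1% galactose.")
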