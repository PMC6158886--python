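"""Expression-fitness dose-response model across galactose concentrations.

In pure-galactose environments fitness is, to good approximation, linear in
network expression with an environment-dependent slope. The model fitted
here makes the slope a linear function of log galactose concentration::

    w = b0 + (b1 + b2 * ln g) * E        (form="log", the default)

fitted by ordinary least squares to (expression, fitness, galactose)
triples pooled from the training environments (the study trains on the
0.3% and 1% galactose-only conditions). An alternative form with the slope
linear in g itself is available (``form="linear"``).

Extrapolating the trained model to 2% galactose predicts a steeper
expression-fitness line than observed when galactose import saturates above
~1%; :func:`saturation_gap` quantifies this as the mean signed residual of
held-out points under the model's own prediction and under a substitute
concentration (e.g. evaluating the 1% line against 2% data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm


class UnidentifiableModelError(ValueError):
    pass


@dataclass
class DoseResponseModel:
    """OLS fit of fitness on expression with galactose-dependent slope."""

    form: str  # "log" or "linear"
    intercept: float  # b0
    expression_slope: float  # b1
    interaction: float  # b2 (per ln-percent or per percent galactose)
    se: Tuple[float, float, float]
    resid_sd: float
    n_points: int
    galactose_levels: Tuple[float, ...]  # training concentrations, percent w/v

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.expression_slope, self.interaction])

    def slope_at(self, galactose: float) -> float:
        """Expression-fitness slope at a galactose concentration."""
        if galactose <= 0:
            raise ValueError(f"galactose concentration must be positive, got {galactose}")
        g = np.log(galactose) if self.form == "log" else galactose
        return self.expression_slope + self.interaction * g


def _design(expression: np.ndarray, galactose: np.ndarray, form: str) -> np.ndarray:
    if form == "log":
        gterm = np.log(galactose)
    elif form == "linear":
        gterm = galactose
    else:
        raise ValueError(f"unknown model form {form!r}")
    return np.column_stack([np.ones_like(expression), expression, expression * gterm])


def fit_dose_response(
    expression: Sequence[float],
    fitness: Sequence[float],
    galactose: Sequence[float],
    form: str = "log",
    weights: Optional[Sequence[float]] = None,
) -> DoseResponseModel:
    """Fit the model by (optionally weighted) ordinary least squares.

    Requires at least 4 points spanning at least 2 distinct galactose
    levels; raises :class:`UnidentifiableModelError` on a rank-deficient
    design.
    """
    e = np.asarray(expression, dtype=float)
    w = np.asarray(fitness, dtype=float)
    g = np.asarray(galactose, dtype=float)
    if not (len(e) == len(w) == len(g)):
        raise ValueError("expression, fitness and galactose must have equal length")
    if len(e) < 4:
        raise ValueError(f"need at least 4 points, got {len(e)}")
    levels = np.unique(g)
    if len(levels) < 2:
        raise UnidentifiableModelError(
            "need at least 2 distinct galactose levels to identify the interaction"
        )
    if (g <= 0).any():
        raise ValueError("galactose concentrations must be positive")

    X = _design(e, g, form)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnidentifiableModelError("rank-deficient design matrix")
    if weights is None:
        res = sm.OLS(w, X).fit()
    else:
        res = sm.WLS(w, X, weights=np.asarray(weights, dtype=float)).fit()
    resid_sd = float(np.sqrt(res.scale))
    return DoseResponseModel(
        form=form,
        intercept=float(res.params[0]),
        expression_slope=float(res.params[1]),
        interaction=float(res.params[2]),
        se=tuple(float(s) for s in res.bse),
        resid_sd=resid_sd,
        n_points=len(e),
        galactose_levels=tuple(float(v) for v in levels),
    )


def predict(
    model: DoseResponseModel,
    expression: Union[float, Sequence[float]],
    galactose: float,
) -> np.ndarray:
    """Model fitness at the requested expression level(s) and concentration."""
    if galactose <= 0:
        raise ValueError(f"galactose concentration must be positive, got {galactose}")
    e = np.asarray(expression, dtype=float)
    return model.intercept + model.slope_at(galactose) * e


@dataclass
class SaturationGap:
    """Mean signed residuals of held-out points against two predictions."""

    galactose: float
    mean_residual: float  # observed - predicted at the held-out concentration
    substitute_galactose: Optional[float]
    substitute_residual: Optional[float]  # same points vs the substitute line
    n_points: int


def saturation_gap(
    model: DoseResponseModel,
    expression: Sequence[float],
    fitness: Sequence[float],
    galactose: float,
    substitute_galactose: Optional[float] = None,
) -> SaturationGap:
    """Mean (observed - predicted) for held-out points at one concentration.

    A strongly negative residual under the model's own line, with a
    smaller-magnitude residual when the line for ``substitute_galactose``
    is used instead, is the signature of a saturated dose response.
    """
    e = np.asarray(expression, dtype=float)
    w = np.asarray(fitness, dtype=float)
    if len(e) == 0:
        raise ValueError("held-out set is empty")
    resid = float(np.mean(w - predict(model, e, galactose)))
    sub_resid = None
    if substitute_galactose is not None:
        sub_resid = float(np.mean(w - predict(model, e, substitute_galactose)))
    return SaturationGap(
        galactose=float(galactose),
        mean_residual=resid,
        substitute_galactose=substitute_galactose,
        substitute_residual=sub_resid,
        n_points=len(e),
    )


def plot_dose_response(
    model: DoseResponseModel,
    points: pd.DataFrame,
    concentrations: Sequence[float] = (0.1, 0.3, 1.0, 2.0),
    ax=None,
):
    """Expression-vs-fitness scatter with model lines per concentration.

    ``points`` needs columns ``expression``, ``fitness`` and optionally
    ``environment`` for coloring. Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if "environment" in points.columns:
        for env, df in points.groupby("environment"):
            ax.errorbar(
                df["expression"], df["fitness"],
                yerr=df["fitness_sem"] if "fitness_sem" in df.columns else None,
                fmt="o", ms=4, label=f"env {env}",
            )
        ax.legend(fontsize=8)
    else:
        ax.plot(points["expression"], points["fitness"], "o", ms=4)
    e_grid = np.linspace(points["expression"].min(), points["expression"].max(), 50)
    styles = [":", "--", "-", "-."]
    for conc, ls in zip(concentrations, styles):
        ax.plot(e_grid, predict(model, e_grid, conc), ls, lw=1, label=f"{conc}% gal")
    ax.set_xlabel("normalized expression")
    ax.set_ylabel("relative fitness")
    return ax
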