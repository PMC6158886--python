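"""The six competition environments.

Each environment is a combination of galactose (the inducing, metabolizable
sugar) and mannose (a neutral, non-inducing carbon source), in percent w/v.
The presets span the natural induction spectrum of the GAL network: a
minimal-galactose/moderate-mannose condition (A), its mirror (B), and four
pure-galactose conditions from 0.1% to 2%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Union


@dataclass(frozen=True)
class Environment:
    name: str
    galactose: float  # percent w/v
    mannose: float  # percent w/v

    def __post_init__(self) -> None:
        if self.galactose < 0 or self.mannose < 0:
            raise ValueError(
                f"sugar concentrations must be non-negative, got "
                f"galactose={self.galactose}, mannose={self.mannose}"
            )


ENVIRONMENTS: Dict[str, Environment] = {
    "A": Environment("A", galactose=0.03, mannose=0.1),
    "B": Environment("B", galactose=0.1, mannose=0.03),
    "C": Environment("C", galactose=0.1, mannose=0.0),
    "D": Environment("D", galactose=1.0, mannose=0.0),
    "E": Environment("E", galactose=0.3, mannose=0.0),
    "F": Environment("F", galactose=2.0, mannose=0.0),
}


def get_environment(env: Union[str, Environment]) -> Environment:
    """Resolve an environment given by preset letter or an Environment object."""
    if isinstance(env, Environment):
        return env
    try:
        return ENVIRONMENTS[env]
    except KeyError:
        raise KeyError(
            f"unknown environment {env!r}; presets are {sorted(ENVIRONMENTS)}"
        ) from None
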