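"""Per-cell event tables and their plain-text round-trip format.

An :class:`EventTable` holds one flow-cytometry sample: one row per recorded
cell with forward scatter (FSC), side scatter (SSC) and the two fluorescence
channels (YFP for the P_GAL1 network-activity reporter of the query strain,
mCherry for the constitutive P_TEF1 reporter of the reference strain), plus
the sample's metadata (genotype, environment, replicate, timepoint).

Tables are stored as CSV with ``#``-prefixed metadata header lines so that a
written table reads back bit-identically (floats are serialized with 17
significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .genotypes import Genotype

#: Channel column order used everywhere.
CHANNELS: Tuple[str, str, str, str] = ("FSC", "SSC", "YFP", "mCherry")

#: The three measurement timepoints of the competition period, in hours.
TIMEPOINTS: Tuple[float, float, float] = (0.0, 24.0, 48.0)


class EventTableParseError(ValueError):
    """Raised when an event file is malformed; carries 1-based line context."""

    def __init__(self, path: Union[str, Path], line: Optional[int], message: str):
        self.path = str(path)
        self.line = line
        where = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{where}: {message}")


@dataclass
class EventTable:
    """One sample's events plus metadata. ``data`` has the :data:`CHANNELS` columns."""

    data: pd.DataFrame
    genotype: Optional[Genotype] = None
    environment: Optional[str] = None
    replicate: Optional[int] = None
    timepoint: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing channel columns {missing}")
        if len(self.data) < 1:
            raise ValueError("event table must contain at least one event")
        values = self.data[list(CHANNELS)].to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("event table contains non-finite channel values")
        if (values < 0).any():
            raise ValueError("event table contains negative channel values")

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def equals(self, other: "EventTable") -> bool:
        return (
            self.genotype == other.genotype
            and self.environment == other.environment
            and self.replicate == other.replicate
            and self.timepoint == other.timepoint
            and self.data[list(CHANNELS)].equals(other.data[list(CHANNELS)])
        )


@dataclass
class CompetitionExperiment:
    """Event tables at 0/24/48 h for one genotype x environment x replicate."""

    genotype: Genotype
    environment: str
    replicate: int
    init_fraction: float
    tables: Dict[float, EventTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.init_fraction < 1.0):
            raise ValueError(f"init_fraction must be in (0, 1), got {self.init_fraction}")
        missing = [t for t in TIMEPOINTS if t not in self.tables]
        if missing:
            raise ValueError(f"experiment missing timepoints {missing}")

    @property
    def timepoints(self) -> Tuple[float, ...]:
        return tuple(sorted(self.tables))


# ---------------------------------------------------------------------------
# Plain-text round-trip I/O
# ---------------------------------------------------------------------------

_META_FIELDS = ("genotype", "environment", "replicate", "timepoint")


def write_events(path: Union[str, Path], table: EventTable) -> None:
    """Write an event table as CSV with ``#``-prefixed metadata lines."""
    path = Path(path)
    meta = {
        "genotype": table.genotype.code if table.genotype is not None else "",
        "environment": table.environment if table.environment is not None else "",
        "replicate": "" if table.replicate is None else str(table.replicate),
        "timepoint": "" if table.timepoint is None else repr(float(table.timepoint)),
    }
    with path.open("w") as fh:
        for key in _META_FIELDS:
            fh.write(f"# {key}={meta[key]}\n")
        fh.write(",".join(CHANNELS) + "\n")
        table.data[list(CHANNELS)].to_csv(
            fh, header=False, index=False, float_format="%.17g"
        )


def read_events(path: Union[str, Path]) -> EventTable:
    """Read an event table written by :func:`write_events`.

    Raises :class:`EventTableParseError` with line context on malformed input
    (missing columns, non-numeric or negative channel values).
    """
    path = Path(path)
    meta: Dict[str, str] = {}
    n_meta = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()

    try:
        data = pd.read_csv(path, comment="#", dtype=float, float_precision="round_trip")
    except ValueError as exc:
        raise EventTableParseError(path, None, f"could not parse events: {exc}") from exc

    missing = [c for c in CHANNELS if c not in data.columns]
    if missing:
        raise EventTableParseError(
            path, n_meta + 1, f"missing channel columns {missing}"
        )
    values = data[list(CHANNELS)].to_numpy()
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        # +1 header line, +1 for 1-based numbering
        raise EventTableParseError(
            path, n_meta + 2 + row, "negative or non-finite channel value"
        )

    genotype = Genotype.from_code(meta["genotype"]) if meta.get("genotype") else None
    timepoint = float(meta["timepoint"]) if meta.get("timepoint") else None
    replicate = int(meta["replicate"]) if meta.get("replicate") else None
    return EventTable(
        data=data,
        genotype=genotype,
        environment=meta.get("environment") or None,
        replicate=replicate,
        timepoint=timepoint,
    )
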