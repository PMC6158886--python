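"""Classify gated events and quantify population ratios and expression.

The reference strain carries a constitutive P_TEF1-mCherry reporter, so
classification is on the mCherry channel alone: events above a threshold are
reference cells, the rest are query cells. The threshold defaults to the
minimum of the smoothed log-mCherry histogram between its two largest modes
(the two strains form well-separated log-normal modes); a fixed threshold
can be supplied instead.

Expression is the mean YFP of query cells normalized by the mean mCherry of
reference cells from the same sample — this controls for instrument drift
and cell-density effects. A strain's expression level per replicate is the
average of the three timepoint values (0/24/48 h); the strain estimate is
the mean over replicates with s.e.m. = sd / sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema

from .events import EventTable


class UnquantifiableSampleError(ValueError):
    """A sample with an empty query or reference population."""


@dataclass
class SampleQuant:
    """Quantification of one gated sample."""

    n_query: int
    n_reference: int
    mean_yfp_query: float
    mean_mcherry_reference: float
    threshold: float

    @property
    def query_fraction(self) -> float:
        return self.n_query / (self.n_query + self.n_reference)


def find_mcherry_threshold(
    mcherry: np.ndarray, bins: int = 128, smooth_sigma: float = 2.0
) -> float:
    """Valley threshold between the two largest modes of log-mCherry.

    Falls back to the midpoint of the log range when fewer than two modes
    are found (e.g. a nearly pure sample).
    """
    logv = np.log1p(np.asarray(mcherry, dtype=float))
    lo, hi = logv.min(), logv.max()
    if hi <= lo:
        return float(np.expm1(lo))
    hist, edges = np.histogram(logv, bins=bins, range=(lo, hi))
    smooth = gaussian_filter1d(hist.astype(float), smooth_sigma)
    peaks = argrelextrema(smooth, np.greater_equal, order=2)[0]
    # drop plateaus: keep strictly distinct peak positions with mass
    peaks = peaks[smooth[peaks] > 0]
    if len(peaks) < 2:
        return float(np.expm1((lo + hi) / 2.0))
    top_two = peaks[np.argsort(smooth[peaks])[-2:]]
    left, right = int(top_two.min()), int(top_two.max())
    if right - left < 2:
        return float(np.expm1((lo + hi) / 2.0))
    valley = left + int(np.argmin(smooth[left : right + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(np.expm1(centers[valley]))


def classify_events(
    gated: Union[EventTable, pd.DataFrame],
    mcherry_threshold: Optional[float] = None,
) -> SampleQuant:
    """Partition gated events into query (low mCherry) and reference (high).

    Raises :class:`UnquantifiableSampleError` if either population is empty.
    """
    data = gated.data if isinstance(gated, EventTable) else gated
    mch = data["mCherry"].to_numpy(dtype=float)
    yfp = data["YFP"].to_numpy(dtype=float)

    if mcherry_threshold is None:
        mcherry_threshold = find_mcherry_threshold(mch)
    if mcherry_threshold <= 0:
        raise ValueError(f"mCherry threshold must be positive, got {mcherry_threshold}")

    is_ref = mch > mcherry_threshold
    n_ref = int(is_ref.sum())
    n_query = len(mch) - n_ref
    if n_query == 0:
        raise UnquantifiableSampleError("no query events below the mCherry threshold")
    if n_ref == 0:
        raise UnquantifiableSampleError("no reference events above the mCherry threshold")

    return SampleQuant(
        n_query=n_query,
        n_reference=n_ref,
        mean_yfp_query=float(yfp[~is_ref].mean()),
        mean_mcherry_reference=float(mch[is_ref].mean()),
        threshold=float(mcherry_threshold),
    )


def population_ratio(quant: SampleQuant) -> float:
    """Query:reference odds, n_query / n_reference."""
    if quant.n_reference < 1:
        raise UnquantifiableSampleError("cannot form a ratio with zero reference events")
    return quant.n_query / quant.n_reference


def normalized_expression(quant: SampleQuant) -> float:
    """Mean query YFP divided by mean reference mCherry of the same sample."""
    if quant.mean_mcherry_reference <= 0:
        raise UnquantifiableSampleError("degenerate sample: zero reference mCherry mean")
    return quant.mean_yfp_query / quant.mean_mcherry_reference


@dataclass
class ExpressionEstimate:
    """Per-strain expression level: mean over replicates of 3-timepoint means."""

    value: float
    sem: float
    n_replicates: int


def expression_estimate(values: Union[np.ndarray, Sequence[Sequence[float]]]) -> ExpressionEstimate:
    """Combine per-timepoint normalized expression into a strain estimate.

    ``values`` has shape (n_replicates, 3): one row per replicate with the
    three timepoint values. Each replicate contributes the mean of its three
    values; the strain estimate is the mean over replicates with
    s.e.m. = sample sd / sqrt(N).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected shape (n_replicates, 3), got {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 replicates for an s.e.m.")
    if not np.isfinite(arr).all():
        raise ValueError("incomplete experiment: missing timepoint value")
    per_rep = arr.mean(axis=1)
    n = len(per_rep)
    return ExpressionEstimate(
        value=float(per_rep.mean()),
        sem=float(per_rep.std(ddof=1) / np.sqrt(n)),
        n_replicates=n,
    )
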