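"""Dynamic range of a feature series: the interquartile range.

A participant's usable variability in a feature (the height of their box in
a per-participant boxplot) is summarized as IQR = Q3 - Q1 of the per-segment
feature values, sessions concatenated. Quantiles use linear interpolation
between order statistics (Hyndman-Fan type 7, numpy's default), declared
once so every reported IQR is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qeeg import FeatureSeries

__all__ = ["iqr", "DynamicRange", "dynamic_ranges", "MIN_SEGMENTS"]

logger = logging.getLogger(__name__)

#: Fewer values than this cannot meaningfully pin down both quartiles.
MIN_SEGMENTS = 4


def iqr(values) -> float:
    """Interquartile range Q3 - Q1 under type-7 (linear interpolation) quantiles."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size < MIN_SEGMENTS:
        raise ValueError(f"IQR needs at least {MIN_SEGMENTS} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("IQR input contains non-finite values")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(q3 - q1)


@dataclass
class DynamicRange:
    participant: str
    feature: str
    iqr: float
    n_segments: int


def dynamic_ranges(features: list[FeatureSeries]) -> list[DynamicRange]:
    """One IQR record per (participant, feature), sessions concatenated.

    Series sharing a participant and feature (e.g. a task session plus the
    flanking resting periods) are concatenated in input order before the
    IQR. Groups with fewer than :data:`MIN_SEGMENTS` values are dropped
    with a log message rather than raising, so one participant's missing
    session does not abort a cohort run.
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    order: list[tuple[str, str]] = []
    for fs in features:
        if fs.values.size == 0:
            raise ValueError(
                f"empty feature series ({fs.participant}, {fs.feature}, {fs.session})"
            )
        key = (fs.participant, fs.feature)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(fs.values)
    out: list[DynamicRange] = []
    for key in sorted(order):
        values = np.concatenate(groups[key])
        if values.size < MIN_SEGMENTS:
            logger.warning(
                "dropping (%s, %s): only %d segments", key[0], key[1], values.size
            )
            continue
        out.append(DynamicRange(key[0], key[1], iqr(values), int(values.size)))
    return out


def to_frame(records: list[DynamicRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.participant, r.feature, r.iqr, r.n_segments) for r in records],
        columns=["participant", "feature", "iqr", "n_segments"],
    )
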