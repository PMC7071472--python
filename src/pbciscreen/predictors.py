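"""The 112 candidate resting-state qEEG predictors.

From one 60-s resting recording, every combination of

* 8 frequency bands (delta, theta, alpha1, alpha2, alpha3, low-beta, beta,
  and the 2-18 Hz full band),
* 7 per-segment quantities (absolute power at Fp1, Fp2 and their mean;
  relative power at Fp1, Fp2 and their mean; interhemispheric asymmetry
  ln(P_Fp1/P_Fp2) of the absolute powers), and
* 2 summary statistics over the artifact-free segments (mean and IQR)

yields 8 x 7 x 2 = 112 named scalars. Names follow the
``[Mean|IQR]-[Abs|Rel|Asym]-[Fp1|Fp2|Fp12]-[band]`` convention, e.g.
``IQR-Asym-Alpha-8-12`` or ``Mean-Rel-Fp12-Theta-4-8`` (asymmetry is a
two-channel quantity, so its names carry no channel token). The two
full-band relative predictors are identically 1 (mean) and 0 (IQR); they
are kept so the vocabulary count stays 112, and feature selection simply
never gains from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynrange import MIN_SEGMENTS, iqr
from .qeeg import BAND_ORDER, BANDS, BandDef, segment_band_powers
from .recording import SegmentSeries

__all__ = [
    "predictor_name",
    "PREDICTOR_NAMES",
    "PredictorVector",
    "extract_candidate_predictors",
    "predictors_to_frame",
    "read_predictor_table",
]

#: (kind, channel) in canonical order; channel is None for asymmetry.
KINDS: tuple[tuple[str, str | None], ...] = (
    ("Abs", "Fp1"),
    ("Abs", "Fp2"),
    ("Abs", "Fp12"),
    ("Rel", "Fp1"),
    ("Rel", "Fp2"),
    ("Rel", "Fp12"),
    ("Asym", None),
)

STATS: tuple[str, ...] = ("Mean", "IQR")


def predictor_name(stat: str, kind: str, channel: str | None, band: BandDef) -> str:
    """Canonical predictor name, e.g. ``("IQR", "Asym", None, alpha3) -> "IQR-Asym-Alpha-8-12"``."""
    if stat not in STATS:
        raise ValueError(f"stat must be one of {STATS}, got {stat!r}")
    if kind == "Asym":
        if channel is not None:
            raise ValueError("asymmetry predictors carry no channel token")
        return f"{stat}-Asym-{band.label}"
    if kind not in ("Abs", "Rel"):
        raise ValueError(f"kind must be Abs, Rel or Asym, got {kind!r}")
    if channel not in ("Fp1", "Fp2", "Fp12"):
        raise ValueError(f"channel must be Fp1, Fp2 or Fp12 for {kind}, got {channel!r}")
    return f"{stat}-{kind}-{channel}-{band.label}"


def _vocabulary() -> list[str]:
    names = []
    for band_key in BAND_ORDER:
        band = BANDS[band_key]
        for kind, channel in KINDS:
            for stat in STATS:
                names.append(predictor_name(stat, kind, channel, band))
    return names


#: The fixed, ordered 112-name vocabulary.
PREDICTOR_NAMES: tuple[str, ...] = tuple(_vocabulary())
assert len(PREDICTOR_NAMES) == 112 and len(set(PREDICTOR_NAMES)) == 112


@dataclass
class PredictorVector:
    """One participant's 112 resting-state predictor values, by canonical name."""

    participant: str
    values: dict[str, float]
    provenance: str = "resting"

    def __post_init__(self) -> None:
        missing = set(PREDICTOR_NAMES) - set(self.values)
        extra = set(self.values) - set(PREDICTOR_NAMES)
        if missing or extra:
            raise ValueError(
                f"predictor vector must carry exactly the 112 canonical names; "
                f"missing={sorted(missing)[:3]}..., extra={sorted(extra)[:3]}..."
                if missing and extra
                else f"predictor vector mismatch: missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]}"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite predictor values: {bad[:5]}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in PREDICTOR_NAMES])


def series_matrix(series: SegmentSeries) -> dict[str, np.ndarray]:
    """Per-segment series of all 56 band x kind quantities, keyed by ``kind-channel-band``-ish names.

    Internal helper shared with the synthetic generator's truth bookkeeping:
    given per-segment band powers, produce the per-segment series whose mean
    and IQR are the 112 predictors.
    """
    powers = segment_band_powers(series)  # (n_valid, n_ch, 8)
    i1 = series.channel_index("Fp1")
    i2 = series.channel_index("Fp2")
    return band_power_series_to_predictor_series(powers[:, i1, :], powers[:, i2, :])


def band_power_series_to_predictor_series(
    p1: np.ndarray, p2: np.ndarray
) -> dict[str, np.ndarray]:
    """Map per-segment band-power series at Fp1/Fp2 to the 56 per-segment predictor series.

    ``p1``/``p2`` have shape ``(n_segments, 8)`` in :data:`BAND_ORDER` order.
    Relative powers divide by the same channel's (or channel-mean's) total
    power; asymmetry uses absolute powers.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.shape != p2.shape or p1.shape[1] != len(BAND_ORDER):
        raise ValueError("expected (n_segments, 8) band-power arrays")
    if np.any(p1 <= 0) or np.any(p2 <= 0):
        raise ValueError("non-positive band power in a segment")
    itot = BAND_ORDER.index("total")
    pm = 0.5 * (p1 + p2)
    out: dict[str, np.ndarray] = {}
    for bi, band_key in enumerate(BAND_ORDER):
        band = BANDS[band_key]
        per_kind = {
            ("Abs", "Fp1"): p1[:, bi],
            ("Abs", "Fp2"): p2[:, bi],
            ("Abs", "Fp12"): pm[:, bi],
            ("Rel", "Fp1"): p1[:, bi] / p1[:, itot],
            ("Rel", "Fp2"): p2[:, bi] / p2[:, itot],
            ("Rel", "Fp12"): pm[:, bi] / pm[:, itot],
            ("Asym", None): np.log(p1[:, bi] / p2[:, bi]),
        }
        for (kind, channel), values in per_kind.items():
            out[predictor_name("Mean", kind, channel, band)] = values
            out[predictor_name("IQR", kind, channel, band)] = values
    return out


def summarize_predictor_series(
    series_by_name: dict[str, np.ndarray], participant: str, provenance: str = "resting"
) -> PredictorVector:
    """Apply the Mean/IQR summary named in each key to its per-segment series."""
    values: dict[str, float] = {}
    for name in PREDICTOR_NAMES:
        s = series_by_name[name]
        if name.startswith("Mean-"):
            values[name] = float(np.mean(s))
        else:
            values[name] = iqr(s)
    return PredictorVector(participant, values, provenance)


def extract_candidate_predictors(
    resting: SegmentSeries, participant: str = "", provenance: str = "resting"
) -> PredictorVector:
    """Compute the 112 predictors from an artifact-free resting segment series."""
    if resting.n_valid < MIN_SEGMENTS:
        raise ValueError(
            f"need at least {MIN_SEGMENTS} valid resting segments, "
            f"got {resting.n_valid}"
        )
    return summarize_predictor_series(series_matrix(resting), participant, provenance)


def predictors_to_frame(vectors: list[PredictorVector]) -> pd.DataFrame:
    """One row per participant, 112 named columns, canonical order."""
    rows = {v.participant: [v.values[n] for n in PREDICTOR_NAMES] for v in vectors}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(PREDICTOR_NAMES))
    df.index.name = "participant"
    return df


def read_predictor_table(path) -> pd.DataFrame:
    """Read a predictor table, validating the full 112-name vocabulary."""
    df = pd.read_csv(path, index_col="participant")
    if list(df.columns) != list(PREDICTOR_NAMES):
        missing = set(PREDICTOR_NAMES) - set(df.columns)
        extra = set(df.columns) - set(PREDICTOR_NAMES)
        raise ValueError(
            f"predictor table vocabulary mismatch: missing {sorted(missing)[:5]}, "
            f"unexpected {sorted(extra)[:5]}"
        )
    return df
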