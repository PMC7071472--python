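"""Quantitative EEG band powers and the three target pBCI features.

Band powers are periodogram estimates (rectangular window, one-sided) on
1-s segments, so the frequency resolution is 1 Hz and a band integral is a
plain sum of PSD bins times the bin width. Band intervals are half-open
``[lo, hi)`` so that the five disjoint bands delta/theta/alpha(8-12)/
low-beta/beta exactly partition the 2-18 Hz total band, and shared edges
(4, 8, 12, 15 Hz) are never counted twice.

The three features screened for passive-BCI use are

* **FAA** — frontal alpha asymmetry, ``ln(P_alpha(Fp1) / P_alpha(Fp2))``
  with alpha taken as 10-12 Hz; a valence marker.
* **rFTP** — relative frontal theta power (4-8 Hz over total 2-18 Hz,
  powers averaged across Fp1/Fp2 before the ratio); a relaxation marker.
* **rFLBP** — relative frontal low-beta power (12-15 Hz over total), same
  channel averaging; an attention marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import SegmentSeries

__all__ = [
    "BandDef",
    "BANDS",
    "BAND_ORDER",
    "FEATURES",
    "band_power",
    "relative_power",
    "asymmetry",
    "faa",
    "feature_series",
    "FeatureSeries",
    "segment_band_powers",
]


@dataclass(frozen=True)
class BandDef:
    """A half-open frequency band ``[lo, hi)`` with its table-style label."""

    name: str
    lo: float
    hi: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


#: Canonical band set. alpha1/alpha2 deliberately leave 9-10 Hz uncovered and
#: alpha3 overlaps both; this mirrors the screening convention as printed in
#: the source tables rather than a tidied-up partition.
BANDS: dict[str, BandDef] = {
    "delta": BandDef("delta", 2.0, 4.0, "Delta-2-4"),
    "theta": BandDef("theta", 4.0, 8.0, "Theta-4-8"),
    "alpha1": BandDef("alpha1", 8.0, 9.0, "Alpha-8-9"),
    "alpha2": BandDef("alpha2", 10.0, 12.0, "Alpha-10-12"),
    "alpha3": BandDef("alpha3", 8.0, 12.0, "Alpha-8-12"),
    "low_beta": BandDef("low_beta", 12.0, 15.0, "Beta-12-15"),
    "beta": BandDef("beta", 15.0, 18.0, "Beta-15-18"),
    "total": BandDef("total", 2.0, 18.0, "total"),
}

#: Fixed enumeration order for the predictor vocabulary.
BAND_ORDER: tuple[str, ...] = (
    "delta", "theta", "alpha1", "alpha2", "alpha3", "low_beta", "beta", "total",
)

FEATURES: tuple[str, ...] = ("FAA", "rFTP", "rFLBP")

#: Feature -> band carrying it.
FEATURE_BANDS: dict[str, str] = {"FAA": "alpha2", "rFTP": "theta", "rFLBP": "low_beta"}


def _psd(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    return signal.periodogram(x, fs=rate, window="boxcar", detrend=False, axis=-1)


def band_power(x: np.ndarray, band: BandDef, rate: float) -> float:
    """Periodogram power of ``x`` in ``[band.lo, band.hi)``, in signal units squared.

    For a 1-s segment the periodogram bins sit on integer frequencies, so a
    bin-centered sinusoid of amplitude A contributes exactly A^2/2.
    """
    x = np.asarray(x, dtype=np.float64)
    if band.hi > rate / 2.0:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}) exceeds Nyquist {rate / 2.0} Hz"
        )
    f, psd = _psd(x, rate)
    df = f[1] - f[0]
    mask = (f >= band.lo) & (f < band.hi)
    return float(psd[..., mask].sum(axis=-1) * df)


def relative_power(x: np.ndarray, band: BandDef, rate: float) -> float:
    """Band power divided by total (2-18 Hz) power; in (0, 1] for sub-bands."""
    total = band_power(x, BANDS["total"], rate)
    if total <= 0.0:
        raise ValueError("degenerate segment: zero total 2-18 Hz power")
    return band_power(x, band, rate) / total


def asymmetry(p_fp1: float, p_fp2: float) -> float:
    """Interhemispheric asymmetry ln(P_Fp1 / P_Fp2), antisymmetric under swap."""
    if p_fp1 <= 0.0 or p_fp2 <= 0.0:
        raise ValueError(f"asymmetry requires positive powers, got ({p_fp1}, {p_fp2})")
    return float(np.log(p_fp1 / p_fp2))


def faa(segment_fp1: np.ndarray, segment_fp2: np.ndarray, rate: float) -> float:
    """Frontal alpha asymmetry of one segment: ln of the 10-12 Hz power ratio."""
    alpha2 = BANDS["alpha2"]
    return asymmetry(
        band_power(segment_fp1, alpha2, rate), band_power(segment_fp2, alpha2, rate)
    )


@dataclass
class FeatureSeries:
    """Per-valid-segment values of one named feature for one participant/session."""

    feature: str
    values: np.ndarray
    session: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite {self.feature} values")


def segment_band_powers(
    series: SegmentSeries, bands: list[BandDef] | None = None
) -> np.ndarray:
    """Band powers of every *valid* segment and channel in one pass.

    Returns shape ``(n_valid, n_channels, n_bands)``. Computing the full
    periodogram once per segment and integrating each band from it is what
    makes the 112-predictor extraction cheap.
    """
    if bands is None:
        bands = [BANDS[n] for n in BAND_ORDER]
    segs = series.valid_segments()
    if segs.shape[0] == 0:
        raise ValueError("no valid segments")
    f, psd = _psd(segs, series.rate)
    df = f[1] - f[0]
    out = np.empty(segs.shape[:2] + (len(bands),))
    for bi, band in enumerate(bands):
        if band.hi > series.rate / 2.0:
            raise ValueError(f"band {band.name} exceeds Nyquist")
        mask = (f >= band.lo) & (f < band.hi)
        out[..., bi] = psd[..., mask].sum(axis=-1) * df
    return out


def feature_series(
    series: SegmentSeries,
    feature: str,
    session: str = "",
    participant: str = "",
) -> FeatureSeries:
    """Compute FAA, rFTP or rFLBP on every valid segment of a recording.

    FAA is the per-segment ln ratio of 10-12 Hz powers at Fp1 vs Fp2. For
    the relative powers, absolute band power and total power are each
    averaged across the two channels before the ratio is taken.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")
    if series.n_valid < 1:
        raise ValueError("no valid segments to compute features on")
    i1 = series.channel_index("Fp1")
    i2 = series.channel_index("Fp2")
    band = BANDS[FEATURE_BANDS[feature]]
    powers = segment_band_powers(series, [band, BANDS["total"]])
    if feature == "FAA":
        p1, p2 = powers[:, i1, 0], powers[:, i2, 0]
        if np.any(p1 <= 0) or np.any(p2 <= 0):
            raise ValueError("non-positive alpha power in a segment")
        values = np.log(p1 / p2)
    else:
        band_mean = powers[:, (i1, i2), 0].mean(axis=1)
        total_mean = powers[:, (i1, i2), 1].mean(axis=1)
        if np.any(total_mean <= 0):
            raise ValueError("degenerate segment: zero total power")
        values = band_mean / total_mean
    return FeatureSeries(feature, values, session=session, participant=participant)
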