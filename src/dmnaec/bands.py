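"""Canonical frequency bands and zero-phase narrowband filtering.

The analysis partitions 2–90 Hz into six bands: delta (2–4 Hz), theta
(5–7 Hz), alpha (8–12 Hz), beta (15–29 Hz), gamma1 (30–59 Hz) and
gamma2 (60–90 Hz).  The gaps between bands (4–5, 7–8, 12–15, 29–30 Hz)
belong to no band; they contribute only to total-power denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandSpec:
    """A closed frequency interval [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: need 0 < f_lo < f_hi, "
                             f"got ({self.f_lo}, {self.f_hi})")

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name} ({self.f_lo}-{self.f_hi} Hz) exceeds the "
                f"Nyquist frequency {fs / 2:g} Hz at fs={fs:g} Hz")

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


DELTA = BandSpec("delta", 2.0, 4.0)
THETA = BandSpec("theta", 5.0, 7.0)
ALPHA = BandSpec("alpha", 8.0, 12.0)
BETA = BandSpec("beta", 15.0, 29.0)
GAMMA1 = BandSpec("gamma1", 30.0, 59.0)
GAMMA2 = BandSpec("gamma2", 60.0, 90.0)

CANONICAL_BANDS: tuple[BandSpec, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA1, GAMMA2)

#: Total-power integration range: the span of the defined bands.
TOTAL_RANGE: tuple[float, float] = (2.0, 90.0)


def band_by_name(name: str) -> BandSpec:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; canonical bands are "
                   f"{[b.name for b in CANONICAL_BANDS]}")


def design_bandpass_fir(band: BandSpec, fs: float) -> np.ndarray:
    """Linear-phase FIR bandpass (Hamming-windowed) for one band.

    The transition width is a quarter of min(f_lo, bandwidth), keeping
    >=95% of the filtered-noise power inside the passband even for the
    narrow low bands; taps are forced odd so the filter has an integer
    group delay and 'same'-mode convolution is exactly zero phase.
    """
    band.validate_for_fs(fs)
    transition = 0.25 * min(band.f_lo, band.width)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs)


def bandpass(ts: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase narrowband filter along the last axis.

    A symmetric FIR applied with centred overlap-add convolution: the
    linear-phase delay cancels exactly, so narrowband bursts are not
    shifted in time (envelope timing across ROIs must stay aligned).
    """
    h = design_bandpass_fir(band, fs)
    x = np.asarray(ts, dtype=float)
    if x.shape[-1] < len(h):
        raise ValueError(f"series too short for the {band.name} filter: "
                         f"{x.shape[-1]} samples < {len(h)} taps")
    return signal.oaconvolve(x, h[np.newaxis, :] if x.ndim == 2 else h,
                             mode="same", axes=-1)


def edge_trim_samples(band: BandSpec, fs: float) -> int:
    """Samples to discard at each end before envelope correlation.

    One filter-transient length: max(1 s, 3 / f_lo).
    """
    return int(np.ceil(fs * max(1.0, 3.0 / band.f_lo)))
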