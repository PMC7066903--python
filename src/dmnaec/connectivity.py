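"""Amplitude-envelope correlation (AEC) networks and node strength.

For each band the ROI series are zero-phase bandpass filtered, the
amplitude envelope is the magnitude of the analytic (Hilbert) signal,
and connectivity is the Pearson correlation between envelope pairs over
the whole (masked) recording.  One filter-transient length
(max(1 s, 3/f_lo)) is trimmed at each end before correlating.  The
12x12 adjacency matrix is symmetric with a zero diagonal; node strength
is the sum of a node's incident AEC values.

No leakage (orthogonalization) correction is applied by default; plain
AEC is the metric.  An orthogonalized variant can be layered on by the
caller but is not part of this module's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandSpec, bandpass, edge_trim_samples


def amplitude_envelope(ts: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Hilbert amplitude envelopes of the band-limited ROI series.

    Returned untrimmed (same length as input); callers that correlate
    envelopes should discard ``edge_trim_samples(band, fs)`` at each
    end, where filter transients distort the envelope.
    """
    x = np.atleast_2d(np.asarray(ts, dtype=float))
    trim = edge_trim_samples(band, fs)
    if x.shape[-1] - 2 * trim < 10 * fs:
        raise ValueError(
            f"series too short for {band.name}-band envelopes: need at least "
            f"{(2 * trim + int(10 * fs))} samples (10 s after edge trimming)")
    nb = bandpass(x, band, fs)
    return np.abs(signal.hilbert(nb, axis=-1))


@dataclass(frozen=True)
class AecMatrix:
    values: np.ndarray           # (n_roi, n_roi), symmetric, zero diagonal
    band: str
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        a = self.values
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.roi_names):
            raise ValueError("AEC matrix shape does not match roi_names")
        if np.abs(a - a.T).max() > 1e-10:
            raise ValueError("AEC matrix must be symmetric")
        if np.abs(np.diag(a)).max() > 0:
            raise ValueError("AEC diagonal must be zero")
        if np.abs(a).max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.roi_names),
                            columns=list(self.roi_names))


def _masked_envelopes(ts, band, fs, mask):
    env = amplitude_envelope(ts, band, fs)
    trim = edge_trim_samples(band, fs)
    keep = np.ones(env.shape[-1], dtype=bool)
    keep[:trim] = keep[-trim:] = False
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != env.shape[-1]:
            raise ValueError("mask length does not match the recording")
        keep &= mask
    return env[:, keep]


def aec_matrix(ts: np.ndarray, band: BandSpec, fs: float,
               roi_names: tuple[str, ...] | None = None,
               mask: np.ndarray | None = None) -> AecMatrix:
    """Pearson correlation of envelope pairs over the masked recording.

    Invariant to per-ROI amplitude scaling.  A constant envelope (zero
    variance) yields 0 entries with a warning rather than NaN.
    """
    x = np.atleast_2d(np.asarray(ts, dtype=float))
    n_roi = x.shape[0]
    if n_roi < 2:
        raise ValueError("need at least 2 ROIs")
    names = tuple(roi_names) if roi_names is not None else tuple(
        f"roi{k}" for k in range(n_roi))
    env = _masked_envelopes(x, band, fs, mask)
    sd = env.std(axis=-1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant envelope(s) in band "
                      f"{band.name}; their correlations are set to 0")
    env = env - env.mean(axis=-1, keepdims=True)
    sd_safe = np.where(degenerate, 1.0, sd)
    a = (env @ env.T) / env.shape[-1] / np.outer(sd_safe, sd_safe)
    a[degenerate, :] = 0.0
    a[:, degenerate] = 0.0
    a = np.clip(0.5 * (a + a.T), -1.0, 1.0)
    np.fill_diagonal(a, 0.0)
    return AecMatrix(values=a, band=band.name, roi_names=names)


def node_strength(a: AecMatrix | np.ndarray) -> np.ndarray:
    """Sum of AEC values incident to each node, s_i = sum_{j != i} A_ij."""
    values = a.values if isinstance(a, AecMatrix) else np.asarray(a, dtype=float)
    if np.abs(values - values.T).max() > 1e-10:
        raise ValueError("node strength requires a symmetric adjacency matrix")
    return values.sum(axis=1) - np.diag(values)


def strength_table(subject_id: str, group: str, mats: list[AecMatrix]) -> pd.DataFrame:
    """Tidy (subject, group, roi, band, strength) rows for one subject."""
    rows = []
    for m in mats:
        s = node_strength(m)
        rows.extend((subject_id, group, roi, m.band, s[k])
                    for k, roi in enumerate(m.roi_names))
    return pd.DataFrame(rows, columns=["subject", "group", "roi", "band", "strength"])
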