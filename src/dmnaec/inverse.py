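"""Depth-weighted minimum-norm source estimation on a supplied leadfield.

The distributed inverse maps sensor data to cortical current density:

    W = R G^T (G R G^T + lambda^2 C)^(-1)

with G the (sensors x sources) gain matrix, C the sensor noise
covariance and R a diagonal depth-weighting prior,
R_ii = ||g_i||^(-2*gamma) normalized to max 1, which compensates the
bias of minimum-norm solutions toward superficial sources.  Source
orientations are assumed fixed (one gain column per source).

The regularization follows the convention lambda^2 = 1/SNR (0.33 at the
default SNR of 3); the more common lambda^2 = 1/SNR^2 is available as a
config switch.  ROI time series are plain arithmetic means of member
source series — opposite-facing dipoles cancel, which is documented
behaviour, not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass(frozen=True)
class InverseConfig:
    snr: float = 3.0
    lambda2: float | None = None     # default derived from snr
    depth_exponent: float = 0.5
    convention: str = "reciprocal_snr"   # or "reciprocal_snr_squared"

    def __post_init__(self) -> None:
        if self.convention not in ("reciprocal_snr", "reciprocal_snr_squared"):
            raise ValueError(f"unknown regularization convention {self.convention!r}")
        implied = self._implied()
        if self.lambda2 is not None:
            if self.lambda2 <= 0:
                raise ValueError("lambda2 must be positive")
            if abs(self.lambda2 - implied) > 1e-2 * implied:
                raise ValueError(
                    f"lambda2={self.lambda2} inconsistent with snr={self.snr} "
                    f"under convention {self.convention} (expected {implied:.4g})")

    def _implied(self) -> float:
        return (1.0 / self.snr if self.convention == "reciprocal_snr"
                else 1.0 / self.snr ** 2)

    @property
    def effective_lambda2(self) -> float:
        return self.lambda2 if self.lambda2 is not None else self._implied()


def default_lambda2(snr: float = 3.0) -> float:
    """Regularization parameter as the reciprocal of the SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return 1.0 / snr


def validate_leadfield(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("leadfield must be a (sensors, sources) matrix")
    if not np.all(np.isfinite(G)):
        raise ValueError("leadfield contains non-finite entries")
    if np.any(np.all(G == 0, axis=1)):
        raise ValueError("leadfield has an all-zero sensor row")
    return G


def regularize_covariance(C: np.ndarray) -> np.ndarray:
    """Symmetrize and, if rank-deficient, diagonally load the noise
    covariance with eps = 1e-6 * trace(C)/n (logged via warning)."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("noise covariance must be square")
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
        raise ValueError("noise covariance must be symmetric")
    C = 0.5 * (C + C.T)
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        raise ValueError("noise covariance has negative eigenvalues")
    n = C.shape[0]
    if eigvals.min() <= 1e-12 * max(eigvals.max(), 1.0):
        eps = 1e-6 * np.trace(C) / n
        if eps <= 0:
            eps = 1e-12
        warnings.warn(f"rank-deficient noise covariance: adding {eps:.3g} I")
        C = C + eps * np.eye(n)
    return C


def depth_weights(G: np.ndarray, exponent: float = 0.5) -> np.ndarray:
    """Diagonal of the source prior R: ||g_i||^(-2*exponent), max-normalized."""
    norms = np.linalg.norm(G, axis=0)
    if np.any(norms == 0):
        raise ValueError("leadfield has an all-zero source column")
    r = norms ** (-2.0 * exponent)
    return r / r.max()


def compute_inverse_operator(G: np.ndarray, C: np.ndarray,
                             cfg: InverseConfig = InverseConfig()) -> np.ndarray:
    """The (sources x sensors) linear inverse W = R G^T (G R G^T + l2 C)^-1."""
    G = validate_leadfield(G)
    C = regularize_covariance(C)
    if C.shape[0] != G.shape[0]:
        raise ValueError("leadfield and covariance sensor dimensions differ")
    r = depth_weights(G, cfg.depth_exponent)
    lam2 = cfg.effective_lambda2
    grg = (G * r) @ G.T
    system = grg + lam2 * C
    cond = np.linalg.cond(system)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"inverse system numerically singular (condition number {cond:.3g})")
    return (r[:, None] * G.T) @ linalg.inv(system)


def apply_inverse(sensor_ts: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Project sensor series to source current density (linear map)."""
    x = np.asarray(sensor_ts, dtype=float)
    if x.shape[0] != W.shape[1]:
        raise ValueError(f"inverse operator expects {W.shape[1]} sensors, "
                         f"data has {x.shape[0]}")
    return W @ x


def roi_average(src: np.ndarray, parcellation: dict[str, list[int]],
                roi_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Arithmetic mean of member source rows per ROI.

    Returns (roi x samples matrix, ROI names in output order).  An empty
    ROI is an error; sign cancellation between opposite-oriented member
    sources is deliberate (plain averaging).
    """
    src = np.asarray(src, dtype=float)
    names = list(roi_order) if roi_order is not None else list(parcellation)
    rows = []
    for roi in names:
        members = parcellation.get(roi, [])
        if len(members) == 0:
            raise ValueError(f"ROI {roi!r} has no member sources")
        if max(members) >= src.shape[0] or min(members) < 0:
            raise ValueError(f"ROI {roi!r} references source indices outside "
                             f"0..{src.shape[0] - 1}")
        rows.append(src[members].mean(axis=0))
    return np.array(rows), names
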