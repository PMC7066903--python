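"""Synthetic resting-state cohorts with programmable envelope coupling.

Real recordings behind this kind of analysis are 5-minute, 1000-Hz
resting runs from two groups: healthy controls (HC) and people with
subjective cognitive decline (SCD).  This module replaces them with a
mechanistic generator whose ground truth is known:

* each ROI signal is a sum of narrowband Gaussian components, one per
  frequency band, built by zero-phase FIR filtering of white noise;
* pairwise coupling is injected per band by giving two ROIs a shared
  narrowband component: with mixing weights ``sqrt(1-r)`` (private) and
  ``sqrt(r)`` (shared) the latent signal correlation of a pair is
  exactly ``r``, and the amplitude-envelope correlation (AEC) of a
  jointly Gaussian narrowband pair is then ``~ r**2`` (first order; the
  exact value is :func:`expected_envelope_correlation`);
* SCD subjects receive extra delta- and gamma-band coupling on
  PCC--LTC and PCC--PCu edges, mirroring the elevated default-mode
  connectivity that distinguishes the groups.

A second, summary-level generator draws node-strength tables directly
from published group means/SDs, for analyses (ROC, power checks) that
need only the feature distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, special

from .bands import (ALPHA, BETA, CANONICAL_BANDS, DELTA, GAMMA1, GAMMA2,
                    THETA, BandSpec, bandpass)

#: Canonical 12-region default-mode-network parcellation (bilateral
#: posterior cingulate, precuneus, inferior parietal lobule, medial
#: temporal cortex, medial frontal cortex, lateral temporal cortex).
DMN_ROIS: tuple[str, ...] = (
    "PCC_L", "PCC_R", "PCu_L", "PCu_R", "IPL_L", "IPL_R",
    "MTC_L", "MTC_R", "MFC_L", "MFC_R", "LTC_L", "LTC_R",
)

HC, SCD = "HC", "SCD"


def expected_envelope_correlation(r: float) -> float:
    """Exact large-sample AEC for latent Gaussian signal correlation r.

    For a jointly Gaussian narrowband pair with signal correlation r the
    Rayleigh amplitude envelopes have correlation

        (pi/2) * (2F1(-1/2, -1/2; 1; r^2) - 1) / (2 - pi/2),

    which is r**2 to first order (0.464 at r=0.7, against the nominal
    0.49).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"latent correlation must be in [0, 1], got {r}")
    z = r * r
    return float((np.pi / 2) * (special.hyp2f1(-0.5, -0.5, 1.0, z) - 1.0)
                 / (2.0 - np.pi / 2))


def make_narrowband_noise(fs: float, duration: float, band: BandSpec,
                          seed: int | np.random.SeedSequence | np.random.Generator,
                          ) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian noise band-limited to ``band``.

    White Gaussian noise is zero-phase FIR filtered and standardized;
    >=95% of the Welch power of the result lies inside [f_lo, f_hi].
    """
    band.validate_for_fs(fs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(fs * duration))
    x = bandpass(rng.standard_normal(n), band, fs)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate zero series after filtering")
    return x / sd


@dataclass(frozen=True)
class CouplingSpec:
    """Latent-correlation targets for ROI pairs within one band.

    ``pairs`` holds (roi_i, roi_j, r) with r in [0, 1] the latent
    Gaussian signal correlation; the implied large-sample AEC is
    ``expected_envelope_correlation(r)`` (~ r**2).
    """

    band: BandSpec
    pairs: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        for i, j, r in self.pairs:
            if i == j:
                raise ValueError(f"coupling pair references one ROI twice: {i}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"coupling r must be in [0, 1], got {r} for ({i}, {j})")


def _default_baseline() -> tuple[CouplingSpec, ...]:
    # Modest within-network coupling shared by both groups: a PCC-centred
    # core present at every band, strongest at alpha (resting posterior
    # rhythm).  Values are generator choices; only the qualitative
    # pattern (nonzero HC connectivity, identical across groups) matters.
    core = (("PCC_L", "PCC_R", 0.15), ("PCC_L", "PCu_L", 0.12),
            ("PCC_R", "PCu_R", 0.12), ("PCC_L", "IPL_L", 0.1))
    out = []
    for band in CANONICAL_BANDS:
        scale = {"alpha": 1.4, "beta": 1.0}.get(band.name, 0.8)
        out.append(CouplingSpec(band, tuple((i, j, min(r * scale, 1.0))
                                            for i, j, r in core)))
    return tuple(out)


def _default_scd_extra() -> tuple[CouplingSpec, ...]:
    # SCD-specific elevation on the edges reported as hyperconnected:
    # PCC-LTC and PCC-PCu at delta and both gamma bands.  Weights keep
    # every node's total shared variance below 1 (see simulate_subject).
    edges = (("PCC_L", "LTC_R", 0.35), ("PCC_R", "LTC_L", 0.35),
             ("PCC_R", "PCu_R", 0.35))
    return tuple(CouplingSpec(band, edges) for band in (DELTA, GAMMA1, GAMMA2))


def _default_band_amplitudes() -> dict[str, float]:
    # Alpha-dominant resting spectrum with a 1/f-like decline into gamma.
    return {"delta": 1.0, "theta": 0.7, "alpha": 1.2,
            "beta": 0.6, "gamma1": 0.35, "gamma2": 0.25}


@dataclass(frozen=True)
class CohortConfig:
    """Full generative description of a two-group synthetic cohort.

    Defaults follow the study design the generator stands in for:
    26 HC and 27 SCD subjects, 5-minute recordings digitized at 1000 Hz.
    """

    n_hc: int = 26
    n_scd: int = 27
    fs: float = 1000.0
    duration: float = 300.0
    roi_names: tuple[str, ...] = DMN_ROIS
    baseline_coupling: tuple[CouplingSpec, ...] = field(default_factory=_default_baseline)
    scd_extra_coupling: tuple[CouplingSpec, ...] = field(default_factory=_default_scd_extra)
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    noise_floor: float = 0.1          # broadband white noise SD, signal units
    complaint_model: tuple[float, float, float] = (2.0, 3.0, 0.5)  # intercept, slope, noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_scd < 2:
            raise ValueError("need at least 2 subjects per group")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        welch_window = 5.0
        if self.duration * self.fs < 10 * welch_window * self.fs / 2:
            raise ValueError("recording shorter than 10 Welch windows (5 s, 50% overlap)")
        for spec in (*self.baseline_coupling, *self.scd_extra_coupling):
            spec.band.validate_for_fs(self.fs)
            for i, j, _ in spec.pairs:
                for roi in (i, j):
                    if roi not in self.roi_names:
                        raise ValueError(f"coupling references unknown ROI {roi!r}")

    def bands(self) -> tuple[BandSpec, ...]:
        """Bands carrying signal: any with an amplitude or a coupling."""
        named = {s.band for s in (*self.baseline_coupling, *self.scd_extra_coupling)}
        named |= {b for b in CANONICAL_BANDS if self.band_amplitudes.get(b.name, 0) > 0}
        return tuple(sorted(named, key=lambda b: b.f_lo))


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    roi_ts: np.ndarray            # (n_roi, n_samples)
    fs: float
    roi_names: tuple[str, ...]
    complaint_count: int | None   # 1..12 for SCD, None for HC
    seed_key: int

    def __post_init__(self) -> None:
        if self.roi_ts.shape[0] != len(self.roi_names):
            raise ValueError("roi_ts row count does not match roi_names")
        if self.group == SCD and not (self.complaint_count and 1 <= self.complaint_count <= 12):
            raise ValueError("SCD subjects report 1..12 complaints")


def _merged_pairs(config: CohortConfig, group: str) -> dict[BandSpec, dict[tuple[int, int], float]]:
    """Effective latent correlation per (band, ordered ROI-index pair).

    A pair listed in both baseline and SCD-extra coupling adds its r
    values.  Pair order is fixed by sorted ROI indices.
    """
    idx = {name: k for k, name in enumerate(config.roi_names)}
    specs = list(config.baseline_coupling)
    if group == SCD:
        specs += list(config.scd_extra_coupling)
    merged: dict[BandSpec, dict[tuple[int, int], float]] = {}
    for spec in specs:
        per_band = merged.setdefault(spec.band, {})
        for i, j, r in spec.pairs:
            key = tuple(sorted((idx[i], idx[j])))
            per_band[key] = per_band.get(key, 0.0) + r
    for band, per_band in merged.items():
        load: dict[int, float] = {}
        for (i, j), r in sorted(per_band.items()):
            if r > 1.0:
                raise ValueError(f"merged coupling r={r:.3f} > 1 for pair "
                                 f"{config.roi_names[i]}-{config.roi_names[j]} ({band.name})")
            load[i] = load.get(i, 0.0) + r
            load[j] = load.get(j, 0.0) + r
        for i, total in load.items():
            if total > 1.0:
                raise ValueError(
                    f"ROI {config.roi_names[i]} carries total coupling {total:.3f} > 1 "
                    f"in band {band.name}; the private mixing weight would be imaginary")
    return merged


def _expected_strength(config: CohortConfig, group: str, roi: str, band: BandSpec) -> float:
    """Large-sample node strength implied by the configured couplings."""
    idx = {name: k for k, name in enumerate(config.roi_names)}
    per_band = _merged_pairs(config, group).get(band, {})
    k = idx[roi]
    return sum(expected_envelope_correlation(r)
               for (i, j), r in per_band.items() if k in (i, j))


def simulate_subject(config: CohortConfig, group: str,
                     subject_seed: int | np.random.SeedSequence,
                     subject_id: str | None = None) -> SubjectRecord:
    """One subject's ROI time series with the group's coupling structure.

    Per band, every ROI gets a private narrowband component and each
    coupled pair a shared one; ROI i mixes
    ``sqrt(1 - sum_k r_k) * private + sum_k sqrt(r_k) * shared_k`` (sum
    over its pairs, in sorted-pair order), keeping unit band variance.
    Band components are scaled by ``band_amplitudes`` and summed, plus a
    broadband white noise floor.
    """
    ss = (subject_seed if isinstance(subject_seed, np.random.SeedSequence)
          else np.random.SeedSequence(subject_seed))
    rng = np.random.default_rng(ss)
    n_roi = len(config.roi_names)
    n = int(round(config.fs * config.duration))
    merged = _merged_pairs(config, group)
    out = np.zeros((n_roi, n))
    for band in config.bands():
        amp = config.band_amplitudes.get(band.name, 0.0)
        pairs = merged.get(band, {})
        if amp == 0 and not pairs:
            continue
        comps = np.empty((n_roi, n))
        for k in range(n_roi):
            comps[k] = make_narrowband_noise(config.fs, config.duration, band, rng)
        loads = np.zeros(n_roi)
        mixed = np.zeros_like(comps)
        for (i, j), r in sorted(pairs.items()):
            shared = make_narrowband_noise(config.fs, config.duration, band, rng)
            mixed[i] += np.sqrt(r) * shared
            mixed[j] += np.sqrt(r) * shared
            loads[i] += r
            loads[j] += r
        mixed += np.sqrt(np.clip(1.0 - loads, 0.0, None))[:, None] * comps
        out += (amp if amp > 0 else 1.0) * mixed
    if config.noise_floor > 0:
        out += config.noise_floor * rng.standard_normal(out.shape)

    complaint = None
    if group == SCD:
        intercept, slope, noise_sd = config.complaint_model
        s = max((_expected_strength(config, SCD, roi, GAMMA1)
                 for roi in ("PCC_L", "PCC_R") if roi in config.roi_names),
                default=0.0)
        lam = max(intercept + slope * s + noise_sd * rng.standard_normal(), 0.1)
        complaint = int(np.clip(rng.poisson(lam), 1, 12))
    return SubjectRecord(
        subject_id=subject_id or f"{group}{int(ss.generate_state(1)[0] % 10_000):04d}",
        group=group, roi_ts=out, fs=config.fs, roi_names=tuple(config.roi_names),
        complaint_count=complaint,
        seed_key=int(ss.generate_state(1)[0] % 2**31),
    )


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """The full two-group cohort, with per-subject seeds spawned from
    the master seed (subject index is the spawn key)."""
    records = []
    labels = [HC] * config.n_hc + [SCD] * config.n_scd
    for idx, group in enumerate(labels):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,))
        n_in_group = idx if group == HC else idx - config.n_hc
        records.append(simulate_subject(config, group, ss,
                                        subject_id=f"{group}{n_in_group + 1:02d}"))
    return records


# ---------------------------------------------------------------------------
# Summary-level cohorts drawn from published group statistics

#: (group, roi, band) -> (mean, sd) node strength, as printed in the
#: source study's results for the cells with significant differences.
PRINTED_STRENGTH_SUMMARIES: dict[tuple[str, str, str], tuple[float, float]] = {
    (HC, "PCC_L", "delta"): (3.1, 0.9),   (SCD, "PCC_L", "delta"): (4.4, 1.6),
    (HC, "PCC_R", "delta"): (3.2, 1.0),   (SCD, "PCC_R", "delta"): (4.3, 1.6),
    (HC, "PCC_L", "theta"): (3.0, 0.8),   (SCD, "PCC_L", "theta"): (4.2, 1.6),
    (HC, "LTC_L", "gamma1"): (1.5, 0.3),  (SCD, "LTC_L", "gamma1"): (2.6, 1.7),
    (HC, "LTC_L", "gamma2"): (1.6, 0.4),  (SCD, "LTC_L", "gamma2"): (2.9, 1.7),
    (HC, "PCu_R", "gamma1"): (1.7, 0.4),  (SCD, "PCu_R", "gamma1"): (2.7, 1.5),
    (HC, "PCu_R", "gamma2"): (1.9, 0.5),  (SCD, "PCu_R", "gamma2"): (3.0, 1.6),
    (HC, "PCC_L", "gamma1"): (2.4, 0.9),  (SCD, "PCC_L", "gamma1"): (3.5, 1.4),
    (HC, "PCC_L", "gamma2"): (2.6, 1.0),  (SCD, "PCC_L", "gamma2"): (3.7, 1.5),
    (HC, "PCC_R", "gamma1"): (2.4, 1.0),  (SCD, "PCC_R", "gamma1"): (3.4, 1.4),
    (HC, "PCC_R", "gamma2"): (2.6, 1.1),  (SCD, "PCC_R", "gamma2"): (3.7, 1.4),
}


@dataclass(frozen=True)
class SummaryCohortConfig:
    """Gaussian node-strength cohorts from (group, roi, band) summaries."""

    cells: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(PRINTED_STRENGTH_SUMMARIES))
    n_hc: int = 26
    n_scd: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (_, sd) in self.cells.items():
            if sd <= 0:
                raise ValueError(f"standard deviation must be positive for cell {key}")


def simulate_strength_summaries(config: SummaryCohortConfig) -> pd.DataFrame:
    """Tidy node-strength table (subject, group, roi, band, strength).

    Independent Gaussian draws per configured cell; sample moments
    converge to the configured values as group sizes grow.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for (group, roi, band), (mean, sd) in sorted(config.cells.items()):
        n = config.n_hc if group == HC else config.n_scd
        draws = rng.normal(mean, sd, size=n)
        for k, value in enumerate(draws):
            rows.append((f"{group}{k + 1:02d}", group, roi, band, value))
    return pd.DataFrame(rows, columns=["subject", "group", "roi", "band", "strength"])


# ---------------------------------------------------------------------------
# Cohort I/O: one delimited-text file per subject plus a JSON manifest

def write_cohort(records: list[SubjectRecord], outdir: str | Path,
                 fmt: str = "%.6g") -> Path:
    from .io import write_roi_timeseries

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        path = outdir / f"{rec.subject_id}.csv"
        write_roi_timeseries(path, rec.roi_ts, rec.fs, rec.roi_names, fmt=fmt)
        manifest.append({"subject_id": rec.subject_id, "group": rec.group,
                         "seed": rec.seed_key, "complaint_count": rec.complaint_count,
                         "file": path.name})
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def null_config(config: CohortConfig | None = None, **kwargs) -> CohortConfig:
    """A copy of ``config`` with the SCD-specific coupling removed."""
    base = config or CohortConfig(**kwargs)
    return replace(base, scd_extra_coupling=())
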