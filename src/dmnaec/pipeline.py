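"""End-to-end orchestration: simulate/load -> clean -> spectra -> AEC ->
group statistics -> ROC, with every stage's output written as text.

A run is described by a :class:`RunConfig` (loadable from YAML).  The
bundle written to ``outdir`` contains relative band-power and
node-strength tables, per-subject AEC matrices, cell- and edge-level
statistics, ROC results and a manifest (config + seeds) sufficient to
reproduce the run bit-identically.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import CANONICAL_BANDS, band_by_name
from .cohort import (HC, SCD, CohortConfig, CouplingSpec, SubjectRecord,
                     simulate_cohort, write_cohort)
from .connectivity import aec_matrix, node_strength, strength_table
from .io import read_mask, read_roi_timeseries, write_json
from .preprocess import mask_to_bool, notch_filter
from .roc import roc_auc
from .spectral import relative_band_power, welch_psd
from .stats import (DEFAULT_EDGE_COMPARISONS, compare_cells, compare_edges,
                    spearman_one_tailed)


@dataclass(frozen=True)
class RocScoreSpec:
    """Which strength feature feeds the headline ROC."""

    band: str = "delta"
    roi: str = "PCC_L"
    bilateral: bool = False      # sum left+right homologues of ``roi``

    def score_name(self) -> str:
        base = self.roi[:-2] if self.bilateral else self.roi
        return f"{base}{'_bilateral' if self.bilateral else ''}_{self.band}"


@dataclass
class RunConfig:
    outdir: str = "results_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None      # read subjects instead of simulating
    bands: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
    notch_base: float | None = None   # synthetic data carry no powerline
    mask_file: str | None = None      # JSON bad-segment intervals, all subjects
    welch_window_s: float = 5.0
    welch_overlap: float = 0.5
    alpha: float = 0.05
    edge_comparisons: int = DEFAULT_EDGE_COMPARISONS
    roc_scores: tuple[RocScoreSpec, ...] = (
        RocScoreSpec("delta", "PCC_L"),
        RocScoreSpec("gamma1", "PCC_L", bilateral=True),
        RocScoreSpec("gamma2", "PCC_L", bilateral=True),
    )
    write_cohort_files: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            ck = dict(kwargs["cohort"])
            for key in ("baseline_coupling", "scd_extra_coupling"):
                if key in ck:
                    ck[key] = tuple(
                        CouplingSpec(band_by_name(spec["band"]),
                                     tuple((p[0], p[1], float(p[2]))
                                           for p in spec["pairs"]))
                        for spec in ck[key])
            if "roi_names" in ck:
                ck["roi_names"] = tuple(ck["roi_names"])
            kwargs["cohort"] = CohortConfig(**ck)
        if "roc_scores" in kwargs:
            kwargs["roc_scores"] = tuple(RocScoreSpec(**s)
                                         for s in kwargs["roc_scores"])
        if "bands" in kwargs:
            kwargs["bands"] = tuple(kwargs["bands"])
        return cls(**kwargs)


@dataclass
class ResultsBundle:
    outdir: Path
    band_power: pd.DataFrame
    strengths: pd.DataFrame
    cell_stats: dict[str, pd.DataFrame]      # measure -> StatTable
    edge_stats: pd.DataFrame | None
    roc: dict[str, dict]
    spearman: tuple[float, float] | None
    manifest: dict


def _load_subjects(cfg: RunConfig) -> list[SubjectRecord]:
    import json

    indir = Path(cfg.input_dir)
    manifest = json.loads((indir / "manifest.json").read_text())
    records = []
    for entry in manifest:
        ts, fs, names = read_roi_timeseries(indir / entry["file"],
                                            expected_rois=cfg.cohort.roi_names)
        records.append(SubjectRecord(
            subject_id=entry["subject_id"], group=entry["group"], roi_ts=ts,
            fs=fs, roi_names=names, complaint_count=entry.get("complaint_count"),
            seed_key=entry.get("seed", -1)))
    return records


def _bilateral_pair(roi: str, names: tuple[str, ...]) -> tuple[str, str]:
    stem = roi[:-2]
    left, right = f"{stem}_L", f"{stem}_R"
    if left not in names or right not in names:
        raise ValueError(f"no bilateral pair for ROI {roi!r}")
    return left, right


def _roc_score_values(spec: RocScoreSpec, strengths: pd.DataFrame) -> pd.DataFrame:
    sub = strengths[strengths["band"] == spec.band]
    if spec.bilateral:
        left, right = _bilateral_pair(spec.roi, tuple(sub["roi"].unique()))
        wide = (sub[sub["roi"].isin([left, right])]
                .pivot_table(index=["subject", "group"], columns="roi",
                             values="strength"))
        score = wide[left] + wide[right]
    else:
        cell = sub[sub["roi"] == spec.roi]
        score = cell.set_index(["subject", "group"])["strength"]
    return score.reset_index().rename(columns={score.name if score.name else 0:
                                               "score", "strength": "score"})


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute every stage on a simulated or loaded cohort."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aec_dir = outdir / "aec"
    aec_dir.mkdir(exist_ok=True)

    stage = "simulate"
    try:
        if config.input_dir is not None:
            stage = "load"
            records = _load_subjects(config)
        else:
            records = simulate_cohort(config.cohort)
            if config.write_cohort_files:
                write_cohort(records, outdir / "cohort")

        bands = [band_by_name(name) for name in config.bands]
        mask_intervals = (read_mask(config.mask_file)
                          if config.mask_file else [])

        power_rows, strength_frames, aec_store = [], [], {}
        for rec in records:
            stage = f"preprocess[{rec.subject_id}]"
            ts = rec.roi_ts
            if config.notch_base is not None:
                ts = notch_filter(ts, config.notch_base, rec.fs)
            keep = (mask_to_bool(mask_intervals, ts.shape[-1])
                    if mask_intervals else None)

            stage = f"spectral[{rec.subject_id}]"
            psd = welch_psd(ts, rec.fs, config.welch_window_s,
                            config.welch_overlap, mask=keep)
            rel = relative_band_power(psd, bands)
            rel.insert(0, "roi", list(rec.roi_names))
            rel.insert(0, "group", rec.group)
            rel.insert(0, "subject", rec.subject_id)
            power_rows.append(rel)

            stage = f"connectivity[{rec.subject_id}]"
            mats = [aec_matrix(ts, band, rec.fs, rec.roi_names, mask=keep)
                    for band in bands]
            for m in mats:
                m.to_frame().to_csv(aec_dir / f"{rec.subject_id}_{m.band}.csv")
                aec_store[(rec.subject_id, m.band)] = m
            strength_frames.append(strength_table(rec.subject_id, rec.group, mats))

        stage = "tables"
        band_power = pd.concat(power_rows, ignore_index=True)
        band_power.to_csv(outdir / "band_power.csv", index=False)
        strengths = pd.concat(strength_frames, ignore_index=True)
        strengths.to_csv(outdir / "node_strength.csv", index=False)

        stage = "stats"
        power_tidy = band_power.melt(id_vars=["subject", "group", "roi"],
                                     var_name="band", value_name="strength")
        cell_stats = {"strength": compare_cells(strengths, config.alpha),
                      "power": compare_cells(power_tidy, config.alpha)}
        cell_stats["strength"].to_csv(outdir / "stats_strength.csv", index=False)
        cell_stats["power"].to_csv(outdir / "stats_power.csv", index=False)

        sig = cell_stats["strength"].query("significant")
        edge_stats = None
        if not sig.empty:
            rows = []
            group_of = dict(zip(strengths["subject"], strengths["group"]))
            roi_names = tuple(config.cohort.roi_names)
            for _, cell in sig.iterrows():
                node, band_name = cell["roi"], cell["band"]
                for other in roi_names:
                    if other == node:
                        continue
                    i, j = sorted((node, other), key=roi_names.index)
                    for (subject, b), m in aec_store.items():
                        if b != band_name:
                            continue
                        v = m.to_frame().loc[i, j]
                        rows.append((subject, group_of[subject], i, j,
                                     band_name, v))
            edge_table = (pd.DataFrame(rows, columns=["subject", "group",
                                                      "roi_i", "roi_j",
                                                      "band", "aec"])
                          .drop_duplicates(["subject", "roi_i", "roi_j", "band"]))
            edge_stats = compare_edges(edge_table, config.alpha,
                                       config.edge_comparisons)
            edge_stats.to_csv(outdir / "stats_edges.csv", index=False)

        stage = "roc"
        roc_results = {}
        for spec in config.roc_scores:
            try:
                scored = _roc_score_values(spec, strengths)
            except (KeyError, ValueError) as exc:
                warnings.warn(f"skipping ROC score {spec.score_name()}: {exc}")
                continue
            res = roc_auc(scored["score"].to_numpy(),
                          scored["group"].to_numpy())
            roc_results[spec.score_name()] = res.to_dict()
            pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
                outdir / f"roc_curve_{spec.score_name()}.csv", index=False)
        write_json(outdir / "roc.json", roc_results)

        stage = "spearman"
        spearman = None
        complaints = {r.subject_id: r.complaint_count
                      for r in records if r.group == SCD and r.complaint_count}
        if len(complaints) >= 5 and "gamma1" in config.bands:
            cell = strengths.query("group == @SCD and band == 'gamma1' "
                                   "and roi == 'PCC_L'")
            merged = cell[cell["subject"].isin(complaints)]
            if len(merged) >= 5:
                x = merged["strength"].to_numpy()
                y = merged["subject"].map(complaints).to_numpy(dtype=float)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    spearman = spearman_one_tailed(x, y)

        manifest = {
            "package_version": __version__,
            "config": _config_dict(config),
            "n_subjects": len(records),
            "subject_seeds": {r.subject_id: r.seed_key for r in records},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        write_json(outdir / "manifest.json", manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return ResultsBundle(outdir=outdir, band_power=band_power,
                         strengths=strengths, cell_stats=cell_stats,
                         edge_stats=edge_stats, roc=roc_results,
                         spearman=spearman, manifest=manifest)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    cohort = d["cohort"]
    for key in ("baseline_coupling", "scd_extra_coupling"):
        cohort[key] = [{"band": s.band.name,
                        "pairs": [list(p) for p in s.pairs]}
                       for s in getattr(config.cohort, key)]
    return d
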