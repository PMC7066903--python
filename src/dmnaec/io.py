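"""Delimited-text I/O for ROI time series, matrices, masks and results.

The ROI time-series format is one CSV per subject: a ``# fs=<Hz>``
comment line, a header row of ROI names, then samples x ROI rows.
Masks are JSON lists of (start, stop) bad-sample intervals; leadfields,
covariances and parcellation live in plain delimited text / JSON so a
pipeline run is reproducible from text files alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


class FormatError(ValueError):
    """Malformed input file (carries the offending line number)."""


def write_roi_timeseries(path: str | Path, ts: np.ndarray, fs: float,
                         roi_names: tuple[str, ...] | list[str],
                         fmt: str = "%.12g") -> None:
    """Write (n_roi, n_samples) series as samples x ROI CSV columns."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] != len(roi_names):
        raise ValueError("roi_names length does not match the series")
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g}\n")
        fh.write(",".join(roi_names) + "\n")
        np.savetxt(fh, ts.T, delimiter=",", fmt=fmt)


def read_roi_timeseries(path: str | Path,
                        expected_rois: tuple[str, ...] | None = None,
                        ) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read a subject file; returns (n_roi x n_samples, fs, roi names).

    Raises :class:`FormatError` with a line number for a missing fs
    header, ragged rows, or an ROI-count mismatch against
    ``expected_rois``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise FormatError(f"{path.name}:1: expected '# fs=<Hz>' header, "
                              f"got {first[:40]!r}")
        try:
            fs = float(first.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}:1: unparseable sampling rate") from exc
        names = tuple(n.strip() for n in fh.readline().strip().split(","))
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != len(names):
                raise FormatError(f"{path.name}:{lineno}: expected "
                                  f"{len(names)} columns, got {len(fields)}")
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric value") from exc
    if expected_rois is not None and names != tuple(expected_rois):
        raise FormatError(f"{path.name}: ROI columns {list(names)} do not match "
                          f"the configured {list(expected_rois)}")
    if not rows:
        raise FormatError(f"{path.name}: no data rows")
    return np.array(rows).T, fs, names


def write_matrix(path: str | Path, m: np.ndarray, fmt: str = "%.12g") -> None:
    np.savetxt(path, np.asarray(m, dtype=float), delimiter=",", fmt=fmt)


def read_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#"))


def write_mask(path: str | Path, intervals: list[tuple[int, int]]) -> None:
    Path(path).write_text(json.dumps([[int(a), int(b)] for a, b in intervals]))


def read_mask(path: str | Path) -> list[tuple[int, int]]:
    data = json.loads(Path(path).read_text())
    return [(int(a), int(b)) for a, b in data]


def read_parcellation(path: str | Path) -> dict[str, list[int]]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError("parcellation JSON must map ROI name -> index list")
    return {str(k): [int(i) for i in v] for k, v in data.items()}


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
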