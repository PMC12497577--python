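"""Cohort manifests, ROI time-series files, and result artifacts.

A cohort is described by a CSV manifest (``subject_id, group, path,
tr_seconds`` plus any number of clinical covariate columns) pointing at
per-subject tab-separated time-series files (T rows of time points, R
columns of regions, no header).  Before inference the per-subject series
are z-scored column-wise and row-stacked into one concatenated matrix with
recorded subject boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("patient", "control")

__all__ = [
    "CohortManifest",
    "ManifestRecord",
    "ROITimeSeries",
    "ConcatenatedDataset",
    "read_manifest",
    "write_manifest",
    "read_timeseries",
    "write_timeseries",
    "standardize",
    "concatenate",
    "load_cohort",
    "save_model_json",
    "load_model_json",
]


@dataclasses.dataclass(frozen=True, eq=False)
class ManifestRecord:
    subject_id: str
    group: str
    path: str
    tr_seconds: float
    covariates: dict[str, float]  # NaN marks a missing value

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ManifestRecord):
            return NotImplemented
        if (self.subject_id, self.group, self.path, self.tr_seconds) != (
            other.subject_id, other.group, other.path, other.tr_seconds
        ):
            return False
        if set(self.covariates) != set(other.covariates):
            return False
        # NaN covariates compare equal: both mean "missing"
        return all(
            v == other.covariates[k]
            or (math.isnan(v) and math.isnan(other.covariates[k]))
            for k, v in self.covariates.items()
        )

    def __hash__(self) -> int:
        return hash((self.subject_id, self.group, self.path, self.tr_seconds))


@dataclasses.dataclass(frozen=True)
class CohortManifest:
    """Ordered cohort description; subject ids are unique."""

    records: tuple[ManifestRecord, ...]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def groups(self) -> list[str]:
        return [r.group for r in self.records]

    @property
    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for r in self.records:
            for name in r.covariates:
                if name not in names:
                    names.append(name)
        return names

    def covariate(self, name: str) -> np.ndarray:
        """Covariate values in manifest order (NaN where missing)."""
        return np.array(
            [r.covariates.get(name, math.nan) for r in self.records], dtype=float
        )

    def subset(self, group: str) -> "CohortManifest":
        return CohortManifest(tuple(r for r in self.records if r.group == group))

    def __len__(self) -> int:
        return len(self.records)


@dataclasses.dataclass
class ROITimeSeries:
    """One subject's T x R regional signal matrix (rows are time points)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    standardized: bool = False
    zero_variance_columns: tuple[int, ...] = ()

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_regions(self) -> int:
        return int(self.data.shape[1])


@dataclasses.dataclass(frozen=True)
class ConcatenatedDataset:
    """Row-stacked multi-subject matrix with half-open subject boundaries."""

    data: np.ndarray
    boundaries: tuple[tuple[int, int], ...]
    subject_ids: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.boundaries)

    @property
    def n_regions(self) -> int:
        return int(self.data.shape[1])

    def segment(self, i: int) -> np.ndarray:
        s, e = self.boundaries[i]
        return self.data[s:e]


_REQUIRED_COLUMNS = ("subject_id", "group", "path", "tr_seconds")


def read_manifest(path: str | Path) -> CohortManifest:
    """Parse a cohort manifest CSV.

    Required columns: ``subject_id, group, path, tr_seconds``.  Any further
    column is treated as a named clinical covariate; blank cells become NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "path": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required column(s): {missing}")

    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate subject_id in manifest: {sorted(set(dup))}")

    bad_groups = sorted(set(df["group"]) - set(GROUP_LABELS))
    if bad_groups:
        raise ValueError(
            f"unknown group label(s) {bad_groups}; allowed: {list(GROUP_LABELS)}"
        )

    covariate_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tr = float(getattr(row, "tr_seconds"))
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"unreadable tr_seconds in manifest row {row_number}: "
                f"{getattr(row, 'tr_seconds')!r}"
            ) from exc
        if not math.isfinite(tr) or tr <= 0:
            raise ValueError(f"tr_seconds must be positive (manifest row {row_number})")
        cov = {}
        for c in covariate_cols:
            v = getattr(row, c)
            try:
                cov[c] = float(v) if v is not None and str(v) != "" else math.nan
            except (TypeError, ValueError):
                cov[c] = math.nan
        records.append(
            ManifestRecord(
                subject_id=str(getattr(row, "subject_id")),
                group=str(getattr(row, "group")),
                path=str(getattr(row, "path")),
                tr_seconds=tr,
                covariates=cov,
            )
        )
    return CohortManifest(tuple(records))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    cov_names = manifest.covariate_names
    rows = []
    for r in manifest.records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "path": r.path,
            "tr_seconds": repr(r.tr_seconds),
        }
        for c in cov_names:
            v = r.covariates.get(c, math.nan)
            row[c] = "" if math.isnan(v) else repr(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timeseries(
    path: str | Path, subject_id: str, tr_seconds: float
) -> ROITimeSeries:
    """Read a tab-separated T x R numeric matrix (no header)."""
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} values, expected {width})"
                )
            parsed = []
            for col, f in enumerate(fields):
                try:
                    parsed.append(float(f))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell at line {lineno}, column {col + 1}: {f!r}"
                    ) from exc
            rows.append(parsed)
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 time points, got {data.shape}")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 regions, got {data.shape[1]}")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite values present")
    return ROITimeSeries(subject_id=subject_id, data=data, tr_seconds=tr_seconds)


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.17g")


def standardize(ts: ROITimeSeries) -> ROITimeSeries:
    """Z-score each region within subject (sample SD, denominator T-1).

    Zero-variance columns are set to all zeros and recorded in
    ``zero_variance_columns``.  Applying the transform twice changes
    nothing beyond floating-point noise.
    """
    x = np.asarray(ts.data, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    if flat.size:
        z[:, flat] = 0.0
    return ROITimeSeries(
        subject_id=ts.subject_id,
        data=z,
        tr_seconds=ts.tr_seconds,
        standardized=True,
        zero_variance_columns=tuple(int(i) for i in flat),
    )


def concatenate(
    series: Sequence[ROITimeSeries], manifest: CohortManifest
) -> ConcatenatedDataset:
    """Row-stack standardized subject series in manifest order."""
    by_id = {ts.subject_id: ts for ts in series}
    missing = [sid for sid in manifest.subject_ids if sid not in by_id]
    if missing:
        raise ValueError(f"series missing for subjects: {missing}")
    ordered = [by_id[sid] for sid in manifest.subject_ids]

    not_std = [ts.subject_id for ts in ordered if not ts.standardized]
    if not_std:
        raise ValueError(f"unstandardized series for subjects: {not_std}")
    widths = {ts.n_regions for ts in ordered}
    if len(widths) > 1:
        detail = {ts.subject_id: ts.n_regions for ts in ordered}
        raise ValueError(f"mismatched region counts across subjects: {detail}")

    boundaries = []
    start = 0
    for ts in ordered:
        end = start + ts.n_timepoints
        boundaries.append((start, end))
        start = end
    data = np.vstack([ts.data for ts in ordered])
    return ConcatenatedDataset(
        data=data,
        boundaries=tuple(boundaries),
        subject_ids=tuple(manifest.subject_ids),
    )


def load_cohort(
    manifest_path: str | Path, standardize_series: bool = True
) -> tuple[CohortManifest, list[ROITimeSeries], ConcatenatedDataset]:
    """Read manifest + all series, standardize, and concatenate.

    Relative series paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    series = []
    for r in manifest.records:
        p = Path(r.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        ts = read_timeseries(p, r.subject_id, r.tr_seconds)
        series.append(standardize(ts) if standardize_series else ts)
    dataset = concatenate(series, manifest)
    return manifest, series, dataset


def save_model_json(model, path: str | Path, extra: dict | None = None) -> None:
    """Serialize a fitted state-space model (means, covariances, transition
    matrix, initial distribution, free-energy trace) as JSON."""
    payload = {
        "n_states": int(model.K),
        "means": np.asarray(model.means).tolist(),
        "covariances": np.asarray(model.covariances).tolist(),
        "transition": np.asarray(model.transition).tolist(),
        "initial": np.asarray(model.initial).tolist(),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path: str | Path):
    from .hmm import HMMModel

    with open(path) as fh:
        payload = json.load(fh)
    return (
        HMMModel(
            K=int(payload["n_states"]),
            means=np.asarray(payload["means"], dtype=float),
            covariances=np.asarray(payload["covariances"], dtype=float),
            transition=np.asarray(payload["transition"], dtype=float),
            initial=np.asarray(payload["initial"], dtype=float),
        ),
        payload,
    )
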