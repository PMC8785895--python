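"""Data model and tabular I/O for ROI sets, time series, phenotypes and metrics.

All files are delimited text (tab-separated by default; commas are accepted
via dialect sniffing on read). ROI time-series files carry one header row of
ROI labels and one row per fMRI volume. Missing clinical values are encoded
as empty fields, never as sentinel numbers.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RoiSet",
    "TimeSeriesMatrix",
    "SubjectRecord",
    "read_roi_set",
    "read_timeseries",
    "write_timeseries",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_metrics",
    "read_metrics",
    "PHENOTYPE_REQUIRED_COLUMNS",
    "PHENOTYPE_OPTIONAL_COLUMNS",
]

PHENOTYPE_REQUIRED_COLUMNS = (
    "subject_id",
    "diagnosis",
    "age",
    "sex",
    "education",
    "site",
    "mean_fd",
)
PHENOTYPE_OPTIONAL_COLUMNS = ("illness_duration", "hamd", "hama", "episodicity")

#: Stable column order for metrics tables written by :func:`write_metrics`.
METRICS_COLUMNS = (
    "subject_id",
    "fc_strength",
    "dfc_variability",
    "window_width_s",
    "step_s",
)


def _sniff_delimiter(path: Path) -> str:
    """Return the field delimiter, preferring tabs and falling back to commas."""
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        return "\t"
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


@dataclass(frozen=True)
class RoiSet:
    """A fixed, ordered set of network regions with MNI coordinates.

    The ROI order defined here is canonical: every time-series matrix is
    reordered to it on read, and all downstream matrix indexing assumes it.
    """

    labels: tuple[str, ...]
    coords: np.ndarray  # (n_rois, 3) MNI x/y/z in mm

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        if len(self.labels) < 2:
            raise ValueError("a ROI set needs at least 2 regions")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_rois, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-numeric or non-finite ROI coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def n_rois(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """One subject's ROI signal array: volumes x ROIs, with its TR in seconds."""

    subject_id: str
    tr_s: float
    data: np.ndarray  # (n_volumes, n_rois)
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x ROIs)")
        if data.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if data.shape[1] != len(self.roi_labels):
            raise ValueError("column count does not match ROI labels")
        if not np.all(np.isfinite(data)):
            raise ValueError(f"missing/non-finite values in time series of {self.subject_id}")
        object.__setattr__(self, "data", data)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    """Phenotype row: demographics, site, motion, and optional clinical scores."""

    subject_id: str
    diagnosis: str  # "MDD" or "HC"
    age: float
    sex: str  # "male" or "female"
    education: float
    site: str
    mean_fd: float
    illness_duration: Optional[float] = None  # months
    hamd: Optional[float] = None
    hama: Optional[float] = None
    episodicity: Optional[str] = None  # "first" or "recurrent"

    def __post_init__(self) -> None:
        if self.diagnosis not in ("MDD", "HC"):
            raise ValueError(f"diagnosis must be MDD or HC, got {self.diagnosis!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")
        if not np.isnan(self.age) and self.age < 0:
            raise ValueError("age must be non-negative")
        if not np.isnan(self.mean_fd) and self.mean_fd < 0:
            raise ValueError("mean_fd must be non-negative")

    @property
    def complete_demographics(self) -> bool:
        """Whether all required (non-clinical) numeric fields are present."""
        return not any(
            np.isnan(v) for v in (self.age, self.education, self.mean_fd)
        )


def read_roi_set(path: Optional[str | Path] = None) -> RoiSet:
    """Read a ROI-definition table (columns label, x, y, z in MNI mm).

    With no path, returns the packaged 58-region default-mode-network set
    (synthetic stand-in coordinates; only labels and count enter computation).
    """
    if path is None:
        ref = importlib.resources.files("dmnage") / "data" / "dmn_rois_synthetic.tsv"
        with importlib.resources.as_file(ref) as p:
            return read_roi_set(p)
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    try:
        coords = df[["x", "y", "z"]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric ROI coordinates in {path}") from exc
    return RoiSet(labels=tuple(df["label"].astype(str)), coords=coords)


def read_timeseries(
    path: str | Path, tr_s: float, roi_set: Optional[RoiSet] = None,
    subject_id: Optional[str] = None,
) -> TimeSeriesMatrix:
    """Read a volumes-x-ROIs time-series file.

    Columns are canonicalized to the RoiSet label order when a ``roi_set`` is
    given; a column-set mismatch is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if df.isna().any().any():
        raise ValueError(f"missing values in time series {path}")
    if roi_set is not None:
        file_cols = set(df.columns)
        want = set(roi_set.labels)
        if file_cols != want:
            missing = sorted(want - file_cols)
            extra = sorted(file_cols - want)
            raise ValueError(
                f"ROI columns of {path} do not match the ROI set "
                f"(missing {missing[:5]}, unexpected {extra[:5]})"
            )
        df = df[list(roi_set.labels)]
    return TimeSeriesMatrix(
        subject_id=subject_id or path.stem,
        tr_s=tr_s,
        data=df.to_numpy(dtype=float),
        roi_labels=tuple(df.columns),
    )


def write_timeseries(path: str | Path, ts: TimeSeriesMatrix) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.roi_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _to_float(value: object, column: str, subject: str) -> float:
    s = "" if value is None else str(value).strip()
    if s == "" or s.lower() == "nan":
        return float("nan")
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(
            f"unparseable numeric field {column}={value!r} for subject {subject}"
        ) from exc


def read_phenotype_table(path: str | Path) -> list[SubjectRecord]:
    """Read a phenotype table into SubjectRecord rows; blanks become NaN/None."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in PHENOTYPE_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = str(d["subject_id"])
        epi = d.get("episodicity", "")
        records.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis=str(d["diagnosis"]).strip(),
                age=_to_float(d["age"], "age", sid),
                sex=str(d["sex"]).strip(),
                education=_to_float(d["education"], "education", sid),
                site=str(d["site"]).strip(),
                mean_fd=_to_float(d["mean_fd"], "mean_fd", sid),
                illness_duration=_opt(d.get("illness_duration"), "illness_duration", sid),
                hamd=_opt(d.get("hamd"), "hamd", sid),
                hama=_opt(d.get("hama"), "hama", sid),
                episodicity=(str(epi).strip() or None) if epi is not None else None,
            )
        )
    return records


def _opt(value: object, column: str, subject: str) -> Optional[float]:
    v = _to_float(value, column, subject)
    return None if np.isnan(v) else v


def write_phenotype_table(path: str | Path, records: list[SubjectRecord]) -> None:
    cols = list(PHENOTYPE_REQUIRED_COLUMNS) + list(PHENOTYPE_OPTIONAL_COLUMNS)
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in cols}
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_metrics(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-subject metrics table with stable column order.

    Metrics columns come first in canonical order; any phenotype columns the
    caller joined in follow in their existing order. Round-trips through
    :func:`read_metrics` at full floating precision.
    """
    first = [c for c in METRICS_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in first]
    table[first + rest].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_delimiter(path))
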