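"""Readers and writers for FSL eddy's motion text outputs and the
package's tabular formats.

FSL's ``eddy`` estimates a rigid head pose for every diffusion volume and
writes two plain-text files this module consumes:

``*_movement_rms``
    Two whitespace-delimited columns per volume: RMS voxel displacement
    relative to the first volume, and relative to the previous volume
    (both in mm, averaged over intracerebral voxels).

``*_parameters``
    One row per volume, >= 6 whitespace-delimited columns; the first six
    are three translations (mm) followed by three rotations (radians),
    expressed relative to the first volume. Trailing columns hold
    eddy-current terms and are ignored here.

Dialect: any run of spaces/tabs separates tokens; blank lines and lines
starting with ``#`` are skipped. Parsers never silently truncate — any
row/column anomaly raises :class:`~dwimotion.errors.FormatError` or
:class:`~dwimotion.errors.ValidationError` naming the offending line.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "MotionTrace",
    "RMSSeries",
    "AcquisitionMeta",
    "DEFAULT_AXIS_MAP",
    "read_eddy_movement_rms",
    "write_rms_series",
    "read_eddy_parameters",
    "write_eddy_parameters",
    "read_acquisition_meta",
    "read_feature_table",
    "write_feature_table",
    "write_summary_table",
    "read_summary_table",
]

#: Default anatomical interpretation of the (x, y, z) parameter axes:
#: x = left/right, y = posterior/anterior, z = inferior/superior.
DEFAULT_AXIS_MAP: tuple[str, str, str] = ("LR", "PA", "IS")

FEATURE_TABLE_COLUMNS = ("subject", "session", "scan", "bundle", "measure", "value")


@dataclass
class RMSSeries:
    """Per-volume RMS voxel displacement in mm.

    ``abs_rms[k]`` is displacement of volume k relative to volume 0,
    ``rel_rms[k]`` relative to volume k-1; both start at 0.
    """

    abs_rms: np.ndarray
    rel_rms: np.ndarray

    def __post_init__(self) -> None:
        self.abs_rms = np.asarray(self.abs_rms, dtype=float)
        self.rel_rms = np.asarray(self.rel_rms, dtype=float)
        if self.abs_rms.ndim != 1 or self.rel_rms.ndim != 1:
            raise ValidationError("RMS series must be one-dimensional")
        if self.abs_rms.shape != self.rel_rms.shape:
            raise ValidationError("abs_rms and rel_rms must have equal length")
        if not (np.isfinite(self.abs_rms).all() and np.isfinite(self.rel_rms).all()):
            raise ValidationError("RMS series contain non-finite values")
        if (self.abs_rms < 0).any() or (self.rel_rms < 0).any():
            raise ValidationError("RMS displacements must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.abs_rms.size


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters relative to the first volume.

    ``trans`` is (n_volumes, 3) in mm on axes (x, y, z); ``rot`` is
    (n_volumes, 3) in radians about (x, y, z). ``axis_map`` records the
    anatomical meaning of each axis (default x→LR, y→PA, z→IS).
    """

    trans: np.ndarray
    rot: np.ndarray
    tr_seconds: float | None = None
    axis_map: tuple[str, str, str] = DEFAULT_AXIS_MAP

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.rot = np.asarray(self.rot, dtype=float)
        for name, arr in (("trans", self.trans), ("rot", self.rot)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"{name} must have shape (n_volumes, 3)")
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} contains non-finite values")
        if self.trans.shape[0] != self.rot.shape[0]:
            raise ValidationError("trans and rot must have equal row counts")
        if self.trans.shape[0] < 2:
            raise ValidationError("a motion trace needs at least 2 volumes")

    @property
    def n_volumes(self) -> int:
        return self.trans.shape[0]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata needed to normalize descriptors by scan time."""

    tr_seconds: float
    n_volumes: int
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if not self.tr_seconds > 0:
            raise ValidationError("tr_seconds must be positive")
        if self.n_volumes < 2:
            raise ValidationError("n_volumes must be at least 2")

    @property
    def scan_duration_min(self) -> float:
        """Nominal scan duration, n_volumes * TR / 60, in minutes."""
        return self.n_volumes * self.tr_seconds / 60.0


def _parse_numeric_lines(path: Path) -> tuple[list[list[float]], list[int]]:
    """Tokenize a whitespace-delimited numeric file.

    Returns parsed rows and their 1-based line numbers; blank lines and
    ``#`` comments are skipped.
    """
    rows: list[list[float]] = []
    linenos: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values = [float(tok) for tok in stripped.split()]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric token ({exc})") from None
            rows.append(values)
            linenos.append(lineno)
    return rows, linenos


def read_eddy_movement_rms(path: str | Path, n_expected: int | None = None) -> RMSSeries:
    """Read an eddy ``*_movement_rms`` file.

    Column 1 is RMS displacement relative to the first volume, column 2
    relative to the previous volume. ``n_expected``, when given, is
    enforced against the row count.
    """
    path = Path(path)
    rows, linenos = _parse_numeric_lines(path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    for row, lineno in zip(rows, linenos):
        if len(row) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
    data = np.asarray(rows, dtype=float)
    if (data < 0).any():
        bad = linenos[int(np.argmax((data < 0).any(axis=1)))]
        raise ValidationError(f"{path}: line {bad}: negative RMS displacement")
    if n_expected is not None and data.shape[0] != n_expected:
        raise ValidationError(
            f"{path}: expected {n_expected} volumes, found {data.shape[0]}"
        )
    return RMSSeries(abs_rms=data[:, 0], rel_rms=data[:, 1])


def write_rms_series(series: RMSSeries, path: str | Path) -> None:
    """Write an RMSSeries in eddy's two-column text format (lossless)."""
    with open(path, "w") as fh:
        for a, r in zip(series.abs_rms, series.rel_rms):
            fh.write(f"{float(a)!r} {float(r)!r}\n")


def read_eddy_parameters(
    path: str | Path, axis_map: tuple[str, str, str] = DEFAULT_AXIS_MAP
) -> MotionTrace:
    """Read an eddy ``*_parameters`` file into a :class:`MotionTrace`.

    Columns 1-3 become translations (mm), 4-6 rotations (radians);
    eddy-current columns beyond 6 are dropped. Files whose first row is
    non-zero are re-referenced to volume 1 (with a warning), since the
    parameters are defined relative to the first volume.
    """
    path = Path(path)
    rows, linenos = _parse_numeric_lines(path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0])
    if width < 6:
        raise FormatError(f"{path}: line {linenos[0]}: expected >=6 columns, got {width}")
    for row, lineno in zip(rows, linenos):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno}: ragged row ({len(row)} columns, expected {width})"
            )
    data = np.asarray(rows, dtype=float)[:, :6]
    if np.any(data[0] != 0.0):
        warnings.warn(
            f"{path}: first row is non-zero; re-referencing parameters to volume 1",
            stacklevel=2,
        )
        data = data - data[0]
    return MotionTrace(trans=data[:, :3], rot=data[:, 3:6], axis_map=axis_map)


def write_eddy_parameters(trace: MotionTrace, path: str | Path, n_columns: int = 6) -> None:
    """Write a MotionTrace in eddy's ``*_parameters`` format.

    ``n_columns`` >= 6 pads with zero eddy-current terms, mirroring real
    eddy output widths (typically 16).
    """
    if n_columns < 6:
        raise ValidationError("eddy parameters files have at least 6 columns")
    pad = n_columns - 6
    with open(path, "w") as fh:
        for t, r in zip(trace.trans, trace.rot):
            tokens = [repr(float(v)) for v in (*t, *r)] + ["0"] * pad
            fh.write(" ".join(tokens) + "\n")


def read_acquisition_meta(path: str | Path) -> AcquisitionMeta:
    """Read acquisition metadata from a JSON or YAML file.

    Expected keys: ``tr`` (seconds), ``n_volumes``, optional ``cohort``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if not isinstance(payload, Mapping):
        raise FormatError(f"{path}: metadata must be a mapping")
    try:
        tr = float(payload["tr"])
        n_volumes = int(payload["n_volumes"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing metadata key {exc}") from None
    return AcquisitionMeta(
        tr_seconds=tr, n_volumes=n_volumes, cohort_id=str(payload.get("cohort", ""))
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format scan-level bundle feature table (TSV).

    Required columns: subject, session, scan, bundle, measure, value.
    Duplicate (subject, session, scan, bundle, measure) keys are
    rejected. An empty table (header only) is valid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"value": float}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (no header)") from None
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    key_cols = ["subject", "session", "scan", "bundle", "measure"]
    dupes = df.duplicated(subset=key_cols)
    if dupes.any():
        first = df.loc[dupes, key_cols].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicate feature key {first}")
    return df[list(FEATURE_TABLE_COLUMNS)].copy()


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format feature table as TSV (lossless round trip)."""
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing column(s) {missing}")
    df[list(FEATURE_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_summary_table(records: Sequence, path: str | Path) -> None:
    """Write one TSV row per scan with demographics and all motion
    descriptors, in a fixed column order.

    ``records`` are :class:`~dwimotion.pipelines.ScanRecord` objects (or
    anything with the same fields). Missing demographics are written as
    empty cells, never 0. Floats round-trip at full precision (pandas
    writes shortest-exact representations).
    """
    if not records:
        raise ValidationError("cannot write an empty summary table")
    rows = []
    for rec in records:
        s = rec.summary
        row: dict[str, object] = {
            "subject": rec.subject,
            "session": rec.session,
            "scan_index": rec.scan_index,
            "cohort": rec.cohort,
            "age": rec.age if rec.age is not None else np.nan,
            "sex": rec.sex if rec.sex is not None else "",
            "dx": rec.dx if rec.dx is not None else "",
            "mean_rel_mm_per_vol": s.mean_rel_mm_per_vol,
            "median_rel_mm_per_vol": s.median_rel_mm_per_vol,
            "mean_rel_mm_per_min": s.mean_rel_mm_per_min,
        }
        for i, axis in enumerate(("lr", "pa", "is")):
            row[f"trans_{axis}_mm_per_vol"] = s.trans_rate_per_vol[i]
            row[f"trans_{axis}_mm_per_min"] = s.trans_rate_per_min[i]
            row[f"rot_{axis}_deg_per_vol"] = s.rot_rate_per_vol[i]
            row[f"rot_{axis}_deg_per_min"] = s.rot_rate_per_min[i]
        rows.append(row)
    # %.17g guarantees bit-exact float round trips through the TSV
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_table(path: str | Path) -> pd.DataFrame:
    """Read a summary TSV written by :func:`write_summary_table`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"subject", "session", "scan_index", "mean_rel_mm_per_vol"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing summary column(s) {sorted(missing)}")
    return df
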