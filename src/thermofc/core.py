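"""Shared domain types, ROI conventions, symmetric-matrix vectorization and I/O.

The unit of analysis throughout the package is a per-acquisition matrix of
ROI cerebral-blood-volume (CBV) time series: one row per region of interest
(ROI), one column per Doppler frame.  This module fixes the canonical ROI
ordering, the thermal-condition vocabulary, the vectorization convention for
symmetric connectivity matrices, and the delimited-text file formats used by
every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ROI_NAMES",
    "DEFAULT_ROI_GROUPS",
    "CONDITION_LABELS",
    "RoiSet",
    "Acquisition",
    "CleanSeries",
    "CorrelationMatrix",
    "SymVector",
    "vectorize_symmetric",
    "devectorize_symmetric",
    "read_manifest",
    "write_manifest",
    "read_acquisition",
    "write_acquisition",
    "write_matrix",
    "read_matrix",
    "write_table",
    "write_sidecar",
]

# Canonical ROI order: atlas numbering 1-10 of the coronal imaging plane.
DEFAULT_ROI_NAMES: tuple[str, ...] = (
    "S1HLL", "M1L", "M2L", "CgL", "CgR", "M2R", "M1R", "S1HLR", "HyThL", "HyThR",
)

# Network membership used for reporting: primary somatosensory hindlimb and
# motor cortices form the somatomotor network; cingulate and hypothalamus
# are their own groups.
DEFAULT_ROI_GROUPS: dict[str, str] = {
    "S1HLL": "somatomotor",
    "M1L": "somatomotor",
    "M2L": "somatomotor",
    "M2R": "somatomotor",
    "M1R": "somatomotor",
    "S1HLR": "somatomotor",
    "CgL": "cingulate",
    "CgR": "cingulate",
    "HyThL": "hypothalamus",
    "HyThR": "hypothalamus",
}

# Thermal-condition vocabulary: three constant floor temperatures plus
# cool/warm, fast/slow, down/up ramps.
CONDITION_LABELS: tuple[str, ...] = (
    "15C", "25C", "35C",
    "CFD", "CFU", "CSD", "CSU",
    "WFU", "WFD", "WSU", "WSD",
)

MANIFEST_COLUMNS = ("acquisition_id", "animal_id", "condition", "fs_hz", "path")

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of ROI labels with network-group membership."""

    names: tuple[str, ...] = DEFAULT_ROI_NAMES
    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROI_GROUPS))

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise InvalidInputError("ROI names must be unique")
        missing = [n for n in self.names if n not in self.groups]
        if missing:
            raise InvalidInputError(f"ROIs without a group label: {missing}")

    @property
    def n(self) -> int:
        return len(self.names)

    def indices(self, group: str) -> list[int]:
        """Positions of the ROIs belonging to a network group."""
        return [i for i, name in enumerate(self.names) if self.groups[name] == group]

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class Acquisition:
    """One imaging session: ROI x frame CBV signals plus metadata."""

    acquisition_id: str
    animal_id: str
    condition: str
    fs: float
    signals: np.ndarray  # (n_roi, T_raw)
    roi: RoiSet = field(default_factory=RoiSet)
    motion_ref: np.ndarray | None = None  # (T_raw,), nonnegative tissue-motion energy

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.condition not in CONDITION_LABELS:
            raise InvalidInputError(
                f"unknown condition {self.condition!r}; expected one of {CONDITION_LABELS}"
            )
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if self.signals.ndim != 2 or self.signals.shape[0] != self.roi.n:
            raise InvalidInputError(
                f"signals must be ({self.roi.n}, T); got {self.signals.shape}"
            )
        if self.signals.shape[1] < 1:
            raise InvalidInputError("acquisition must contain at least one frame")
        if not np.all(np.isfinite(self.signals)):
            raise InvalidInputError("signals contain non-finite values")
        if self.motion_ref is not None:
            self.motion_ref = np.asarray(self.motion_ref, dtype=float)
            if self.motion_ref.shape != (self.signals.shape[1],):
                raise InvalidInputError("motion_ref length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]


@dataclass
class CleanSeries:
    """Concatenated artifact-free, conditioned ROI signals.

    ``epochs`` records the retained runs as (start, length) pairs in the
    original 0-based frame indexing; intervals are half-open.
    """

    signals: np.ndarray  # (n_roi, T)
    epochs: list[tuple[int, int]]
    source_id: str
    fs: float
    roi: RoiSet = field(default_factory=RoiSet)
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        total = sum(length for _, length in self.epochs)
        if total != self.signals.shape[1]:
            raise InvalidInputError(
                f"epoch lengths sum to {total} but series has {self.signals.shape[1]} frames"
            )
        prev_end = -1
        for start, length in self.epochs:
            if length < 1 or start < 0:
                raise InvalidInputError("epochs must be nonempty with nonnegative start")
            if start <= prev_end:
                raise InvalidInputError("epochs must be sorted and non-overlapping")
            prev_end = start + length - 1

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]


@dataclass
class CorrelationMatrix:
    """An N x N Pearson correlation matrix over a RoiSet."""

    values: np.ndarray
    roi: RoiSet
    n_frames: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = self.roi.n
        if v.shape != (n, n):
            raise InvalidInputError(f"expected ({n}, {n}) matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL):
            raise InvalidInputError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise InvalidInputError("correlation matrix diagonal must be 1")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise InvalidInputError("correlation entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(v).min() < -PSD_TOL:
            raise InvalidInputError("correlation matrix is not positive semidefinite")
        self.values = v


@dataclass
class SymVector:
    """Row-major upper-triangle vectorization of a symmetric matrix."""

    values: np.ndarray
    n: int
    with_diagonal: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n * (self.n + 1) // 2 if self.with_diagonal else self.n * (self.n - 1) // 2
        if self.values.shape[-1] != expected:
            raise InvalidInputError(
                f"vector length {self.values.shape[-1]} inconsistent with n={self.n}, "
                f"with_diagonal={self.with_diagonal} (expected {expected})"
            )


def triu_indices(n: int, with_diagonal: bool) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle index pair for the fixed vectorization order."""
    return np.triu_indices(n, k=0 if with_diagonal else 1)


def vectorize_symmetric(matrix: np.ndarray, with_diagonal: bool = True) -> SymVector:
    """Vectorize a symmetric matrix in fixed row-major upper-triangle order.

    For N=10 this yields the 55-element (with diagonal) or 45-element
    (off-diagonal only) vectors used throughout the connectivity analysis.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=SYMMETRY_TOL):
        raise InvalidInputError("matrix is not symmetric within tolerance")
    rows, cols = triu_indices(m.shape[0], with_diagonal)
    return SymVector(values=m[rows, cols], n=m.shape[0], with_diagonal=with_diagonal)


def devectorize_symmetric(vec: SymVector | np.ndarray, n: int | None = None,
                          with_diagonal: bool = True) -> np.ndarray:
    """Invert :func:`vectorize_symmetric`.

    Off-diagonal-only vectors devectorize to a matrix with zero diagonal.
    """
    if isinstance(vec, SymVector):
        values, n, with_diagonal = vec.values, vec.n, vec.with_diagonal
    else:
        values = np.asarray(vec, dtype=float)
        if n is None:
            raise InvalidInputError("n is required when passing a bare array")
    out = np.zeros((n, n), dtype=float)
    rows, cols = triu_indices(n, with_diagonal)
    out[rows, cols] = values
    out[cols, rows] = values
    return out


# ---------------------------------------------------------------------------
# File I/O: delimited text throughout, JSON sidecars for provenance.
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise InvalidInputError(f"{path}: file is empty or not delimited text") from None
    if df.empty and df.columns.empty:
        raise InvalidInputError(f"{path}: file is empty")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest and validate ids and condition labels.

    Returns a DataFrame with columns acquisition_id, animal_id, condition,
    fs_hz, path (ids coerced to str).
    """
    df = _read_delimited(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: manifest is missing columns {missing}")
    df = df.loc[:, list(MANIFEST_COLUMNS)].copy()
    df["acquisition_id"] = df["acquisition_id"].astype(str)
    df["animal_id"] = df["animal_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    bad = df.loc[~df["condition"].isin(CONDITION_LABELS)]
    if not bad.empty:
        row = bad.iloc[0]
        raise InvalidInputError(
            f"{path}: unknown condition {row['condition']!r} in row for "
            f"acquisition {row['acquisition_id']!r}"
        )
    dup = df["acquisition_id"].duplicated()
    if dup.any():
        raise InvalidInputError(
            f"{path}: duplicate acquisition_id {df.loc[dup, 'acquisition_id'].iloc[0]!r}"
        )
    return df


def write_manifest(path: str | Path, rows: Iterable[dict]) -> None:
    df = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)


def read_acquisition(path: str | Path, roi: RoiSet | None = None, *,
                     acquisition_id: str = "", animal_id: str = "",
                     condition: str = "25C", fs: float = 1.0) -> Acquisition:
    """Read an acquisition file (frames x ROIs, header row mandatory).

    Columns may appear in any order and are reordered to the canonical
    RoiSet order; an optional ``motion_ref`` column is carried along.
    """
    roi = roi or RoiSet()
    df = _read_delimited(path)
    missing = [name for name in roi.names if name not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing ROI columns {missing}")
    sub = df.loc[:, list(roi.names)]
    if sub.isna().any().any():
        raise InvalidInputError(f"{path}: NaN cells in ROI signals")
    signals = sub.to_numpy(dtype=float).T
    motion = None
    if "motion_ref" in df.columns:
        motion = df["motion_ref"].to_numpy(dtype=float)
    return Acquisition(
        acquisition_id=acquisition_id or Path(path).stem,
        animal_id=animal_id,
        condition=condition,
        fs=fs,
        signals=signals,
        roi=roi,
        motion_ref=motion,
    )


def load_cohort(manifest_path: str | Path, roi: RoiSet | None = None) -> list[Acquisition]:
    """Read every acquisition listed in a manifest, resolving relative paths."""
    roi = roi or RoiSet()
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    acqs = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        acqs.append(
            read_acquisition(
                p, roi,
                acquisition_id=row["acquisition_id"],
                animal_id=row["animal_id"],
                condition=row["condition"],
                fs=float(row["fs_hz"]),
            )
        )
    return acqs


def write_acquisition(path: str | Path, acq: Acquisition) -> None:
    """Write an acquisition as delimited text, one row per frame.

    Values are printed with 17 significant digits so that a write/read
    round-trip is lossless for double precision.
    """
    data = {name: acq.signals[i] for i, name in enumerate(acq.roi.names)}
    if acq.motion_ref is not None:
        data["motion_ref"] = acq.motion_ref
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_matrix(path: str | Path, matrix: np.ndarray, labels: Sequence[str]) -> None:
    """Write a labeled square matrix as delimited text."""
    m = np.asarray(matrix, dtype=float)
    pd.DataFrame(m, index=list(labels), columns=list(labels)).to_csv(
        path, float_format="%.17g"
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def write_sidecar(path: str | Path, **metadata) -> None:
    """Write a JSON provenance sidecar (seed, config hash, version ...)."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
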