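"""Reading, validation, assembly and persistence of Raman spectra.

A single-point measurement is a :class:`Spectrum` (wavenumber axis in
cm^-1 plus intensities in detector counts).  A study is a
:class:`HyperspectralDataset`: an m x n matrix ``A`` whose columns are
spectra sharing one wavenumber grid, together with per-column metadata
(cell id, group label, point index).  All downstream chemometrics
(PCA/LDA/SVM, MCR-ALS) operate on ``A``.

Files are plain two-column text (whitespace- or comma-delimited,
``#`` comments allowed); datasets persist as a matrix CSV plus a sibling
metadata CSV keyed by column id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AssemblyError, IntegrityError, ParseError, ValidationError

__all__ = [
    "Spectrum",
    "HyperspectralDataset",
    "read_spectrum",
    "assemble_dataset",
    "write_dataset",
    "read_dataset",
]

#: metadata keys every spectrum must carry before assembly
REQUIRED_META = ("cell_id", "group", "point")


@dataclass
class Spectrum:
    """One Raman spectrum: a strictly increasing wavenumber axis (cm^-1)
    and an equally long intensity vector (counts), plus free-form metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValidationError(
                f"axis length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise ValidationError("a spectrum needs at least 2 samples")
        d = np.diff(self.wavenumbers)
        if np.any(d <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class HyperspectralDataset:
    """m x n intensity matrix ``A`` on one shared wavenumber grid.

    ``columns`` is a DataFrame with one row per column of ``A`` and at
    least the fields ``id``, ``cell_id``, ``group``, ``point``.
    """

    axis: np.ndarray
    A: np.ndarray
    columns: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValidationError("A must be 2-D")
        if self.axis.size != self.A.shape[0]:
            raise ValidationError(
                f"axis length {self.axis.size} != matrix rows {self.A.shape[0]}"
            )
        if np.any(np.diff(self.axis) <= 0):
            raise ValidationError("axis must be strictly increasing")
        if len(self.columns) != self.A.shape[1]:
            raise IntegrityError(
                f"{len(self.columns)} metadata rows for {self.A.shape[1]} columns"
            )
        for key in ("group",):
            if key not in self.columns.columns:
                raise ValidationError(f"column metadata lacks required key {key!r}")

    @property
    def n_spectra(self) -> int:
        return int(self.A.shape[1])

    @property
    def n_wavenumbers(self) -> int:
        return int(self.A.shape[0])

    def groups(self) -> np.ndarray:
        return self.columns["group"].to_numpy()

    def replace(self, **kw) -> "HyperspectralDataset":
        out = {"axis": self.axis, "A": self.A, "columns": self.columns}
        out.update(kw)
        return HyperspectralDataset(
            axis=out["axis"], A=out["A"], columns=out["columns"].reset_index(drop=True)
        )


_NUMERIC_SPLIT = re.compile(r"[,\s]+")


def read_spectrum(path, meta: dict | None = None) -> Spectrum:
    """Read a two-column text file into a :class:`Spectrum`.

    Accepts whitespace- or comma-delimited columns (auto-detected) and
    ``#`` comment lines; rows are sorted into ascending wavenumber order.
    Duplicate wavenumbers and non-numeric rows are rejected.
    """
    path = Path(path)
    wn, counts = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _NUMERIC_SPLIT.split(line) if p]
            if len(parts) < 2:
                raise ParseError(f"{path.name}: line {lineno}: fewer than 2 columns")
            try:
                wn.append(float(parts[0]))
                counts.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path.name}: line {lineno}: non-numeric value") from exc
    if len(wn) < 2:
        raise ParseError(f"{path.name}: fewer than 2 data rows (empty spectrum)")
    wn_arr = np.asarray(wn)
    if np.unique(wn_arr).size != wn_arr.size:
        raise ParseError(f"{path.name}: duplicate wavenumbers")
    order = np.argsort(wn_arr)
    return Spectrum(wn_arr[order], np.asarray(counts)[order], dict(meta or {}))


def _column_id(meta: dict) -> str:
    return f"{meta['cell_id']}_{meta['point']}"


def assemble_dataset(
    spectra: Sequence[Spectrum], target_axis: np.ndarray | None = None
) -> HyperspectralDataset:
    """Stack spectra into one matrix on a shared wavenumber grid.

    The default grid is the first spectrum's axis clipped to the interval
    covered by every spectrum; spectra on other grids are linearly
    interpolated onto it.  Column order follows input order.
    """
    if not spectra:
        raise AssemblyError("no spectra to assemble")
    for i, s in enumerate(spectra):
        for key in REQUIRED_META:
            if key not in s.meta:
                raise ValidationError(f"spectrum {i} lacks metadata key {key!r}")
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if lo > hi:
        raise AssemblyError(f"spectra have disjoint axes (common interval [{lo}, {hi}])")
    if target_axis is None:
        base = spectra[0].wavenumbers
        target_axis = base[(base >= lo) & (base <= hi)]
    else:
        target_axis = np.asarray(target_axis, dtype=float)
        if target_axis[0] < lo or target_axis[-1] > hi:
            raise AssemblyError("target_axis extends beyond the common interval")
    cols = []
    for s in spectra:
        if s.wavenumbers.size == target_axis.size and np.array_equal(
            s.wavenumbers, target_axis
        ):
            cols.append(s.intensities)
        else:
            cols.append(np.interp(target_axis, s.wavenumbers, s.intensities))
    meta = pd.DataFrame(
        {
            "id": [_column_id(s.meta) for s in spectra],
            "cell_id": [s.meta["cell_id"] for s in spectra],
            "group": [s.meta["group"] for s in spectra],
            "point": [s.meta["point"] for s in spectra],
        }
    )
    return HyperspectralDataset(target_axis, np.column_stack(cols), meta)


def _meta_path(matrix_path: Path) -> Path:
    return matrix_path.with_name(matrix_path.stem + ".meta.csv")


def write_dataset(ds: HyperspectralDataset, path, meta_path=None) -> tuple[Path, Path]:
    """Persist a dataset as matrix CSV (first column = wavenumber, headers =
    column ids) plus a sibling metadata CSV keyed by column id."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    mat = pd.DataFrame(ds.A, columns=ds.columns["id"].to_numpy())
    mat.insert(0, "wavenumber", ds.axis)
    mat.to_csv(path, index=False, float_format="%.17g")
    ds.columns.to_csv(meta_path, index=False)
    return path, meta_path


def read_dataset(path, meta_path=None) -> HyperspectralDataset:
    """Inverse of :func:`write_dataset`; checks matrix/metadata consistency."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    mat = pd.read_csv(path, float_precision="round_trip")
    meta = pd.read_csv(meta_path)
    axis = mat["wavenumber"].to_numpy()
    A = mat.drop(columns="wavenumber").to_numpy()
    if len(meta) != A.shape[1]:
        raise IntegrityError(
            f"metadata has {len(meta)} rows but matrix has {A.shape[1]} columns"
        )
    ids_mat = list(mat.columns[1:])
    ids_meta = [str(x) for x in meta["id"]]
    if ids_mat != ids_meta:
        raise IntegrityError("column ids in matrix and metadata disagree")
    return HyperspectralDataset(axis, A, meta)
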