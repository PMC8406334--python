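"""Ramanome data model and file I/O.

A single-cell Raman spectrum (SCRS) is an intensity vector on a wavenumber
grid (cm^-1); a ramanome is the matrix of such spectra, one row per cell,
acquired from one isogenic population at one instant. All downstream
analysis (phenotypes, correlation networks, signatures) operates on the
``Ramanome`` container defined here.

Supported on-disk formats are plain text: per-cell two-column files
(wavenumber, intensity) as exported by Raman instruments, and wide
delimited matrices (rows = cells, header row = wavenumbers) with a sidecar
metadata table (cell_id, strain, condition, time_h, replicate). An
optional HDF5 container mirrors the same schema.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IrcaError", "ParseError", "AxisMismatchError", "DegenerateInputError",
    "SpectralAxis", "Spectrum", "CellMeta", "Ramanome", "RamanomeSeries",
    "read_spectrum", "read_ramanome", "write_ramanome",
    "read_ramanome_hdf5", "write_ramanome_hdf5",
]

META_COLUMNS = ("cell_id", "strain", "condition", "time_h", "replicate")


class IrcaError(Exception):
    """Base class for errors raised by this package."""


class ParseError(IrcaError):
    """A file could not be parsed; the message names the offending line."""


class AxisMismatchError(IrcaError):
    """Spectra that must share a wavenumber grid do not."""


class DegenerateInputError(IrcaError):
    """Input too small or otherwise degenerate for the requested operation."""


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        if w.ndim != 1 or w.size < 2:
            raise DegenerateInputError(
                f"spectral axis needs >= 2 points, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise IrcaError("spectral axis contains non-finite wavenumbers")
        if not np.all(np.diff(w) > 0):
            raise IrcaError("spectral axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return (len(self) == len(other)
                and bool(np.array_equal(self.wavenumbers, other.wavenumbers)))

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((len(self), float(self.wavenumbers[0]),
                     float(self.wavenumbers[-1])))

    @property
    def lo(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def hi(self) -> float:
        return float(self.wavenumbers[-1])

    def index_of(self, wavenumber: float, tol: float = 1.0) -> int:
        """Index of the grid point nearest ``wavenumber``.

        Raises if the nearest point is farther than ``tol`` cm^-1, so a
        named peak (e.g. 940 cm^-1) can only resolve onto a grid that
        actually covers it.
        """
        i = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        if abs(self.wavenumbers[i] - wavenumber) > tol:
            raise IrcaError(
                f"wavenumber {wavenumber} cm^-1 not resolvable on axis "
                f"[{self.lo}, {self.hi}] within +/-{tol} cm^-1"
            )
        return i


@dataclass(frozen=True)
class Spectrum:
    """One cell's intensities (arbitrary units) on a spectral axis."""

    axis: SpectralAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        if y.shape != (len(self.axis),):
            raise IrcaError(
                f"intensities shape {y.shape} does not match axis length "
                f"{len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise IrcaError("spectrum contains non-finite intensities")

    def __len__(self) -> int:
        return len(self.axis)


@dataclass(frozen=True)
class CellMeta:
    cell_id: str
    ramanome_id: str = ""


@dataclass
class Ramanome:
    """Cells x wavenumbers matrix plus per-cell and population metadata.

    ``meta`` carries population-level fields (strain, condition, time_h,
    replicate); time is stored uniformly in hours.
    """

    axis: SpectralAxis
    matrix: np.ndarray
    cells: list[CellMeta] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise IrcaError(f"ramanome matrix must be 2-D, got {m.ndim}-D")
        if m.shape[0] < 2:
            raise DegenerateInputError(
                f"a ramanome needs >= 2 cells, got {m.shape[0]}"
            )
        if m.shape[1] != len(self.axis):
            raise AxisMismatchError(
                f"matrix has {m.shape[1]} features but axis has "
                f"{len(self.axis)} points"
            )
        if not np.all(np.isfinite(m)):
            raise IrcaError("ramanome matrix contains non-finite values")
        self.matrix = m
        if not self.cells:
            rid = str(self.meta.get("ramanome_id", ""))
            self.cells = [CellMeta(f"cell_{i:04d}", rid)
                          for i in range(m.shape[0])]
        if len(self.cells) != m.shape[0]:
            raise IrcaError(
                f"{len(self.cells)} cell metadata rows for {m.shape[0]} "
                "spectra"
            )
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise IrcaError("cell_id values must be unique within a ramanome")

    @property
    def n_cells(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.matrix.shape[1])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.matrix[i])

    def peak_column(self, wavenumber: float, tol: float = 1.0) -> np.ndarray:
        """Per-cell intensities at the grid point nearest ``wavenumber``."""
        return self.matrix[:, self.axis.index_of(wavenumber, tol)]


@dataclass
class RamanomeSeries:
    """Time-ordered ramanomes of one population, sharing one axis."""

    ramanomes: list[Ramanome]
    time_points: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, dtype=float)
        if len(self.ramanomes) != t.size:
            raise IrcaError("ramanomes and time_points lengths differ")
        if np.any(np.diff(t) < 0):
            raise IrcaError("time_points must be non-decreasing")
        axes = {r.axis for r in self.ramanomes}
        if len({(len(r.axis), r.axis.lo, r.axis.hi) for r in self.ramanomes}) > 1 \
                or any(not np.array_equal(r.axis.wavenumbers,
                                          self.ramanomes[0].axis.wavenumbers)
                       for r in self.ramanomes):
            raise AxisMismatchError("all ramanomes in a series must share one axis")
        del axes
        self.time_points = t

    def __len__(self) -> int:
        return len(self.ramanomes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    w: list[float] = []
    y: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got "
                    f"{len(parts)}"
                )
            try:
                w.append(float(parts[0]))
                y.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: malformed numeric field ({exc})"
                ) from None
    return np.asarray(w), np.asarray(y)


def read_spectrum(path: str | os.PathLike, dialect: str = "two_column") -> Spectrum:
    """Read one spectrum from a two-column text file.

    The file holds one (wavenumber, intensity) pair per line, whitespace or
    comma separated; rows may appear in any order and are sorted onto an
    ascending axis. Duplicate wavenumbers are rejected.
    """
    if dialect != "two_column":
        raise ValueError(f"unknown dialect {dialect!r}")
    p = Path(path)
    w, y = _parse_two_column(p)
    if w.size < 2:
        raise DegenerateInputError(f"{p}: fewer than 2 spectral points")
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    if np.any(np.diff(w) == 0):
        dup = w[:-1][np.diff(w) == 0][0]
        raise ParseError(f"{p}: duplicate wavenumber {dup}")
    return Spectrum(SpectralAxis(w), y)


def _read_meta(meta: str | os.PathLike | pd.DataFrame | None,
               n_cells: int) -> pd.DataFrame:
    if meta is None:
        return pd.DataFrame({"cell_id": [f"cell_{i:04d}" for i in range(n_cells)]})
    df = meta.copy() if isinstance(meta, pd.DataFrame) else pd.read_csv(meta)
    if "cell_id" not in df.columns:
        raise ParseError("metadata table must have a 'cell_id' column")
    if len(df) != n_cells:
        raise IrcaError(
            f"metadata has {len(df)} rows for {n_cells} spectra"
        )
    return df.reset_index(drop=True)


def _population_meta(df: pd.DataFrame) -> dict:
    out: dict = {}
    for col in ("strain", "condition", "time_h", "replicate", "ramanome_id"):
        if col in df.columns:
            vals = df[col].dropna().unique()
            if len(vals) == 1:
                v = vals[0]
                out[col] = float(v) if col == "time_h" else v
    return out


def read_ramanome(dir_or_matrix: str | os.PathLike,
                  meta: str | os.PathLike | pd.DataFrame | None = None,
                  *, resample_to: SpectralAxis | None = None) -> Ramanome:
    """Read a ramanome from a directory of two-column files or a wide matrix.

    A directory is read as one spectrum per ``*.txt``/``*.csv`` file (sorted
    by filename; filenames become cell ids unless ``meta`` supplies them).
    A file is read as a wide delimited matrix whose header row holds the
    wavenumbers and whose rows are cells. All cells must share one axis;
    pass ``resample_to`` to unify mismatched axes by linear interpolation.
    """
    from irca.preprocess import resample  # local import to avoid a cycle

    p = Path(dir_or_matrix)
    if p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in (".txt", ".csv", ".tsv", ".dat"))
        if len(files) < 2:
            raise DegenerateInputError(
                f"{p}: need >= 2 spectrum files, found {len(files)}"
            )
        spectra = [read_spectrum(q) for q in files]
        if resample_to is not None:
            spectra = [resample(s, resample_to) for s in spectra]
        ax = spectra[0].axis
        for q, s in zip(files[1:], spectra[1:]):
            if not np.array_equal(s.axis.wavenumbers, ax.wavenumbers):
                raise AxisMismatchError(
                    f"{q}: axis differs from {files[0]}; pass resample_to="
                    "to unify"
                )
        matrix = np.vstack([s.intensities for s in spectra])
        df = _read_meta(meta, len(files))
        if meta is None:
            df["cell_id"] = [q.stem for q in files]
    else:
        sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
        wide = pd.read_csv(p, sep=sep, index_col=0,
                           float_precision="round_trip")
        try:
            w = wide.columns.to_numpy(dtype=float)
        except (TypeError, ValueError):
            raise ParseError(
                f"{p}: header row must hold numeric wavenumbers"
            ) from None
        ax = SpectralAxis(w)
        matrix = wide.to_numpy(dtype=float)
        if resample_to is not None:
            matrix = np.vstack([
                resample(Spectrum(ax, row), resample_to).intensities
                for row in matrix
            ])
            ax = resample_to
        df = _read_meta(meta, matrix.shape[0])
        if meta is None:
            df["cell_id"] = wide.index.astype(str).tolist()
    rid = str(df["ramanome_id"].iloc[0]) if "ramanome_id" in df.columns else p.stem
    cells = [CellMeta(str(c), rid) for c in df["cell_id"]]
    pop = _population_meta(df)
    pop.setdefault("ramanome_id", rid)
    return Ramanome(ax, matrix, cells, pop)


def write_ramanome(r: Ramanome, path: str | os.PathLike) -> Path:
    """Write a ramanome as a wide CSV plus ``<stem>.meta.csv`` sidecar.

    Values are written with 17 significant digits so a read/write round
    trip reproduces the float64 matrix bitwise.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    wide = pd.DataFrame(
        r.matrix,
        index=[c.cell_id for c in r.cells],
        columns=[np.format_float_positional(w, trim="-")
                 for w in r.axis.wavenumbers],
    )
    wide.index.name = "cell_id"
    wide.to_csv(p, float_format="%.17g")
    meta = pd.DataFrame({"cell_id": [c.cell_id for c in r.cells]})
    for k in ("strain", "condition", "time_h", "replicate", "ramanome_id"):
        if k in r.meta:
            meta[k] = r.meta[k]
    meta.to_csv(p.with_suffix(".meta.csv"), index=False)
    return p


def read_ramanome_hdf5(path: str | os.PathLike) -> Ramanome:
    import h5py

    with h5py.File(path, "r") as f:
        ax = SpectralAxis(f["wavenumbers"][...])
        matrix = f["matrix"][...]
        cell_ids = [s.decode() for s in f["cell_id"][...]]
        meta = {k: (v.decode() if isinstance(v, bytes) else v)
                for k, v in f.attrs.items()}
    rid = str(meta.get("ramanome_id", ""))
    cells = [CellMeta(c, rid) for c in cell_ids]
    return Ramanome(ax, matrix, cells, meta)


def write_ramanome_hdf5(r: Ramanome, path: str | os.PathLike) -> Path:
    import h5py

    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(p, "w") as f:
        f.create_dataset("wavenumbers", data=r.axis.wavenumbers)
        f.create_dataset("matrix", data=r.matrix)
        f.create_dataset(
            "cell_id",
            data=np.array([c.cell_id.encode() for c in r.cells]),
        )
        for k, v in r.meta.items():
            if v is not None:
                f.attrs[k] = v
    return p
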