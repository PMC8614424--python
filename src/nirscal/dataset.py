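"""Containers and text I/O for NIR spectra and wet-chemistry reference tables.

Spectra are stored as absorbance, log10(1/R), on a strictly increasing
uniform wavelength grid in nm.  Reference values are percent of dry matter.
The native on-disk format for both is delimited UTF-8 text so that fixtures
diff cleanly and round-trip bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridError, ParseError, RangeError

log = logging.getLogger(__name__)

#: Constituents reported on a dry-matter basis, in canonical order.
CONSTITUENTS = ("moisture", "cp", "ndf", "adf", "adl", "hemicellulose")

_GRID_TOL = 1e-9  # max absolute deviation of the wavelength step, nm


def _check_grid(wavelengths: np.ndarray) -> None:
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise GridError("wavelength grid needs at least two points")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise GridError("wavelengths must be strictly increasing")
    if np.max(np.abs(steps - steps[0])) > _GRID_TOL:
        raise GridError(
            f"wavelength step is not uniform: spread {np.ptp(steps):.3g} nm"
        )


@dataclass
class SpectraSet:
    """A wavelength grid plus one absorbance row per sample.

    Every pipeline stage consumes and returns this object; stages that
    shorten the spectrum (derivatives, smoothing) carry the trimmed grid
    so downstream wavelength counts stay honest.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    species: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_grid(self.wavelengths)
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise GridError(
                f"absorbance has {p} columns but grid has {self.wavelengths.size}"
            )
        if n != len(self.sample_ids):
            raise ParseError(
                f"{n} spectra but {len(self.sample_ids)} sample ids"
            )
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ParseError(
                f"non-finite absorbance at sample {self.sample_ids[bad[0]]}, "
                f"wavelength {self.wavelengths[bad[1]]} nm"
            )
        seen: set[str] = set()
        for sid in self.sample_ids:
            if sid in seen:
                raise ParseError(f"duplicate sample id: {sid!r}")
            seen.add(sid)
        if self.species is not None:
            self.species = [str(s) for s in self.species]
            if len(self.species) != n:
                raise ParseError("species labels do not match sample count")

    # -- basic views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def take(self, index: Sequence[int] | np.ndarray) -> "SpectraSet":
        """Row subset/reorder by positional index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[index],
            sample_ids=[self.sample_ids[i] for i in index],
            species=[self.species[i] for i in index] if self.species else None,
        )

    def select_ids(self, ids: Sequence[str]) -> "SpectraSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            index = [pos[s] for s in ids]
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return self.take(index)

    def subset_wavelengths(self, mask: np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask)
        return replace(
            self,
            wavelengths=self.wavelengths[mask],
            absorbance=self.absorbance[:, mask],
        )

    def with_matrix(
        self, absorbance: np.ndarray, wavelengths: np.ndarray | None = None
    ) -> "SpectraSet":
        """Same samples, new absorbance matrix (and optionally new grid)."""
        return SpectraSet(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            species=list(self.species) if self.species else None,
        )


@dataclass
class ReferenceTable:
    """Per-sample wet-chemistry values (% DM) used as regression targets.

    Missing values are NaN, never silent zeros.  NDF < ADF in a complete
    row is logged as a consistency warning but kept: wet chemistry is
    noisy and discarding data is the outlier screens' job, not the
    reader's.
    """

    data: pd.DataFrame  # index: sample_id; columns: constituents
    species: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 100)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise RangeError(
                f"value {vals[i, j]} for {self.data.columns[j]} of sample "
                f"{self.data.index[i]!r} outside [0, 100] %DM"
            )
        if {"ndf", "adf"} <= set(self.data.columns):
            both = self.data[["ndf", "adf"]].dropna()
            inverted = both[both["ndf"] < both["adf"]]
            for sid, row in inverted.iterrows():
                log.warning(
                    "sample %s: NDF (%.4g) < ADF (%.4g); row retained",
                    sid, row["ndf"], row["adf"],
                )
        if self.species is not None and not self.species.index.equals(self.data.index):
            raise ParseError("species labels do not align with sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def constituents(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, constituent: str) -> pd.Series:
        if constituent not in self.data.columns:
            raise KeyError(f"unknown constituent {constituent!r}")
        return self.data[constituent]

    def select_ids(self, ids: Sequence[str]) -> "ReferenceTable":
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample id {missing[0]!r}")
        return ReferenceTable(
            data=self.data.loc[list(ids)].copy(),
            species=self.species.loc[list(ids)].copy() if self.species is not None else None,
        )

    def concat(self, other: "ReferenceTable") -> "ReferenceTable":
        data = pd.concat([self.data, other.data])
        sp = None
        if self.species is not None and other.species is not None:
            sp = pd.concat([self.species, other.species])
        return ReferenceTable(data=data, species=sp)


def concat_spectra(sets: Sequence[SpectraSet]) -> SpectraSet:
    """Pool several SpectraSets sharing one grid (grid mismatch is an error)."""
    first = sets[0]
    for s in sets[1:]:
        if s.wavelengths.shape != first.wavelengths.shape or np.any(
            np.abs(s.wavelengths - first.wavelengths) > _GRID_TOL
        ):
            raise GridError("cannot pool SpectraSets on different grids")
    species: list[str] | None = []
    for s in sets:
        if s.species is None:
            species = None
            break
        species.extend(s.species)
    return SpectraSet(
        wavelengths=first.wavelengths.copy(),
        absorbance=np.vstack([s.absorbance for s in sets]),
        sample_ids=[sid for s in sets for sid in s.sample_ids],
        species=species,
    )


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

_ID_COL = "sample_id"
_SPECIES_COL = "species"
_FLOAT_FMT = "%.17g"  # shortest round-trip-exact decimal for float64


def read_spectra(path, dialect: str = "csv") -> SpectraSet:
    """Read a spectra matrix: first column sample id, optional ``species``
    column, remaining column headers wavelengths in nm."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    if df.columns[0] != _ID_COL:
        raise ParseError(
            f"{path}: first column must be {_ID_COL!r}, got {df.columns[0]!r}"
        )
    species = None
    cols = list(df.columns[1:])
    if cols and cols[0] == _SPECIES_COL:
        species = df[_SPECIES_COL].tolist()
        cols = cols[1:]
    if not cols:
        raise ParseError(f"{path}: no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in cols])
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric wavelength header: {e}") from e
    try:
        _check_grid(wavelengths)
    except GridError as e:
        raise GridError(f"{path}: {e}") from e
    matrix = np.empty((len(df), wavelengths.size))
    for j, c in enumerate(cols):
        try:
            matrix[:, j] = df[c].astype(float)
        except ValueError:
            for i, v in enumerate(df[c]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell {v!r} at sample "
                        f"{df.iloc[i, 0]!r}, wavelength {c} nm"
                    ) from None
            raise
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=matrix,
        sample_ids=df[_ID_COL].tolist(),
        species=species,
    )


def write_spectra(path, s: SpectraSet, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.DataFrame(
        s.absorbance, columns=[_FLOAT_FMT % w for w in s.wavelengths]
    )
    df.insert(0, _ID_COL, s.sample_ids)
    if s.species is not None:
        df.insert(1, _SPECIES_COL, s.species)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_reference(path, na_values: str | Sequence[str] = "NA") -> ReferenceTable:
    """Read a reference table: sample_id column, constituent columns (% DM),
    optional ``species`` column; the declared NA sentinel marks missing."""
    if isinstance(na_values, str):
        na_values = [na_values]
    df = pd.read_csv(
        path, na_values=list(na_values), keep_default_na=False, dtype=str
    )
    if _ID_COL not in df.columns:
        raise ParseError(f"{path}: missing {_ID_COL!r} column")
    df = df.set_index(_ID_COL)
    species = None
    if _SPECIES_COL in df.columns:
        species = df.pop(_SPECIES_COL)
    try:
        data = df.astype(float)
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric reference value: {e}") from e
    return ReferenceTable(data=data, species=species)


def write_reference(path, ref: ReferenceTable, na_rep: str = "NA") -> None:
    df = ref.data.copy()
    if ref.species is not None:
        df.insert(0, _SPECIES_COL, ref.species)
    df.index.name = _ID_COL
    df.to_csv(path, na_rep=na_rep, float_format=_FLOAT_FMT)


def average_replicates(
    s: SpectraSet, groups: Mapping[str, str]
) -> SpectraSet:
    """Average replicate scans into one spectrum per sample.

    ``groups`` maps every scan id in ``s`` to its sample id; each output
    row is the arithmetic mean (in absorbance space) of its group's scans.
    Output sample order follows first appearance of each sample id.
    """
    for sid in s.sample_ids:
        if sid not in groups:
            raise KeyError(f"scan id {sid!r} missing from replicate groups")
    unknown = set(groups) - set(s.sample_ids)
    if unknown:
        raise KeyError(f"replicate group references unknown scan id {sorted(unknown)[0]!r}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, scan in enumerate(s.sample_ids):
        target = groups[scan]
        if target not in members:
            members[target] = []
            order.append(target)
        members[target].append(i)
    rows = np.vstack(
        [s.absorbance[members[t]].mean(axis=0) for t in order]
    )
    species = None
    if s.species is not None:
        species = [s.species[members[t][0]] for t in order]
    return SpectraSet(
        wavelengths=s.wavelengths.copy(),
        absorbance=rows,
        sample_ids=order,
        species=species,
    )
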