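"""Reading and writing Raman spectra and sample metadata.

Everything downstream operates on a shared axis convention: wavenumbers in
cm^-1, strictly ascending, finite, paired one-to-one with intensities in
arbitrary units (a.u.).  Intensities may be negative — baseline subtraction
and derivative filters legitimately produce negative values.

Two plain-CSV dialects are supported (optionally prefixed with ``#`` comment
lines):

* two-column — header ``wavenumber,intensity``, one spectrum per file;
* matrix — first column ``wavenumber``, one additional column per sample,
  column headers are the sample ids.

Sample metadata travels in a separate CSV with columns
``sample_id,concentration,unit,group`` and is joined by exact sample-id
match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum_set",
    "read_metadata",
    "attach_metadata",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed into a valid SpectrumSet."""


def _as_axis(wavenumbers: np.ndarray, intensities: np.ndarray):
    """Validate an axis/intensity pair, silently reversing a descending axis.

    Raman acquisition software frequently exports the axis high-to-low; a
    strictly descending axis is reversed (with its intensities kept paired)
    rather than rejected.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if nu.ndim != 1:
        raise ValueError("wavenumbers must be one-dimensional")
    if nu.shape[0] != inten.shape[-1]:
        raise ValueError(
            f"axis length {nu.shape[0]} does not match intensity length {inten.shape[-1]}"
        )
    if nu.shape[0] < 2:
        raise ValueError("a spectrum needs at least 2 points")
    if not np.all(np.isfinite(nu)):
        raise ValueError("wavenumbers must be finite")
    if not np.all(np.isfinite(inten)):
        raise ValueError("intensities must be finite")
    diffs = np.diff(nu)
    if np.all(diffs < 0):
        logger.info("descending wavenumber axis reversed to ascending")
        nu = nu[::-1].copy()
        inten = inten[..., ::-1].copy()
    elif not np.all(diffs > 0):
        raise ValueError("wavenumbers must be strictly monotonic")
    return nu, inten


@dataclass
class Spectrum:
    """One Raman spectrum: a wavenumber axis (cm^-1) and intensities (a.u.)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.wavenumbers, self.intensities = _as_axis(
            self.wavenumbers, np.asarray(self.intensities, dtype=float)
        )

    def __len__(self) -> int:
        return self.wavenumbers.shape[0]

    @property
    def step(self) -> float:
        """Mean axis spacing in cm^-1."""
        return float(np.mean(np.diff(self.wavenumbers)))

    def intensity_at(self, wavenumber: float) -> float:
        """Intensity at the axis point nearest to ``wavenumber``."""
        idx = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        return float(self.intensities[idx])


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis.

    ``intensities`` is (n_samples, n_points).  ``concentrations`` holds the
    per-sample analyte concentration (NaN where unknown) in the recorded
    ``unit``; ``groups`` carries replicate-group labels.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    concentrations: np.ndarray | None = None
    unit: str = ""
    groups: list[str] | None = None

    def __post_init__(self):
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.wavenumbers, self.intensities = _as_axis(self.wavenumbers, self.intensities)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise ValueError("one sample_id required per spectrum")
        if self.concentrations is not None:
            self.concentrations = np.asarray(self.concentrations, dtype=float)
            if self.concentrations.shape[0] != len(self.sample_ids):
                raise ValueError("one concentration required per spectrum")
            known = self.concentrations[~np.isnan(self.concentrations)]
            if np.any(known < 0):
                raise ValueError("concentrations must be non-negative")
        if self.groups is not None and len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label required per spectrum")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i], self.sample_ids[i])

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = list(indices)
        return SpectrumSet(
            self.wavenumbers,
            self.intensities[idx],
            [self.sample_ids[i] for i in idx],
            None if self.concentrations is None else self.concentrations[idx],
            self.unit,
            None if self.groups is None else [self.groups[i] for i in idx],
        )

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum], **kwargs) -> "SpectrumSet":
        if not spectra:
            raise ValueError("cannot build a SpectrumSet from zero spectra")
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != axis.shape or not np.array_equal(s.wavenumbers, axis):
                raise ValueError("all spectra must share an identical wavenumber axis")
        return cls(
            axis,
            np.vstack([s.intensities for s in spectra]),
            [s.sample_id for s in spectra],
            **kwargs,
        )


def _numeric_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    """Coerce every cell to float, raising a parse error naming the bad cell."""
    out = {}
    for col in df.columns:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectrumParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, data row {row}"
            )
        if num.isna().any():
            row = int(np.flatnonzero(num.isna().to_numpy())[0])
            raise SpectrumParseError(
                f"{path}: missing value in column {col!r}, data row {row} (ragged matrix?)"
            )
        out[col] = num.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_spectrum(path, dialect: str = "auto") -> SpectrumSet:
    """Read a two-column or matrix CSV into a :class:`SpectrumSet`.

    ``dialect`` is ``"two-column"``, ``"matrix"`` or ``"auto"`` (two-column
    when the file has exactly the columns ``wavenumber,intensity``).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 1 or df.columns[0].strip().lower() != "wavenumber":
        raise SpectrumParseError(f"{path}: first column must be 'wavenumber'")
    cols = [c.strip() for c in df.columns]
    if dialect == "auto":
        dialect = "two-column" if cols == ["wavenumber", "intensity"] else "matrix"
    if dialect not in ("two-column", "matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "two-column" and cols != ["wavenumber", "intensity"]:
        raise SpectrumParseError(
            f"{path}: two-column dialect requires header 'wavenumber,intensity'"
        )
    if df.shape[1] == 1 and df.shape[0] == 0:
        # header-only file: an empty set on an empty axis is represented as
        # a zero-sample matrix on a minimal two-point axis placeholder
        raise SpectrumParseError(f"{path}: file contains no data rows")
    num = _numeric_frame(df, path)
    nu = num.iloc[:, 0].to_numpy()
    if dialect == "two-column":
        inten = num.iloc[:, 1].to_numpy()[None, :]
        ids = [path.stem]
    else:
        # zero sample columns is legal: the empty-set round trip
        inten = num.iloc[:, 1:].to_numpy().T
        ids = [c.strip() for c in df.columns[1:]]
    return SpectrumSet(nu, inten, ids)


def write_spectrum_set(sset: SpectrumSet, path) -> None:
    """Write a SpectrumSet as a matrix CSV (full round-trip precision).

    Floats are written with Python's shortest round-trip repr, so
    ``read_spectrum(write_spectrum_set(s))`` reproduces the values exactly.
    """
    path = Path(path)
    df = pd.DataFrame({"wavenumber": sset.wavenumbers})
    for i, sid in enumerate(sset.sample_ids):
        df[sid] = sset.intensities[i]
    df.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read a ``sample_id,concentration,unit,group`` metadata CSV."""
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str})
    required = {"sample_id", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise SpectrumParseError(f"{path}: metadata missing columns {sorted(missing)}")
    if "unit" not in df.columns:
        df["unit"] = ""
    if "group" not in df.columns:
        df["group"] = ""
    return df


def attach_metadata(sset: SpectrumSet, meta: pd.DataFrame) -> SpectrumSet:
    """Join metadata onto a SpectrumSet by exact sample-id match.

    Every spectrum must have a metadata row; unmatched ids raise an error
    listing them.
    """
    table = meta.set_index(meta["sample_id"].astype(str))
    unmatched = [sid for sid in sset.sample_ids if sid not in table.index]
    if unmatched:
        raise KeyError(f"sample ids without metadata: {unmatched}")
    rows = table.loc[sset.sample_ids]
    units = [u for u in rows["unit"].astype(str).unique() if u and u != "nan"]
    return SpectrumSet(
        sset.wavenumbers,
        sset.intensities,
        sset.sample_ids,
        rows["concentration"].to_numpy(dtype=float),
        units[0] if units else "",
        rows["group"].astype(str).tolist(),
    )
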