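"""Core data model for NIR spectra and the wide-CSV reader/writer.

A dataset is a :class:`SpectraBlock`: an ``N x P`` absorbance matrix on an
evenly spaced wavelength grid, with one row of sample metadata per spectrum.
Metadata follow the acquisition hierarchy of a bench NIR experiment on
prepared mixtures: each *sample type* (a variety label plus an adulterant
mass fraction) is prepared in replicates, each replicate is loaded into the
cuvette in refills, and each refill is scanned several consecutive times.

The on-disk format is a wide CSV: the seven metadata columns first, then one
column per wavelength, named by its nm value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, GridError

#: Fixed metadata column order for the wide CSV format.
META_COLUMNS = [
    "sample_id",
    "variety",
    "robusta_fraction",
    "form",
    "replicate",
    "refill",
    "scan",
]

_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced, strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise GridError("wavelength grid needs at least two points")
        diffs = np.diff(values)
        if np.any(diffs <= 0):
            raise GridError("wavelengths must be strictly increasing")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=_GRID_RTOL, atol=step * _GRID_RTOL):
            raise GridError(
                f"wavelength spacing is not uniform (min {diffs.min():g}, max {diffs.max():g} nm)"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def from_range(cls, start_nm: float, end_nm: float, step_nm: float) -> "WavelengthGrid":
        if not (start_nm < end_nm and step_nm > 0):
            raise GridError("need start < end and step > 0")
        n = int(round((end_nm - start_nm) / step_nm)) + 1
        values = start_nm + step_nm * np.arange(n)
        if not np.isclose(values[-1], end_nm):
            raise GridError(f"range {start_nm}-{end_nm} nm is not a whole number of {step_nm} nm steps")
        return cls(values)

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def end_nm(self) -> float:
        return float(self.values[-1])

    @property
    def step_nm(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def nearest_index(self, nm: float) -> int:
        """Index of the grid point closest to ``nm``."""
        return int(np.argmin(np.abs(self.values - nm)))


def default_grid() -> WavelengthGrid:
    """The instrument's full range: 740-1700 nm at 2 nm spacing (481 points)."""
    return WavelengthGrid.from_range(740.0, 1700.0, 2.0)


@dataclass
class SpectraBlock:
    """Absorbance matrix with per-row sample metadata.

    Attributes
    ----------
    grid : WavelengthGrid
        Shared wavelength axis; ``absorbance.shape[1] == len(grid)``.
    absorbance : ndarray, shape (N, P)
        Unitless absorbance values; no NaN/inf allowed.
    meta : DataFrame
        One row per spectrum, columns :data:`META_COLUMNS`.
    provenance : list of str
        Human-readable record of the processing steps applied so far.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[0] < 1:
            raise DimensionError("a SpectraBlock needs at least one spectrum")
        if self.absorbance.shape[1] != len(self.grid):
            raise DimensionError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise DimensionError("absorbance contains missing or non-finite values")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise FormatError(f"metadata is missing column(s): {', '.join(missing)}")
        if len(self.meta) != self.absorbance.shape[0]:
            raise DimensionError("metadata row count does not match spectra count")
        frac = self.meta["robusta_fraction"].to_numpy(dtype=float)
        if np.any((frac < 0) | (frac > 100)):
            raise DimensionError("robusta_fraction must lie in [0, 100] % w/w")
        meta = self.meta.reset_index(drop=True)[META_COLUMNS].copy()
        meta["sample_id"] = meta["sample_id"].astype(str)
        meta["variety"] = meta["variety"].astype(str)
        meta["form"] = meta["form"].astype(str)
        meta["robusta_fraction"] = meta["robusta_fraction"].astype(float)
        for col in ("replicate", "refill", "scan"):
            meta[col] = meta[col].astype(int)
        self.meta = meta

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def copy_with(self, *, absorbance=None, grid=None, meta=None, step: str | None = None) -> "SpectraBlock":
        """A modified copy, appending ``step`` to the provenance trail."""
        prov = list(self.provenance) + ([step] if step else [])
        return SpectraBlock(
            grid=grid if grid is not None else self.grid,
            absorbance=absorbance if absorbance is not None else self.absorbance.copy(),
            meta=meta if meta is not None else self.meta.copy(),
            provenance=prov,
        )

    def select(self, mask) -> "SpectraBlock":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectraBlock(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            meta=self.meta.iloc[idx],
            provenance=list(self.provenance),
        )


@dataclass(frozen=True)
class MixtureDesign:
    """Experimental design of a two-endmember mixture study.

    ``levels`` are adulterant (Robusta) mass fractions in % w/w, strictly
    inside (0, 100); ``controls`` are the pure endmembers (0 and 100);
    ``blends`` are externally sourced test samples given as (label, fraction)
    pairs.  Each sample type is measured ``n_replicates x n_refills x
    n_scans`` times.
    """

    levels: tuple
    n_replicates: int = 3
    n_refills: int = 3
    n_scans: int = 3
    controls: tuple = (0.0, 100.0)
    blends: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        object.__setattr__(self, "controls", tuple(float(v) for v in self.controls))
        object.__setattr__(self, "blends", tuple((str(l), float(f)) for l, f in self.blends))
        if any(not (0.0 < v < 100.0) for v in self.levels):
            raise DimensionError("mixture levels must lie strictly inside (0, 100) % w/w")
        if min(self.n_replicates, self.n_refills, self.n_scans) < 1:
            raise DimensionError("replicate/refill/scan counts must be positive")

    @property
    def n_sample_types(self) -> int:
        return len(self.levels) + len(self.controls) + len(self.blends)

    @property
    def total_spectra(self) -> int:
        return self.n_sample_types * self.n_replicates * self.n_refills * self.n_scans


def read_spectra(path) -> SpectraBlock:
    """Read a wide-CSV spectra table.

    The header must name the seven metadata columns followed by numeric
    wavelength columns in increasing order with uniform spacing.
    """
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {', '.join(missing)}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not wl_cols:
        raise FormatError(f"{path}: no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength column header: {exc}") from None
    grid = WavelengthGrid(wavelengths)  # raises GridError on uneven spacing
    absorbance = df[wl_cols].to_numpy(dtype=float)
    return SpectraBlock(grid=grid, absorbance=absorbance, meta=df[META_COLUMNS])


def write_spectra(block: SpectraBlock, path) -> str:
    """Write a block as wide CSV (lossless: 17 significant digits)."""
    out = block.meta.copy()
    wl_names = [f"{v:.1f}" for v in block.grid.values]
    spec = pd.DataFrame(block.absorbance, columns=wl_names)
    pd.concat([out, spec], axis=1).to_csv(path, index=False, float_format="%.17g")
    return str(path)


__all__ = [
    "META_COLUMNS",
    "WavelengthGrid",
    "SpectraBlock",
    "MixtureDesign",
    "default_grid",
    "read_spectra",
    "write_spectra",
]
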