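"""Spectral preprocessing: truncation, Savitzky-Golay, MSC, SNV, detrend, averaging.

All operations take and return :class:`~aquanir.io.SpectraBlock` and can be
composed into an ordered chain (:class:`PreprocessSpec`).  Conventions:

* Savitzky-Golay edge columns (half a window per side) are dropped, not
  extrapolated, so every retained point is a true centered polynomial fit;
  the grid shrinks accordingly.  Derivatives are scaled per nm.
* The MSC reference is the mean of the block it is *fit* on and is returned
  so held-out data can be corrected against the calibration reference.
* Sample standard deviations (ddof=1) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import DegenerateDataError, ParameterError, RangeError
from .io import META_COLUMNS, SpectraBlock, WavelengthGrid

_B_TOL = 1e-12  # |slope| below this makes an MSC row degenerate

VALID_STEPS = {"truncate", "savgol", "msc", "snv", "detrend", "average"}
AVERAGE_LEVELS = ("scan", "refill", "replicate")


def truncate(block: SpectraBlock, lo_nm: float, hi_nm: float) -> SpectraBlock:
    """Keep wavelengths with lo <= lambda <= hi (inclusive)."""
    keep = (block.grid.values >= lo_nm) & (block.grid.values <= hi_nm)
    if not keep.any():
        raise RangeError(f"truncation window {lo_nm}-{hi_nm} nm does not overlap the grid")
    return block.copy_with(
        absorbance=block.absorbance[:, keep],
        grid=WavelengthGrid(block.grid.values[keep]),
        step=f"truncate({lo_nm:g},{hi_nm:g})",
    )


def savgol(block: SpectraBlock, window: int, polyorder: int, deriv: int = 0) -> SpectraBlock:
    """Savitzky-Golay smoothing / derivative filter, per spectrum.

    ``window`` is an odd point count; the derivative (order ``deriv``) is in
    per-nm units.  The (window-1)/2 edge columns on each side are dropped.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ParameterError(f"polyorder {polyorder} must be < window {window}")
    if deriv > polyorder:
        raise ParameterError(f"deriv {deriv} must be <= polyorder {polyorder}")
    if window > block.n_wavelengths:
        raise ParameterError(f"window {window} exceeds {block.n_wavelengths} wavelengths")
    half = (window - 1) // 2
    filtered = savgol_filter(
        block.absorbance, window, polyorder, deriv=deriv, delta=block.grid.step_nm, axis=1
    )
    return block.copy_with(
        absorbance=filtered[:, half:-half],
        grid=WavelengthGrid(block.grid.values[half:-half]),
        step=f"savgol({window},{polyorder},{deriv})",
    )


def msc(block: SpectraBlock, reference="mean") -> tuple[SpectraBlock, np.ndarray]:
    """Multiplicative scatter correction.

    Each row is regressed on the reference spectrum, ``A_i ~ a_i + b_i*ref``
    (OLS), and corrected to ``(A_i - a_i) / b_i``.  Returns the corrected
    block and the reference actually used, so validation spectra can be
    corrected against the calibration reference.
    """
    X = block.absorbance
    if isinstance(reference, str):
        if reference != "mean":
            raise ParameterError(f"reference must be 'mean' or a vector, got {reference!r}")
        if X.shape[0] < 2:
            raise DegenerateDataError("MSC with reference='mean' needs at least two spectra")
        ref = X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (X.shape[1],):
            raise ParameterError("MSC reference length must equal the wavelength count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= _B_TOL:
        raise DegenerateDataError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < _B_TOL)
    if bad.size:
        raise DegenerateDataError(f"MSC slope ~ 0 for row(s) {bad.tolist()}")
    a = X.mean(axis=1) - b * ref.mean()
    corrected = (X - a[:, None]) / b[:, None]
    return block.copy_with(absorbance=corrected, step="msc"), ref


def snv(block: SpectraBlock) -> SpectraBlock:
    """Standard normal variate: per-row (A - mean) / sample s.d."""
    X = block.absorbance
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise DegenerateDataError(f"SNV undefined for constant row(s) {bad.tolist()}")
    return block.copy_with(absorbance=(X - X.mean(axis=1, keepdims=True)) / sd[:, None], step="snv")


def detrend(block: SpectraBlock, degree: int = 2) -> SpectraBlock:
    """Subtract each row's least-squares polynomial in wavelength."""
    if degree < 1:
        raise ParameterError("detrend degree must be >= 1")
    if degree >= block.n_wavelengths:
        raise ParameterError(f"degree {degree} must be < {block.n_wavelengths} wavelengths")
    # scale lambda to [-1, 1] for conditioning; the fitted subspace is identical
    lam = block.grid.values
    x = (lam - lam.mean()) / (0.5 * (lam[-1] - lam[0]))
    V = np.polynomial.polynomial.polyvander(x, degree)
    coef, *_ = np.linalg.lstsq(V, block.absorbance.T, rcond=None)
    return block.copy_with(absorbance=block.absorbance - (V @ coef).T, step=f"detrend({degree})")


def average(block: SpectraBlock, level: str) -> SpectraBlock:
    """Average absorbance rows within the acquisition hierarchy.

    ``level='scan'`` averages consecutive scans (collapses the scan index);
    ``'refill'`` additionally collapses refills; ``'replicate'`` collapses
    everything down to one mean spectrum per sample type.
    """
    if level not in AVERAGE_LEVELS:
        raise ParameterError(f"average level must be one of {AVERAGE_LEVELS}, got {level!r}")
    keys = ["variety", "robusta_fraction", "form", "replicate", "refill"]
    if level in ("refill", "replicate"):
        keys.remove("refill")
    if level == "replicate":
        keys.remove("replicate")

    meta = block.meta
    groups = meta.groupby(keys, sort=False, observed=True).indices
    rows, new_meta = [], []
    for key, idx in groups.items():
        rows.append(block.absorbance[idx].mean(axis=0))
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.setdefault("replicate", 1)
        rec.setdefault("refill", 1)
        rec["scan"] = 1
        rec["sample_id"] = f"{rec['variety']}-r{rec['replicate']}-f{rec['refill']}-avg"
        new_meta.append(rec)
    return block.copy_with(
        absorbance=np.vstack(rows),
        meta=pd.DataFrame(new_meta, columns=META_COLUMNS),
        step=f"average({level})",
    )


@dataclass
class PreprocessSpec:
    """Ordered preprocessing chain: a list of (step name, parameter dict)."""

    steps: list = field(default_factory=list)

    def __post_init__(self):
        for name, params in self.steps:
            if name not in VALID_STEPS:
                raise ParameterError(f"unknown preprocessing step {name!r}")
            if name == "savgol":
                w, p = int(params["window"]), int(params["polyorder"])
                if w % 2 == 0 or w < p + 1:
                    raise ParameterError(f"savgol window {w} must be odd and >= polyorder+1")
            if name == "average" and params.get("level") not in AVERAGE_LEVELS:
                raise ParameterError(f"average level must be one of {AVERAGE_LEVELS}")

    @classmethod
    def parse(cls, chain: str) -> "PreprocessSpec":
        """Parse a chain string like ``"truncate:1300,1600|savgol:19,2,1|snv"``."""
        steps = []
        for token in filter(None, (t.strip() for t in chain.split("|"))):
            name, _, argstr = token.partition(":")
            args = [a.strip() for a in argstr.split(",") if a.strip()] if argstr else []
            if name == "truncate":
                steps.append(("truncate", {"lo_nm": float(args[0]), "hi_nm": float(args[1])}))
            elif name == "savgol":
                w, p = int(args[0]), int(args[1])
                d = int(args[2]) if len(args) > 2 else 0
                steps.append(("savgol", {"window": w, "polyorder": p, "deriv": d}))
            elif name == "msc":
                steps.append(("msc", {}))
            elif name == "snv":
                steps.append(("snv", {}))
            elif name == "detrend":
                steps.append(("detrend", {"degree": int(args[0]) if args else 2}))
            elif name == "average":
                steps.append(("average", {"level": args[0]}))
            else:
                raise ParameterError(f"unknown preprocessing step {name!r}")
        return cls(steps)

    def describe(self) -> str:
        return " | ".join(name + (f":{params}" if params else "") for name, params in self.steps)


def apply_chain(block: SpectraBlock, spec: PreprocessSpec) -> SpectraBlock:
    """Apply the steps of ``spec`` in order (MSC reference = fit-block mean)."""
    out = block
    for name, params in spec.steps:
        if name == "truncate":
            out = truncate(out, **params)
        elif name == "savgol":
            out = savgol(out, **params)
        elif name == "msc":
            out, _ = msc(out, params.get("reference", "mean"))
        elif name == "snv":
            out = snv(out)
        elif name == "detrend":
            out = detrend(out, **params)
        elif name == "average":
            out = average(out, **params)
    return out


__all__ = [
    "truncate",
    "savgol",
    "msc",
    "snv",
    "detrend",
    "average",
    "PreprocessSpec",
    "apply_chain",
    "AVERAGE_LEVELS",
]
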