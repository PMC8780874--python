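"""Classical aquagrams: standardized absorbance at water matrix coordinates.

A water matrix coordinate (WAMAC) is a wavelength at which a specific water
molecular conformation absorbs.  The aquagram standardizes each wavelength
across *all* spectra passed in (z-score with sample s.d.), then averages the
z-values per sample group at the WAMACs — giving each group a water
absorption spectral pattern (WASP) that is displayed on a radar chart.

The normalization population is deliberately "the rows passed in": plotting
a different sample subset changes the standardization, exactly as when
different sample sets are displayed on different aquagrams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateDataError, ParameterError
from .io import SpectraBlock
from .preprocess import PreprocessSpec, apply_chain

#: Overtone display ranges (nm): first and second OH-stretch overtones.
OVERTONE_RANGES = {"first": (1300.0, 1600.0), "second": (800.0, 1100.0)}

_WAMACS = {
    # second overtone (800-1100 nm): 11 coordinates
    "second": (890, 908, 924, 946, 954, 975, 1001, 1019, 1036, 1044, 1060),
    # first overtone (1300-1600 nm): 12 coordinates
    "first": (1342, 1364, 1374, 1384, 1412, 1426, 1440, 1452, 1462, 1476, 1488, 1512),
}


def default_wamacs(overtone: str) -> list[float]:
    """The standard WAMAC wavelength list for an overtone region."""
    try:
        return [float(v) for v in _WAMACS[overtone]]
    except KeyError:
        raise ParameterError(f"unknown overtone {overtone!r}; choose 'first' or 'second'") from None


def default_preprocessing(overtone: str) -> PreprocessSpec:
    """Truncate to the overtone range, smooth (Savitzky-Golay 19/2), MSC."""
    lo, hi = OVERTONE_RANGES[overtone]
    return PreprocessSpec(
        [
            ("truncate", {"lo_nm": lo, "hi_nm": hi}),
            ("savgol", {"window": 19, "polyorder": 2, "deriv": 0}),
            ("msc", {}),
        ]
    )


@dataclass
class AquagramSpec:
    """Which overtone, which WAMACs, and the pre-chain applied first."""

    overtone: str = "second"
    wamacs_nm: list = None
    preprocessing: PreprocessSpec = None

    def __post_init__(self):
        if self.overtone not in OVERTONE_RANGES:
            raise ParameterError(f"unknown overtone {self.overtone!r}")
        if self.wamacs_nm is None:
            self.wamacs_nm = default_wamacs(self.overtone)
        lo, hi = OVERTONE_RANGES[self.overtone]
        outside = [w for w in self.wamacs_nm if not lo <= w <= hi]
        if outside:
            raise ParameterError(f"WAMAC(s) {outside} outside the {self.overtone}-overtone range")
        if self.preprocessing is None:
            self.preprocessing = default_preprocessing(self.overtone)


@dataclass
class AquagramResult:
    """Per-group standardized absorbance (z units) at the WAMACs."""

    groups: list
    wamacs_nm: list
    values: np.ndarray  # (n_groups, n_wamacs)
    n_per_group: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: group, wavelength_nm, value, n."""
        rows = [
            {"group": g, "wavelength_nm": w, "value": self.values[i, j], "n": int(self.n_per_group[i])}
            for i, g in enumerate(self.groups)
            for j, w in enumerate(self.wamacs_nm)
        ]
        return pd.DataFrame(rows)


def compute_aquagram(
    block: SpectraBlock, group_key: str = "variety", spec: AquagramSpec | None = None
) -> AquagramResult:
    """Preprocess, z-standardize each wavelength over all rows, average per group.

    WAMACs are looked up at the nearest grid point; a WAMAC that falls off
    the (possibly filter-shortened) grid raises :class:`CoverageError`.
    """
    spec = spec if spec is not None else AquagramSpec()
    if block.n_spectra < 2:
        raise DegenerateDataError("aquagram standardization needs at least two spectra")
    pre = apply_chain(block, spec.preprocessing)

    step = pre.grid.step_nm
    cols = []
    for w in spec.wamacs_nm:
        j = pre.grid.nearest_index(w)
        if abs(pre.grid.values[j] - w) > step:
            raise CoverageError(f"WAMAC {w} nm is not covered by the processed grid")
        cols.append(j)

    X = pre.absorbance[:, cols]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateDataError("zero variance at a WAMAC; cannot standardize")
    Z = (X - mu) / sd

    labels = pre.meta[group_key].to_numpy()
    groups = list(pd.unique(pd.Series(labels)))
    values = np.vstack([Z[labels == g].mean(axis=0) for g in groups])
    n_per_group = np.array([int(np.sum(labels == g)) for g in groups])
    return AquagramResult(groups=groups, wamacs_nm=list(spec.wamacs_nm), values=values, n_per_group=n_per_group)


def export_aquagram(result: AquagramResult, path, plot_path=None) -> str:
    """Write the tidy CSV; optionally render a radar chart to ``plot_path``."""
    df = result.to_frame()
    if df.empty:
        raise ParameterError("empty aquagram result")
    df.to_csv(path, index=False)
    if plot_path is not None:
        _radar_plot(result, plot_path)
    return str(path)


def _radar_plot(result: AquagramResult, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(result.wamacs_nm)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for g, row in zip(result.groups, result.values):
        closed = np.append(row, row[0])
        ax.plot(np.append(theta, theta[0]), closed, label=str(g))
    ax.set_xticks(theta)
    ax.set_xticklabels([f"{w:g}" for w in result.wamacs_nm])
    ax.set_title("Water absorption spectral pattern")
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


__all__ = [
    "OVERTONE_RANGES",
    "default_wamacs",
    "default_preprocessing",
    "AquagramSpec",
    "AquagramResult",
    "compute_aquagram",
    "export_aquagram",
]
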