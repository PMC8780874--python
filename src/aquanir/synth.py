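"""Synthetic two-endmember NIR mixture datasets.

Measured two-variety coffee datasets of this kind are rarely public, so this
module emulates their statistical structure: Beer-Lambert linear mixing of an Arabica-like and a
Robusta-like endmember, a replicate x refill x consecutive-scan acquisition
hierarchy, per-refill multiplicative/additive scatter and baseline tilt (the
artifacts that MSC/SNV/detrend are designed to remove), and i.i.d.
per-wavelength noise.

Endmembers are sums of Gaussian absorption bands.  The defaults share a
water-dominated background and differ at the bands that separate the two
varieties in the second overtone: Robusta-associated 908 and 954 nm (water
shells / weakly bound water) versus Arabica-associated 1018, 1036, 1044 and
1060 nm (water clusters with two to four hydrogen bonds and strongly
hydrogen-bonded water), plus analogous first-overtone bands, so that
qualitative aquagram behaviour is reproducible on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError
from .io import META_COLUMNS, MixtureDesign, SpectraBlock, WavelengthGrid, default_grid


@dataclass(frozen=True)
class EndmemberSpec:
    """A pure-component absorbance spectrum as Gaussian bands plus offset.

    ``peaks`` is a sequence of ``(center_nm, width_nm, height)`` triples;
    the spectrum is ``baseline + sum_k height_k * exp(-(lam-center_k)^2 /
    (2 width_k^2))``.
    """

    peaks: tuple
    baseline: float = 0.0

    def __post_init__(self):
        peaks = tuple((float(c), float(w), float(h)) for c, w, h in self.peaks)
        if any(w <= 0 for _, w, _ in peaks):
            raise ParameterError("peak widths must be positive")
        if any(h < 0 for _, _, h in peaks):
            raise ParameterError("peak heights must be non-negative")
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: per-refill scatter plus per-point detector noise.

    mult_sd : s.d. of the multiplicative gain g ~ N(1, mult_sd), per refill.
    add_offset_sd : s.d. of the additive offset o ~ N(0, .), per refill.
    tilt_sd : s.d. of the linear baseline slope t (AU per nm), per refill.
    noise_sd : s.d. of i.i.d. per-wavelength noise, per scan.
    seed : integer seed for the generator stream.
    """

    mult_sd: float = 0.0
    add_offset_sd: float = 0.0
    tilt_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.mult_sd, self.add_offset_sd, self.tilt_sd, self.noise_sd) < 0:
            raise ParameterError("noise standard deviations must be non-negative")

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=int(seed))


#: Named noise presets.  "low" keeps the per-point noise s.d. (5e-4 AU) well
#: under 1% of the ~0.1 AU endmember-difference amplitude; "realistic" is
#: strong enough that mixtures below ~2% w/w overlap with the pure Arabica
#: class, reproducing the qualitative confusion structure of a real liquid
#: experiment.
NOISE_PRESETS = {
    "none": NoiseModel(),
    "low": NoiseModel(mult_sd=0.003, add_offset_sd=0.003, tilt_sd=2e-6, noise_sd=5e-4),
    "realistic": NoiseModel(mult_sd=0.02, add_offset_sd=0.02, tilt_sd=2e-5, noise_sd=4e-3),
}


def noise_preset(name: str, seed: int = 0) -> NoiseModel:
    """Look up a preset by name and attach a seed."""
    try:
        return NOISE_PRESETS[name].with_seed(seed)
    except KeyError:
        raise ParameterError(
            f"unknown noise preset {name!r}; choose from {sorted(NOISE_PRESETS)}"
        ) from None


def default_endmembers() -> tuple[EndmemberSpec, EndmemberSpec]:
    """Default Arabica-like and Robusta-like endmember pair.

    Both share the dominant water bands (970 nm second overtone, 1450 nm
    first overtone) and a constant baseline; they differ at the
    variety-discriminating bands described in the module docstring.
    """
    shared = (
        (970.0, 35.0, 0.60),
        (1190.0, 45.0, 0.15),
        (1450.0, 50.0, 0.90),
    )
    arabica = EndmemberSpec(
        peaks=shared
        + (
            (1018.0, 12.0, 0.10),
            (1036.0, 10.0, 0.08),
            (1044.0, 10.0, 0.07),
            (1060.0, 12.0, 0.09),
            (1410.0, 14.0, 0.08),
            (1488.0, 15.0, 0.07),
        ),
        baseline=0.25,
    )
    robusta = EndmemberSpec(
        peaks=shared
        + (
            (908.0, 14.0, 0.12),
            (954.0, 12.0, 0.10),
            (1364.0, 14.0, 0.09),
            (1512.0, 16.0, 0.08),
        ),
        baseline=0.25,
    )
    return arabica, robusta


def endmember_spectrum(spec: EndmemberSpec, grid: WavelengthGrid) -> np.ndarray:
    """Evaluate an endmember's clean absorbance on a grid (deterministic)."""
    lam = grid.values
    out = np.full(lam.shape, float(spec.baseline))
    for center, width, height in spec.peaks:
        out += height * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
    return out


def default_mixture_design(form: str = "liquid") -> MixtureDesign:
    """Default design: 8 mixture levels, 2 pure controls, 2 marketed blends.

    Liquid samples use a 3 replicate x 3 refill x 3 scan hierarchy (324
    spectra in total); ground coffee is not refilled (refills = 1, 108
    spectra).
    """
    levels = (0.5, 1, 2, 3, 5, 10, 20, 35)
    blends = (("B10", 10.0), ("B30", 30.0))
    if form == "liquid":
        return MixtureDesign(levels=levels, blends=blends, n_replicates=3, n_refills=3, n_scans=3)
    if form == "ground":
        return MixtureDesign(levels=levels, blends=blends, n_replicates=3, n_refills=1, n_scans=3)
    raise ParameterError(f"unknown form {form!r}; choose 'liquid' or 'ground'")


def sample_type_table(design: MixtureDesign) -> list[tuple[str, float, str]]:
    """(variety label, fraction % w/w, kind) per sample type, in design order.

    Controls are labelled ARA3 (0%) and ROB3 (100%); lab mixtures MIX<f>;
    blends keep their given labels.
    """
    rows = []
    for f in design.controls:
        label = "ARA3" if f == 0.0 else "ROB3" if f == 100.0 else f"CTRL{f:g}"
        rows.append((label, f, "control"))
    for f in design.levels:
        rows.append((f"MIX{f:g}", f, "mixture"))
    for label, f in design.blends:
        rows.append((label, f, "blend"))
    return rows


def mixture_spectrum(
    arabica: np.ndarray, robusta: np.ndarray, fraction_pct: float
) -> np.ndarray:
    """Beer-Lambert linear mix: (1 - f/100) * A_ara + (f/100) * A_rob."""
    if not 0.0 <= fraction_pct <= 100.0:
        raise DimensionError(f"fraction {fraction_pct} % w/w outside [0, 100]")
    p = fraction_pct / 100.0
    return (1.0 - p) * arabica + p * robusta


def perturb_endmember(spec: EndmemberSpec, rel: float, rng: np.random.Generator) -> EndmemberSpec:
    """Jitter peak heights (relative) and centers (+- rel*10 nm).

    Used to give marketed blends endmembers of a different provenance than
    the calibration pair, so that external-test error exceeds CV error.
    """
    peaks = tuple(
        (
            c + rng.normal(0.0, rel * 10.0),
            w,
            max(h * (1.0 + rng.normal(0.0, rel)), 0.0),
        )
        for c, w, h in spec.peaks
    )
    return EndmemberSpec(peaks=peaks, baseline=spec.baseline * (1.0 + rng.normal(0.0, rel)))


def generate_mixture_dataset(
    arabica: EndmemberSpec,
    robusta: EndmemberSpec,
    design: MixtureDesign,
    noise: NoiseModel,
    grid: WavelengthGrid | None = None,
    form: str = "liquid",
    blend_endmembers: tuple[EndmemberSpec, EndmemberSpec] | None = None,
) -> SpectraBlock:
    """Simulate a full mixture experiment.

    Each emitted spectrum is ``g * A_f + o + t * (lam - lam_mid) + eps`` with
    the scatter triple (g, o, t) drawn once per (sample type, replicate,
    refill) — consecutive scans of one refill share the physical sample
    presentation — and eps i.i.d. per wavelength per scan.  Bit-reproducible
    for a fixed ``noise.seed``.

    ``blend_endmembers``, when given, replaces the endmember pair for blend
    sample types only (marketed blends of different provenance).
    """
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed))
    lam = grid.values
    lam_c = lam - 0.5 * (lam[0] + lam[-1])

    a_spec = endmember_spectrum(arabica, grid)
    r_spec = endmember_spectrum(robusta, grid)
    if blend_endmembers is not None:
        ba_spec = endmember_spectrum(blend_endmembers[0], grid)
        br_spec = endmember_spectrum(blend_endmembers[1], grid)
    else:
        ba_spec, br_spec = a_spec, r_spec

    rows, meta = [], []
    for label, fraction, kind in sample_type_table(design):
        if kind == "blend":
            clean = mixture_spectrum(ba_spec, br_spec, fraction)
        else:
            clean = mixture_spectrum(a_spec, r_spec, fraction)
        for rep in range(1, design.n_replicates + 1):
            for refill in range(1, design.n_refills + 1):
                g = rng.normal(1.0, noise.mult_sd)
                o = rng.normal(0.0, noise.add_offset_sd)
                t = rng.normal(0.0, noise.tilt_sd)
                base = g * clean + o + t * lam_c
                for scan in range(1, design.n_scans + 1):
                    eps = rng.normal(0.0, noise.noise_sd, size=lam.size) if noise.noise_sd > 0 else 0.0
                    rows.append(base + eps)
                    meta.append(
                        {
                            "sample_id": f"{label}-r{rep}-f{refill}-s{scan}",
                            "variety": label,
                            "robusta_fraction": fraction,
                            "form": form,
                            "replicate": rep,
                            "refill": refill,
                            "scan": scan,
                        }
                    )
    block = SpectraBlock(
        grid=grid,
        absorbance=np.vstack(rows),
        meta=pd.DataFrame(meta, columns=META_COLUMNS),
        provenance=[f"synthetic(seed={noise.seed}, form={form})"],
    )
    assert block.n_spectra == design.total_spectra
    return block


__all__ = [
    "EndmemberSpec",
    "NoiseModel",
    "NOISE_PRESETS",
    "noise_preset",
    "default_endmembers",
    "endmember_spectrum",
    "default_mixture_design",
    "sample_type_table",
    "mixture_spectrum",
    "perturb_endmember",
    "generate_mixture_dataset",
]
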