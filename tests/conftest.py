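import numpy as np
import pandas as pd
import pytest

from aquanir.io import META_COLUMNS, SpectraBlock, WavelengthGrid


def make_meta(n, variety="S", fraction=0.0, form="liquid", replicate=None, refill=None, scan=None):
    """Minimal valid metadata frame; hierarchy indices default to row order."""
    rows = []
    for i in range(n):
        rep = replicate[i] if replicate is not None else i + 1
        ref = refill[i] if refill is not None else 1
        sc = scan[i] if scan is not None else 1
        var = variety if isinstance(variety, str) else variety[i]
        frac = fraction if np.isscalar(fraction) else fraction[i]
        rows.append(
            {
                "sample_id": f"{var}-r{rep}-f{ref}-s{sc}-{i}",
                "variety": var,
                "robusta_fraction": float(frac),
                "form": form,
                "replicate": int(rep),
                "refill": int(ref),
                "scan": int(sc),
            }
        )
    return pd.DataFrame(rows, columns=META_COLUMNS)


def make_block(absorbance, start_nm=1300.0, step_nm=2.0, **meta_kwargs):
    """SpectraBlock on an evenly spaced grid starting at ``start_nm``."""
    absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n, p = absorbance.shape
    grid = WavelengthGrid(start_nm + step_nm * np.arange(p))
    return SpectraBlock(grid=grid, absorbance=absorbance, meta=make_meta(n, **meta_kwargs))


def random_block(rng, n, p, scale=1.0, **meta_kwargs):
    return make_block(scale * rng.standard_normal((n, p)), **meta_kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
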