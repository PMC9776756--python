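import numpy as np
import pandas as pd
import pytest

from rdeep.fitting import MixtureFit
from rdeep.simulate import FRACTIONS, GaussianPeak, gaussian_curve


def make_fit(peaks, protein_id="P", condition="CTRL", qc=True):
    """Assemble a MixtureFit directly from known peaks (fixture helper)."""
    curve = gaussian_curve(peaks, FRACTIONS)
    return MixtureFit(protein_id, condition, sorted(peaks, key=lambda p: p.position),
                      1.0, qc, curve)


def replicate_curves(curve, jitter=0.0, n=3, seed=0):
    """Stack n replicate copies of a curve with optional deterministic jitter."""
    rng = np.random.default_rng(seed)
    reps = np.tile(np.asarray(curve, dtype=float), (n, 1))
    if jitter:
        reps = reps + rng.normal(0.0, jitter, size=reps.shape)
    return np.clip(reps, 0.0, None)


def peak_with_grid_area(area, position, width):
    """A Gaussian peak whose area on the 1..25 grid equals `area`."""
    unit = GaussianPeak(1.0, position, width)
    return GaussianPeak(area / unit.grid_area(), position, width)


@pytest.fixture
def small_screen():
    """Deterministic 1-protein x 2-condition x 3-replicate long table."""
    rows = []
    base = gaussian_curve([GaussianPeak(10.0, 12.0, 1.5)], FRACTIONS)
    for cond, shiftpos in (("CTRL", 0), ("RNASE", 0)):
        for rep in (1, 2, 3):
            for f, v in zip(FRACTIONS, base):
                rows.append(("P1", cond, rep, int(f), float(v)))
    return pd.DataFrame(rows, columns=["protein_id", "condition", "replicate", "fraction", "intensity"])
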