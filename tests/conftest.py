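import numpy as np
import pandas as pd
import pytest

from gbmsynergy.dose_response import EffectVector
from gbmsynergy.simulate import SimulationConfig, default_panel_truth


@pytest.fixture(scope="session")
def panel_truth():
    return default_panel_truth()


@pytest.fixture
def noiseless_config():
    return SimulationConfig(seed=0, noise_cv=0.0)


def median_effect_vector(m, Dm, doses):
    """Noiseless fraction-affected vector on the exact median-effect curve."""
    doses = np.asarray(doses, dtype=float)
    ratio = (doses / Dm) ** m
    return EffectVector(doses=doses, fa=ratio / (1 + ratio),
                        n_reps=np.full(doses.size, 1))


@pytest.fixture
def plate_records():
    """Tiny long-format plate table: one model, one agent, with controls."""
    rows = []
    for r, lum in enumerate([200.0, 198.0, 202.0], start=1):
        rows.append(("M1", "control", 0.0, lum, r))
    for dose, lum in [(0.1, 180.0), (1.0, 100.0), (10.0, 20.0)]:
        for r in (1, 2):
            rows.append(("M1", "drugA", dose, lum, r))
    df = pd.DataFrame(
        rows, columns=["model_id", "agent", "dose_uM", "luminescence", "replicate"]
    )
    df["dose2_uM"] = 0.0
    return df
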