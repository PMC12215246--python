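import numpy as np
import pandas as pd
import pytest

from methrhythm import (
    MethylationMatrix,
    PlantedTruthConfig,
    StudyDesign,
    generate_methylation,
)
from methrhythm import preprocess as pp


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def default_dataset():
    """A modest default-condition dataset shared across read-only tests."""
    return generate_methylation(n_probes=300, seed=101, missing_rate=0.03)


@pytest.fixture(scope="session")
def strong_dataset():
    """High signal-to-noise (A/sigma = 5), no drift: clean rhythm classes."""
    cfg = PlantedTruthConfig(
        amplitude=1.0,
        noise_sd=0.2,
        noise_sd_spread=0.0,
        drift_fraction=0.0,
        class_proportions={
            "arrhy": 0.2, "same": 0.2, "loss": 0.2, "gain": 0.2, "change": 0.2
        },
    )
    return generate_methylation(
        truth_config=cfg, n_probes=500, seed=202, cellcounts=False
    )


@pytest.fixture(scope="session")
def strong_windows(strong_dataset):
    base, sd = pp.split_conditions(
        strong_dataset.m_values, strong_dataset.sample_sheet
    )
    base_z, _ = pp.zscore_per_probe(base)
    sd_z, _ = pp.zscore_per_probe(sd)
    return base_z, sd_z


def toy_matrix(values, scale=pp.MSCALE, sheet=None, probe_prefix="p"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = [f"{probe_prefix}{i}" for i in range(values.shape[0])]
    samples = (
        list(sheet.index)
        if sheet is not None
        else [f"s{j}" for j in range(values.shape[1])]
    )
    frame = pd.DataFrame(values, index=probes, columns=samples)
    return MethylationMatrix(frame, scale, sheet)
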