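"""Shared fixtures: small simulated experiments and a hand-built QC fixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hzemeth.config import SimulationConfig
from hzemeth.preprocess import IntensityMatrix
from hzemeth import simulate


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_probes=1200, n_dose_probes=60, n_drift_probes=60)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """Sheet, probes, annotation, intensities and truth for a 1200-probe run."""
    sheet = simulate.generate_sample_sheet(small_config)
    probes, annotation = simulate.generate_probe_annotation(small_config)
    intensities, truth = simulate.generate_intensities(small_config, sheet, probes)
    return {
        "config": small_config,
        "sheet": sheet,
        "probes": probes,
        "annotation": annotation,
        "intensities": intensities,
        "truth": truth,
    }


def build_qc_fixture():
    """50 probes x 10 samples with hand-planted QC defects.

    - probes p0..p6 fail detection in 2 of 10 samples (20% missing -> dropped)
    - probe p7 fails detection in exactly 1 of 10 samples (10% -> retained)
    - sample s9 has average intensity 40% of the experiment median
      (excluded by the median rule; still above the 2000 AU absolute floor)
    - sample s8 has detection call rate 0.90 (excluded by the call-rate rule)
    """
    rng = np.random.default_rng(42)
    probes = [f"p{i}" for i in range(50)]
    samples = [f"s{i}" for i in range(10)]
    M = pd.DataFrame(rng.uniform(8000, 12000, (50, 10)), index=probes, columns=samples)
    U = pd.DataFrame(rng.uniform(8000, 12000, (50, 10)), index=probes, columns=samples)
    detection = pd.DataFrame(np.zeros((50, 10)), index=probes, columns=samples)
    for i in range(7):  # 20% missing
        detection.iloc[i, [0, 1]] = 0.5
    detection.iloc[7, 2] = 0.5  # exactly 10% missing
    detection.loc[[f"p{i}" for i in range(10, 15)], "s8"] = 0.5  # call rate 45/50 = 0.90
    M["s9"] *= 0.4
    U["s9"] *= 0.4
    return IntensityMatrix(M=M, U=U, detection_p=detection)


@pytest.fixture
def qc_fixture():
    return build_qc_fixture()
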