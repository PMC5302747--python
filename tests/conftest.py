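import numpy as np
import pandas as pd
import pytest

from radmarkers.containers import LabeledMatrix
from radmarkers.simulate import (
    DigeSimConfig,
    MarkerSpec,
    PeakSpec,
    SeldiSimConfig,
    generate_dige_dataset,
    generate_seldi_spectra,
)

MARKER_IDX = [0, 40, 80, 120, 160]


def tiny_matrix(values, doses, day=3, qc_flags=None):
    """Hand-built LabeledMatrix for arithmetic oracles."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    qc_flags = qc_flags or [False] * n
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "dose_gy": [float(d) for d in doses],
            "day": [day] * n,
            "batch": [1] * n,
            "is_qc_pool": qc_flags,
        }
    )
    return LabeledMatrix(values, [f"f{j}" for j in range(values.shape[1])], meta)


@pytest.fixture(scope="session")
def null_dige():
    """A no-effect 200-feature dataset, 8 animals per dose group."""
    return generate_dige_dataset(DigeSimConfig(n_features=200, n_per_group=8, seed=11), 3)


@pytest.fixture(scope="session")
def planted_dige():
    """941 features, 16/group, five exposure markers at linear fold 1.5."""
    markers = [MarkerSpec(j, "exposure", 1.5) for j in [0, 188, 376, 564, 752]]
    cfg = DigeSimConfig(n_features=941, n_per_group=16, markers=markers, seed=7)
    return generate_dige_dataset(cfg, 3), [0, 188, 376, 564, 752]


@pytest.fixture(scope="session")
def small_spectra():
    """Three well-separated peaks, 6 samples + 4 QC replicates."""
    peaks = [
        PeakSpec(3000.0, 80.0, 0.2),
        PeakSpec(5000.0, 50.0, 0.2),
        PeakSpec(8000.0, 120.0, 0.2),
    ]
    cfg = SeldiSimConfig(
        true_peaks=peaks, grid_points=3000, n_per_group=2, n_qc_replicates=4,
        noise_sd=1.0, mass_jitter_frac=0.001, seed=5,
    )
    return generate_seldi_spectra(cfg)
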