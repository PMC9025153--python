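"""Shared fixtures: the default synthetic-mirror run and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from imsferm.pipeline import RunConfig, run_pipeline
from imsferm.preprocess import GCIMSSpectrum


@pytest.fixture(scope="session")
def default_run():
    """One full default-configuration pipeline run, shared across tests.

    16 samples per class, 5 classes, duplicate measurements, PCA/NNMF with
    four components fitted on the stratified training split.
    """
    manifest, artifacts = run_pipeline(RunConfig())
    return manifest, artifacts


def make_gaussian_spectrum(
    amplitude: float = 100.0,
    rt_center: float = 50.0,
    rt_sigma: float = 5.0,
    dt_center: float = 2.5,
    dt_sigma: float = 0.05,
    rt_axis: np.ndarray | None = None,
    dt_axis: np.ndarray | None = None,
    pedestal: float = 0.0,
    sample_id: str = "s1",
) -> GCIMSSpectrum:
    """A single symmetric 2-D Gaussian peak on an optionally raised floor."""
    rt = rt_axis if rt_axis is not None else np.arange(0.0, 100.0, 1.0)
    dt = dt_axis if dt_axis is not None else np.arange(2.0, 3.0, 0.01)
    peak = amplitude * np.outer(
        np.exp(-0.5 * ((rt - rt_center) / rt_sigma) ** 2),
        np.exp(-0.5 * ((dt - dt_center) / dt_sigma) ** 2),
    )
    return GCIMSSpectrum(
        sample_id=sample_id,
        replicate_id="a",
        intensity=peak + pedestal,
        retention_axis=rt,
        drift_axis=dt,
    )
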