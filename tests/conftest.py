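"""Shared fixtures: synthetic datasets and pipeline runs reused across tests.

The two full pipeline runs (noisy and noiseless study-shaped datasets) are
session-scoped because they are the expensive fixtures; everything that
needs an end-to-end result shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from capsulecalib import OpticsParams, ScenarioSpec, generate_dataset
from capsulecalib.pipeline import PipelineConfig, run_pipeline

#: root seed for all session fixtures
SEED = 42


def make_disc_image(
    shape=(128, 128),
    centre=(64, 64),
    radius=40,
    disc_rgb=(120, 110, 100),
    bg_rgb=(220, 218, 216),
):
    """Uniform disc on a uniform brighter background (no noise)."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    mask = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.array(bg_rgb, dtype=np.uint8)
    img[mask] = np.array(disc_rgb, dtype=np.uint8)
    return img, mask


def _dataset_with_measurements(tmp_path, spec, optics):
    """Generate a dataset and write its ground truth as the measurements table."""
    manifest, truth = generate_dataset(spec, optics, tmp_path)
    meas = truth.rename(columns={"h_true_um": "h_um"})
    meas_path = tmp_path / "measurements.csv"
    meas.to_csv(meas_path, index=False)
    return {
        "dir": tmp_path,
        "manifest": tmp_path / "manifest.csv",
        "measurements": meas_path,
        "truth": truth,
        "spec": spec,
        "optics": optics,
    }


@pytest.fixture(scope="session")
def noisy_dataset(tmp_path_factory):
    """Study-shaped dataset at the default noise level (sigma = 2)."""
    tmp = tmp_path_factory.mktemp("noisy_ds")
    return _dataset_with_measurements(
        tmp, ScenarioSpec(seed=SEED), OpticsParams(noise_sigma=2.0)
    )


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """Same scenario rendered without noise."""
    tmp = tmp_path_factory.mktemp("noiseless_ds")
    return _dataset_with_measurements(
        tmp, ScenarioSpec(seed=SEED), OpticsParams(noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def noisy_report(noisy_dataset):
    return run_pipeline(
        noisy_dataset["manifest"], noisy_dataset["measurements"], PipelineConfig()
    )


@pytest.fixture(scope="session")
def noiseless_report(noiseless_dataset):
    return run_pipeline(
        noiseless_dataset["manifest"], noiseless_dataset["measurements"], PipelineConfig()
    )
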