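import numpy as np
import pytest

from sccmsi import preprocess as pp
from sccmsi.synthetic import SyntheticConfig, generate_cohort, generate_dataset
from sccmsi.workflow import RunConfig, analyze_cohort


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    """The study conditions: 10 datasets, 32x32 grid, 200 peaks, effect 1.0."""
    return RunConfig(log_level="WARNING")


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config.n_datasets, default_config.synthetic)


@pytest.fixture(scope="session")
def study(default_config, default_cohort):
    """Full pipeline run on the default synthetic cohort (shared across tests)."""
    pairs = [(ds, mask) for ds, mask, _ in default_cohort]
    return analyze_cohort(pairs, default_config)


@pytest.fixture(scope="session")
def small():
    """One default-condition dataset with its mask and ground truth."""
    return generate_dataset(SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def small_processed(small):
    """Recalibrated small dataset with tissue flags, peaks and features."""
    ds, _mask, _truth = small
    flags = pp.detect_tissue_pixels(ds)
    model = pp.fit_recalibration(ds)
    cal = pp.apply_recalibration(ds, model)
    axis, mean = pp.mean_spectrum(cal, flags)
    smoothed = pp.smooth_spectrum(mean)
    peaks = pp.pick_peaks(axis, smoothed)
    feats = pp.extract_features(cal, peaks)
    feats.tissue_flags = flags
    return {
        "cal": cal,
        "flags": flags,
        "model": model,
        "axis": axis,
        "mean": mean,
        "smoothed": smoothed,
        "peaks": peaks,
        "features": feats,
    }


def nearest_ppm(mzs: np.ndarray, target: float) -> float:
    """Helper: |ppm| distance from target to the nearest entry of mzs."""
    mzs = np.asarray(mzs, float)
    if len(mzs) == 0:
        return np.inf
    return float(np.min(np.abs(mzs - target)) / target * 1e6)
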