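import numpy as np
import pytest

import fetaldelta as fd


@pytest.fixture(scope="session")
def protocol():
    return fd.make_protocol()


@pytest.fixture(scope="session")
def reference_table():
    return fd.load_reference_table()


@pytest.fixture(scope="session")
def default_record(protocol):
    """One simulated subject with a known decompensation time."""
    subj = fd.SubjectParams(decomp_time=11000.0, rng_seed=42)
    return fd.simulate_beats(protocol, subj), subj


@pytest.fixture(scope="session")
def baseline_record():
    """A stationary baseline-only tachogram (full record length)."""
    subj = fd.SubjectParams(rng_seed=7)
    return fd.simulate_baseline(19800.0, subj), subj


@pytest.fixture(scope="session")
def default_series(default_record):
    beats, _ = default_record
    quality = fd.assess_quality(beats)
    return fd.rmssd_series(beats, quality)


def stationary_gp_series(seed: int, n_windows: int = 131,
                         sf2: float = 0.09, ell: float = 3.0,
                         sn2: float = 0.02, mean: float = 3.0) -> fd.RMSSDSeries:
    """Window-level stationary series drawn from a known GP (test helper)."""
    from scipy.linalg import cholesky
    rng = np.random.default_rng(seed)
    x = np.arange(float(n_windows))
    K = sf2 * np.exp(-0.5 * (x[:, None] - x[None, :]) ** 2 / ell ** 2) \
        + sn2 * np.eye(n_windows)
    y = mean + cholesky(K + 1e-10 * np.eye(n_windows), lower=True) @ rng.normal(
        0.0, 1.0, n_windows)
    centers = 150.0 + 150.0 * np.arange(n_windows)
    return fd.RMSSDSeries(centers, y, "beat_exact", np.ones(n_windows, bool))
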