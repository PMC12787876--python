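import numpy as np
import pytest

from facecadence import CorrectionModel, TraceSpec, generate_trace


@pytest.fixture
def stated_model() -> CorrectionModel:
    """The global bias-correction model shipped as the default."""
    return CorrectionModel(slope=0.83, intercept=13.70)


@pytest.fixture
def bin_center_trace():
    """Noise-free, drift-free trace oscillating exactly at FFT bin 10.

    Bin 10 of a 128-sample window at 30 Hz is 10/(128/30) Hz, i.e.
    140.625 steps/min — the raw estimator must recover it exactly.
    """
    spec = TraceSpec(
        true_cadence=140.625,
        noise_sd=0.0,
        drift_slope=0.0,
        drift_sine_amplitude=0.0,
        seed=7,
    )
    return generate_trace(spec)


def naive_dft(x: np.ndarray) -> np.ndarray:
    """O(n^2) direct-summation DFT oracle."""
    x = np.asarray(x, dtype=complex)
    n = x.size
    k = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(k, k) / n) @ x
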