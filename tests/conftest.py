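import numpy as np
import pytest

from gaitstride import WalkConfig, build_template, generate_walk
from gaitstride.sdatw import extract_stride_signals


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free constant-cadence walk used across modules."""
    return generate_walk(WalkConfig(n_strides=20, cadence_hz=0.9, noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def template(clean_walk):
    sigs = extract_stride_signals(clean_walk.recording, clean_walk.truth.strides)
    return build_template(sigs)


@pytest.fixture()
def recording_csv(tmp_path, clean_walk):
    from gaitstride import save_recording

    path = tmp_path / "rec.csv"
    save_recording(clean_walk.recording, path)
    return path


def make_recording(accel_sagittal=None, accel_vertical=None, accel_coronal=None,
                   gyro_coronal=None, n=None, fs=100.0):
    """Hand-built recording where unspecified channels are zero."""
    from gaitstride import ImuRecording

    parts = [p for p in (accel_sagittal, accel_vertical, accel_coronal, gyro_coronal)
             if p is not None]
    if n is None:
        n = len(parts[0])
    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    if accel_coronal is not None:
        accel[:, 0] = accel_coronal
    if accel_sagittal is not None:
        accel[:, 1] = accel_sagittal
    if accel_vertical is not None:
        accel[:, 2] = accel_vertical
    if gyro_coronal is not None:
        gyro[:, 0] = gyro_coronal
    return ImuRecording(
        sample_rate_hz=fs,
        timestamps=np.arange(n) / fs,
        accel=accel,
        gyro=gyro,
        channel_map={
            "accel": {"coronal": 0, "sagittal": 1, "vertical": 2},
            "gyro": {"coronal": 0, "sagittal": 1, "vertical": 2},
        },
    )
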