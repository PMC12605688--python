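import numpy as np
import pandas as pd
import pytest

from pepflow.icg import detect_c_points
from pepflow.io import preprocess_dzdt, preprocess_ecg
from pepflow.segmentation import detect_r_peaks, partition_cycles
from pepflow.synthetic import SynthConfig, synth_recording


class Prepared:
    """A synthetic recording taken through preprocessing + segmentation,
    with ground truth aligned to the detected cycles."""

    def __init__(self, config: SynthConfig):
        self.config = config
        self.recording, self.truth, self.annotations = synth_recording(config)
        fs = self.recording.fs
        self.ecg = preprocess_ecg(self.recording.ecg, fs)
        self.dzdt = preprocess_dzdt(self.recording.dzdt, fs)
        r = detect_r_peaks(self.ecg, fs)
        self.partition = partition_cycles(r, fs, n_samples=self.recording.n_samples)
        self.cpoints = detect_c_points(self.dzdt, self.partition, fs)
        # align truth rows to detected cycles via the R-peak
        truth_by_r = self.truth.set_index("r_peak")
        rows = []
        for r_det in self.partition["r_peak"]:
            near = truth_by_r.index[np.abs(truth_by_r.index - r_det) <= 10]
            rows.append(truth_by_r.loc[near[0]] if len(near) else pd.Series(dtype=float))
        self.truth_aligned = pd.DataFrame(rows).reset_index(drop=True)
        self.fs = fs


@pytest.fixture(scope="session")
def notch_train():
    """~30 s clean notch-morphology train at 1000 Hz, PEP 100 ms."""
    return Prepared(SynthConfig(duration_s=30.0, seed=7))


@pytest.fixture(scope="session")
def featureless_train():
    return Prepared(SynthConfig(duration_s=30.0, b_morphology="featureless", seed=7))


@pytest.fixture(scope="session")
def long_notch_train():
    """>=120-beat clean notch train (fs 1000, HR 60, PEP 100 ms)."""
    return Prepared(SynthConfig(duration_s=122.0, seed=11))
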