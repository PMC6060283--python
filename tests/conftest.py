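import struct

import numpy as np
import pytest

from pesp.dataset_builder import SplitSpec
from pesp.synthetic_data import default_patient


@pytest.fixture(scope="session")
def small_patient():
    """Scaled-down 3-seizure synthetic patient shared across tests.

    30-min seizure recordings (onset at 25 min), a 30-min interictal
    recording, 20-min preictal horizon: the same regime structure as
    the full-scale default at a fraction of the compute.
    """
    return default_patient(
        seed=3, record_hours=0.5, onset_min=25.0, interictal_hours=0.5, preictal_len_min=20.0
    )


@pytest.fixture(scope="session")
def small_split():
    return SplitSpec(preictal_horizon=20.0, exclusion_margin=2.0)


def write_minimal_edf(path, signal_uv: np.ndarray, fs: int, ch_names):
    """Write a bare-bones EDF file (1-s data records, int16 samples).

    Synthetic fixture writer for exercising the EDF *reader*; physical
    range is +/-1000 uV, so the roundtrip is exact to ~0.03 uV.
    """
    n_ch, n_samp = signal_uv.shape
    assert n_samp % fs == 0, "need a whole number of 1-s records"
    n_rec = n_samp // fs

    def pad(value, width):
        s = str(value)
        assert len(s) <= width
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            pad(0, 8),
            pad("synthetic", 80),
            pad("synthetic fixture", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (n_ch + 1), 8),
            pad("", 44),
            pad(n_rec, 8),
            pad(1, 8),
            pad(n_ch, 4),
        ]
    )
    fields = [
        (16, list(ch_names)),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [-1000] * n_ch),
        (8, [1000] * n_ch),
        (8, [-32768] * n_ch),
        (8, [32767] * n_ch),
        (80, [""] * n_ch),
        (8, [fs] * n_ch),
        (32, [""] * n_ch),
    ]
    for width, values in fields:
        header += b"".join(pad(v, width) for v in values)

    scale = 32767.0 / 1000.0
    digital = np.clip(np.round(signal_uv * scale), -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * fs : (r + 1) * fs].tobytes())
    return path
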