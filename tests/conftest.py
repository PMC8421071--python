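import struct

import numpy as np
import pytest

from titerflow import ChannelMap, EventTable, SampleMeta


@pytest.fixture
def cmap():
    return ChannelMap()


@pytest.fixture
def make_table():
    """Factory for small event tables with the standard channel layout."""

    def _make(n=100, seed=0, channels=("FSC-A", "FSC-W", "SSC-H", "FL1"),
              meta=None):
        rng = np.random.default_rng(seed)
        events = rng.lognormal(5.0, 0.4, size=(n, len(channels)))
        return EventTable(events, channels, meta or SampleMeta())

    return _make


def write_minimal_fcs(path, data: np.ndarray, names, version=b"FCS3.0",
                      extra_text=()):
    """Write a minimal list-mode FCS 3.0/3.1 file ($DATATYPE=F, little-endian).

    Test-only helper, deliberately independent of the package's FCS reader.
    """
    n_tot, n_par = data.shape
    delim = "/"
    kv = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    kv.update(dict(extra_text))

    payload = data.astype("<f4").tobytes()
    # iterate: text length depends on the data offsets written inside it
    data_begin = 256
    for _ in range(3):
        kv["$BEGINDATA"] = str(data_begin)
        kv["$ENDDATA"] = str(data_begin + len(payload) - 1)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
        text_begin = 58
        text_end = text_begin + len(text) - 1
        new_begin = ((text_end + 16) // 8 + 1) * 8
        if new_begin == data_begin:
            break
        data_begin = new_begin
    header = (version.ljust(10) +
              f"{text_begin:>8d}{text_end:>8d}".encode() +
              f"{data_begin:>8d}{data_begin + len(payload) - 1:>8d}".encode() +
              b" " * 16)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_begin - len(header)))
        fh.write(text.encode("latin-1"))
        fh.write(b" " * (data_begin - text_end - 1))
        fh.write(payload)
    return path


@pytest.fixture
def fcs_writer():
    return write_minimal_fcs
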