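"""Shared fixtures: tiny event tables and a minimal FCS fixture writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from cytoval.cytometry_io import ChannelDef, EventTable
from cytoval.synthetic import SyntheticSampleSpec, default_populations, generate_sample


def write_fcs_fixture(
    path: Path,
    events: np.ndarray,
    names: list[str],
    datatype: str = "F",
    version: str = "FCS3.0",
) -> None:
    """Write a minimal list-mode FCS file for read-path tests."""
    events = np.asarray(events)
    n, k = events.shape if events.size else (0, len(names))
    delim = b"/"
    if datatype == "F":
        payload = events.astype("<f4").tobytes()
        bits = 32
    elif datatype == "D":
        payload = events.astype("<f8").tobytes()
        bits = 64
    elif datatype == "I":
        payload = events.astype("<u4").tobytes()
        bits = 32
    else:
        raise ValueError(datatype)

    def compose(begin: int, end: int) -> bytes:
        pairs = [
            ("$PAR", str(k)),
            ("$TOT", str(n)),
            ("$DATATYPE", datatype),
            ("$BYTEORD", "1,2,3,4"),
            ("$MODE", "L"),
            ("$BEGINDATA", str(begin).rjust(10, "0")),
            ("$ENDDATA", str(end).rjust(10, "0")),
        ]
        for p, name in enumerate(names, start=1):
            pairs += [(f"$P{p}N", name), (f"$P{p}B", str(bits)), (f"$P{p}E", "0,0")]
        body = b"".join(
            key.encode() + delim + val.encode() + delim for key, val in pairs
        )
        return delim + body

    text_start = 58
    # the padded $BEGINDATA/$ENDDATA keep the TEXT length fixed across passes
    text = compose(0, 0)
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + max(len(payload) - 1, 0)
    text = compose(data_start, data_end)
    assert text_start + len(text) - 1 == text_end

    header = version.encode() + b" " * 4
    header += str(text_start).rjust(8).encode()
    header += str(text_end).rjust(8).encode()
    header += b"0".rjust(8) * 2  # data offsets via $BEGINDATA/$ENDDATA
    header += b"0".rjust(8) * 2  # no ANALYSIS segment
    path.write_bytes(header + text + payload)


@pytest.fixture
def tiny_table() -> EventTable:
    channels = [
        ChannelDef("FSC-A", "FSC-A"),
        ChannelDef("FSC-H", "FSC-H"),
        ChannelDef("FL1-A", "fluorescence"),
    ]
    events = np.array(
        [[100.0, 100.0, 10.0], [200.0, 190.0, 20.0], [150.0, 150.0, 30.0]]
    )
    return EventTable(events=events, channels=channels, meta={"condition": "stained"})


@pytest.fixture(scope="session")
def standard_sample():
    """One 20,000-event mixture sample with ground truth (session cached)."""
    spec = SyntheticSampleSpec(populations=default_populations(25_000.0))
    return generate_sample(spec, seed=20260928)
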