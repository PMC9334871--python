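"""Event-table I/O round trips and compensation contracts."""

from __future__ import annotations

import numpy as np
import pytest

from cytoval.cytometry_io import (
    ChannelDef,
    EventTable,
    SpilloverMatrix,
    compensate,
    infer_role,
    read_event_csv,
    read_fcs,
    write_event_csv,
)
from cytoval.errors import FormatError, MappingError, SpecError
from cytoval.synthetic import SyntheticSampleSpec, default_populations, generate_sample

from .conftest import write_fcs_fixture

NAMES = ["FSC-A", "FSC-H", "FSC-Width", "SSC-A", "FL1-A"]


def test_fcs_round_trip_float(tmp_path):
    rng = np.random.default_rng(0)
    events = rng.uniform(0, 1e5, size=(100, 5)).astype(np.float32)
    path = tmp_path / "fix.fcs"
    write_fcs_fixture(path, events, NAMES)
    table = read_fcs(path)
    assert table.n_events == 100
    assert table.channel_names == NAMES
    np.testing.assert_array_equal(table.events, events.astype(float))
    # exporting to CSV and re-reading keeps the event matrix identical
    csv = tmp_path / "fix.csv"
    write_event_csv(table, csv)
    again = read_event_csv(csv)
    np.testing.assert_array_equal(again.events, table.events)
    assert [c.role for c in again.channels] == [c.role for c in table.channels]


@pytest.mark.parametrize("datatype", ["D", "I"])
def test_fcs_other_datatypes(tmp_path, datatype):
    events = np.arange(20, dtype=float).reshape(4, 5) * 7
    path = tmp_path / "fix.fcs"
    write_fcs_fixture(path, events, NAMES, datatype=datatype)
    table = read_fcs(path)
    np.testing.assert_array_equal(table.events, events)


def test_fcs_empty_event_segment_rejected(tmp_path):
    path = tmp_path / "empty.fcs"
    write_fcs_fixture(path, np.empty((0, 5)), NAMES)
    with pytest.raises(FormatError, match="empty event segment"):
        read_fcs(path)


def test_fcs_truncated_and_bad_version(tmp_path):
    path = tmp_path / "trunc.fcs"
    write_fcs_fixture(path, np.ones((10, 5)), NAMES)
    blob = path.read_bytes()
    path.write_bytes(blob[:-40])  # chop the DATA segment
    with pytest.raises(FormatError, match="DATA segment"):
        read_fcs(path)
    bad = tmp_path / "bad.fcs"
    bad.write_bytes(b"FCS2.0" + blob[6:])
    with pytest.raises(FormatError, match="version"):
        read_fcs(bad)


def test_unknown_channel_requires_mapping(tmp_path):
    path = tmp_path / "odd.fcs"
    write_fcs_fixture(path, np.ones((5, 2)), ["FSC-A", "MYSTERY"])
    with pytest.raises(MappingError):
        read_fcs(path)
    table = read_fcs(path, channel_map={"MYSTERY": "fluorescence"})
    assert table.channels[1].role == "fluorescence"


def test_infer_role_defaults():
    assert infer_role("FSC-Width") == "FSC-Width"
    assert infer_role("LiveDead-A") == "viability"
    assert infer_role("PE-A") == "fluorescence"
    with pytest.raises(MappingError):
        infer_role("Time")


def test_csv_round_trip_small(tmp_path, tiny_table):
    path = tmp_path / "t.csv"
    write_event_csv(tiny_table, path)
    back = read_event_csv(path)
    np.testing.assert_array_equal(back.events, tiny_table.events)
    assert back.meta["condition"] == "stained"


def test_csv_round_trip_full_sample(tmp_path):
    spec = SyntheticSampleSpec(populations=default_populations(25_000.0))
    table, _ = generate_sample(spec, seed=11)
    path = tmp_path / "sample.csv"
    write_event_csv(table, path)
    back = read_event_csv(path)
    np.testing.assert_array_equal(back.events, table.events)
    assert back.channel_names == table.channel_names


def test_csv_errors(tmp_path):
    p = tmp_path / "noheader.csv"
    p.write_text("1,2\n3,4\n")
    with pytest.raises(FormatError, match="header"):
        read_event_csv(p)
    q = tmp_path / "badcell.csv"
    q.write_text("FSC-A,FL1-A\n1,2\n3,oops\n")
    with pytest.raises(FormatError, match="row 3"):
        read_event_csv(q)


def test_event_table_invariants():
    ch = [ChannelDef("FL1-A", "fluorescence")]
    with pytest.raises(SpecError):
        EventTable(events=np.array([[-1.0]]), channels=ch)
    with pytest.raises(SpecError):
        EventTable(events=np.array([[1.0]]), channels=ch, meta={"condition": "weird"})
    EventTable(events=np.array([[1.0]]), channels=ch, meta={"condition": "blocked:bSyn"})


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------


def _fluor_table(values: np.ndarray) -> EventTable:
    channels = [
        ChannelDef("FSC-A", "FSC-A"),
        ChannelDef("FL1-A", "fluorescence"),
        ChannelDef("FL2-A", "fluorescence"),
    ]
    scatter = np.full((values.shape[0], 1), 5.0)
    return EventTable(events=np.hstack([scatter, values]), channels=channels)


def test_compensate_identity_is_identity():
    table = _fluor_table(np.array([[100.0, 110.0], [5.0, 7.0]]))
    spill = SpilloverMatrix(np.eye(2), ("FL1-A", "FL2-A"))
    out = compensate(table, spill)
    np.testing.assert_array_equal(out.events, table.events)
    assert out.meta["compensated"] is True


def test_compensate_triangular_hand_case():
    # x = [100, 110], S = [[1, .1], [0, 1]]  =>  y = x·S⁻¹ = [100, 100]
    table = _fluor_table(np.array([[100.0, 110.0]]))
    spill = SpilloverMatrix(np.array([[1.0, 0.1], [0.0, 1.0]]), ("FL1-A", "FL2-A"))
    out = compensate(table, spill)
    np.testing.assert_allclose(out.events[0, 1:], [100.0, 100.0])
    assert out.events[0, 0] == 5.0  # scatter untouched


def test_compensate_round_trip_and_linearity():
    rng = np.random.default_rng(1)
    vals = rng.uniform(10, 1e4, size=(50, 2))
    table = _fluor_table(vals)
    S = np.array([[1.0, 0.2], [0.05, 1.0]])
    spill = SpilloverMatrix(S, ("FL1-A", "FL2-A"))
    comp = compensate(table, spill)
    # re-mixing the compensated values restores the observations
    np.testing.assert_allclose(comp.events[:, 1:] @ S, vals, rtol=1e-12)
    # linearity in the input
    doubled = compensate(_fluor_table(2 * vals), spill)
    np.testing.assert_allclose(doubled.events[:, 1:], 2 * comp.events[:, 1:], rtol=1e-12)


def test_compensate_negative_qc_counter():
    table = _fluor_table(np.array([[0.0, 50.0]]))
    spill = SpilloverMatrix(np.array([[1.0, 0.0], [0.5, 1.0]]), ("FL1-A", "FL2-A"))
    out = compensate(table, spill)
    assert out.events[0, 1] < 0  # retained, not clipped
    assert out.meta["qc_negative_after_compensation"] == 1


def test_compensate_channel_mismatch_and_bad_matrix():
    table = _fluor_table(np.array([[1.0, 2.0]]))
    spill = SpilloverMatrix(np.eye(2), ("FL1-A", "FSC-A"))
    with pytest.raises(MappingError):
        compensate(table, spill)
    with pytest.raises(SpecError):
        SpilloverMatrix(np.array([[1.0, 1.5], [0.0, 1.0]]), ("FL1-A", "FL2-A"))
    with pytest.raises(SpecError):
        SpilloverMatrix(np.array([[1.0, 0.1], [0.0, 0.9]]), ("FL1-A", "FL2-A"))
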