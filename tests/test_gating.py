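"""Gating geometry, hierarchy monotonicity, and synthetic recovery."""

from __future__ import annotations

import numpy as np
import pytest

from cytoval.cytometry_io import ChannelDef, EventTable
from cytoval.errors import ConfigError, SpecError
from cytoval.gating import (
    GateHierarchy,
    GateSpec,
    apply_gate,
    apply_hierarchy,
    auto_place_scatter_gate,
    gate_singlets,
    gate_viability,
    qc_min_events,
    scatter_hierarchy,
    viability_hierarchy,
)
from cytoval.stain_metrics import population_stats
from cytoval.synthetic import (
    SyntheticSampleSpec,
    default_populations,
    generate_sample,
)

SCATTER_GATES = scatter_hierarchy(7.0e4, 1.0e9)
VIABILITY_GATES = viability_hierarchy("LiveDead-A", 500.0, 3.0e4)


def test_rectangle_covering_everything_passes_all(standard_sample):
    table, _ = standard_sample
    gate = GateSpec(
        "all", "rectangle", ("FSC-A", "SSC-A"),
        {"x": (-np.inf, np.inf), "y": (-np.inf, np.inf)},
    )
    assert apply_gate(table, gate).all()


def test_threshold_extremes(standard_sample):
    table, _ = standard_sample
    hi = GateSpec("keep-all", "threshold", ("LiveDead-A",), {"value": np.inf})
    lo = GateSpec("keep-none", "threshold", ("LiveDead-A",), {"value": 0.0})
    assert apply_gate(table, hi).all()
    assert not apply_gate(table, lo).any()


def test_polygon_boundary_inclusive_and_zero_area_rejected():
    channels = [ChannelDef("FSC-A", "FSC-A"), ChannelDef("FSC-H", "FSC-H")]
    events = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.0], [2.0, 2.0]])
    table = EventTable(events=events, channels=channels)
    square = GateSpec(
        "sq", "polygon", ("FSC-A", "FSC-H"),
        {"vertices": [(0, 0), (1, 0), (1, 1), (0, 1)]},
    )
    mask = apply_gate(table, square)
    assert mask.tolist() == [True, True, True, False]  # vertices/edges included
    with pytest.raises(SpecError, match="polygon"):
        GateSpec("line", "polygon", ("FSC-A", "FSC-H"),
                 {"vertices": [(0, 0), (1, 1), (2, 2)]})


def test_gate_idempotent(standard_sample):
    table, _ = standard_sample
    gate = GateSpec(
        "live", "rectangle", ("FSC-H", "FSC-Width"),
        {"x": (7.0e4, np.inf), "y": (-np.inf, 1e9)},
    )
    m1 = apply_gate(table, gate)
    once = table.subset(m1)
    m2 = apply_gate(once, gate)
    assert m2.all()


def test_scatter_gating_recovers_live_singlets(standard_sample):
    """≥99% of true live singlets kept; ≥99% of every artifact excluded."""
    table, truth = standard_sample
    pop = apply_hierarchy(table, SCATTER_GATES)
    live = truth.labels == "live_singlet"
    kept = pop.final_mask
    assert (kept & live).sum() / live.sum() >= 0.99
    for artifact in ("debris", "dead", "doublet"):
        lab = truth.labels == artifact
        assert (kept & lab).sum() / lab.sum() <= 0.01


def test_viability_gate_recovers_dead_fraction(standard_sample):
    table, truth = standard_sample
    keep = gate_viability(table, "LiveDead-A", threshold=500.0)
    excluded = 1 - keep.mean()
    true_dead = (truth.labels == "dead").mean()
    assert excluded == pytest.approx(true_dead, abs=0.01)
    # boundary cases
    assert gate_viability(table, "LiveDead-A", threshold=np.inf).all()
    assert not gate_viability(table, "LiveDead-A", threshold=0.0).any()


def test_viability_strategy_requires_dye_channel(tiny_table):
    with pytest.raises(ConfigError):
        gate_viability(tiny_table, None, threshold=100.0)


def test_singlet_band_keeps_proportional_events():
    channels = [ChannelDef("FSC-A", "FSC-A"), ChannelDef("FSC-H", "FSC-H")]
    h = np.linspace(1e4, 1e5, 50)
    table = EventTable(events=np.column_stack([1.07 * h, h]), channels=channels)
    assert gate_singlets(table).all()  # constant ratio normalizes to 1
    # measure-zero band on continuous data keeps (almost) nothing
    rng = np.random.default_rng(0)
    jitter = EventTable(
        events=np.column_stack([h * rng.uniform(0.9, 1.1, 50), h]), channels=channels
    )
    assert gate_singlets(jitter, r_lo=1.0, r_hi=1.0).sum() <= 1


def test_singlet_gate_excludes_doublets(standard_sample):
    table, truth = standard_sample
    mask = gate_singlets(table)
    doublets = truth.labels == "doublet"
    assert (mask & doublets).sum() / doublets.sum() <= 0.01
    zero_h = EventTable(
        events=np.array([[100.0, 0.0]]),
        channels=[ChannelDef("FSC-A", "FSC-A"), ChannelDef("FSC-H", "FSC-H")],
    )
    assert not gate_singlets(zero_h).any()  # FSC-H = 0 excluded, no error


def test_hierarchy_counts_monotone_and_conjunctive(standard_sample):
    table, _ = standard_sample
    pop = apply_hierarchy(table, VIABILITY_GATES)
    assert all(a >= b for a, b in zip(pop.counts, pop.counts[1:]))
    combined = np.logical_and.reduce(
        [pop.level_masks[0]] + [m for m in pop.level_masks[1:]]
    )
    np.testing.assert_array_equal(pop.final_mask, pop.level_masks[-1])
    np.testing.assert_array_equal(pop.final_mask, combined)


def test_two_strategies_agree(standard_sample):
    """Scatter-based and dye-based live-singlet counts agree within 2%."""
    table, truth = standard_sample
    n_scatter = apply_hierarchy(table, SCATTER_GATES).counts[-1]
    n_dye = apply_hierarchy(table, VIABILITY_GATES).counts[-1]
    assert abs(n_scatter - n_dye) / max(n_scatter, n_dye) <= 0.02
    true_live = (truth.labels == "live_singlet").sum()
    assert n_scatter == pytest.approx(true_live, rel=0.02)


def test_debris_only_sample_gates_to_zero():
    pops = default_populations(1000.0)
    debris = pops[1]
    spec = SyntheticSampleSpec(
        populations=(type(debris)(
            label="debris", fraction=1.0, scatter=debris.scatter,
            fluor_mean=debris.fluor_mean,
        ),),
        n_events=2000,
    )
    table, _ = generate_sample(spec, 5)
    pop = apply_hierarchy(table, SCATTER_GATES)
    assert pop.counts[-1] == 0


def test_gated_mfi_matches_generating_mean(standard_sample):
    table, truth = standard_sample
    pop = apply_hierarchy(table, SCATTER_GATES)
    mfi, _ = population_stats(table.subset(pop.final_mask), "FL1-A")
    assert mfi == pytest.approx(truth.live_fluor_mean, rel=0.02)


def test_qc_min_events_boundary(standard_sample):
    table, _ = standard_sample
    pop = apply_hierarchy(table, SCATTER_GATES)
    assert qc_min_events(pop, 20_000).passed
    assert not qc_min_events(pop, 20_001).passed
    small_pop = apply_hierarchy(table.subset(np.arange(table.n_events) < 100),
                                SCATTER_GATES)
    assert not qc_min_events(small_pop, 20_000).passed
    assert qc_min_events(small_pop, 0).passed


def test_auto_place_helper_matches_quantiles(standard_sample):
    table, _ = standard_sample
    h_min, w_max = auto_place_scatter_gate(table, 0.05, 0.99)
    assert h_min == pytest.approx(np.quantile(table.column("FSC-H"), 0.05))
    assert w_max == pytest.approx(np.quantile(table.column("FSC-Width"), 0.99))
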