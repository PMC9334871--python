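"""Two-branch gating: debris/dead exclusion, live selection, singlets, QC.

Living single cells are selected by one of two strategies that mirror common
bench practice:

* ``scatter_only`` — debris and dead cells are excluded on an FSC-H vs
  FSC-Width rectangle (debris and shrunken dead cells sit at low FSC-H),
* ``viability_dye`` — events bright in a fixable viability-dye channel are
  excluded as dead.

Both branches end with a singlet gate on the FSC-A/FSC-H pulse ratio:
doublets carry roughly twice the area at a given height, so after dividing
each event's ratio by the population median, singlets cluster near 1 and
doublets near 2.  Gate regions are closed (boundary events are kept) and
data-independent; an optional percentile-based auto-placement helper exists
for convenience but nothing places gates automatically by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .cytometry_io import EventTable
from .errors import ConfigError, MappingError, SpecError

STRATEGIES = ("scatter_only", "viability_dye")


@dataclass(frozen=True)
class GateSpec:
    """One gate: a named region on one or two channels.

    kinds
        ``rectangle``  — parameters {"x": (lo, hi), "y": (lo, hi)} on two
        channels (either bound may be ±inf);
        ``polygon``    — parameters {"vertices": [(x, y), ...]} (≥3,
        non-collinear), even-odd rule, boundary inclusive;
        ``threshold``  — parameters {"value": t, "keep": "below"|"above"};
        events strictly on the wrong side are excluded, the boundary is kept;
        ``ratio_band`` — parameters {"r_lo": a, "r_hi": b, "normalize":
        "median"|"none"} on the ratio channels[0]/channels[1].
    """

    name: str
    kind: str
    channels: tuple[str, ...]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "polygon", "threshold", "ratio_band"):
            raise SpecError(f"unknown gate kind {self.kind!r}")
        need = 1 if self.kind == "threshold" else 2
        if len(self.channels) != need:
            raise SpecError(f"{self.kind} gate needs {need} channel(s)")
        if self.kind == "polygon":
            verts = np.asarray(self.parameters.get("vertices", ()), dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise SpecError("polygon needs >= 3 (x, y) vertices")
            if shapely.Polygon(verts).area <= 0:
                raise SpecError("zero-area polygon")
        if self.kind == "ratio_band":
            r_lo, r_hi = self.parameters["r_lo"], self.parameters["r_hi"]
            if not (0 < r_lo <= r_hi):
                raise SpecError("ratio band requires 0 < r_lo <= r_hi")


@dataclass(frozen=True)
class GateHierarchy:
    """Ordered gates applied conjunctively (debris/dead → live → singlets)."""

    gates: tuple[GateSpec, ...]
    strategy: str = "scatter_only"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise SpecError(f"unknown strategy {self.strategy!r}")


@dataclass
class GatedPopulation:
    """Per-level inclusion masks and counts; final mask is their conjunction."""

    level_names: list[str]
    level_masks: list[np.ndarray]
    counts: list[int]
    final_mask: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.level_masks[0].shape[0]) if self.level_masks else 0

    def report(self):
        import pandas as pd

        n = self.n_total
        rows = [{"level": "all_events", "count": n, "fraction": 1.0}]
        for name, c in zip(self.level_names, self.counts):
            rows.append({"level": name, "count": c, "fraction": c / n if n else 0.0})
        return pd.DataFrame(rows)


def apply_gate(table: EventTable, gate: GateSpec) -> np.ndarray:
    """Boolean mask of events inside the gate region (boundary inclusive)."""
    if gate.kind == "threshold":
        x = table.column(gate.channels[0])
        t = float(gate.parameters["value"])
        if gate.parameters.get("keep", "below") == "below":
            return x <= t
        return x >= t
    x = table.column(gate.channels[0])
    y = table.column(gate.channels[1])
    if gate.kind == "rectangle":
        xlo, xhi = gate.parameters["x"]
        ylo, yhi = gate.parameters["y"]
        return (x >= xlo) & (x <= xhi) & (y >= ylo) & (y <= yhi)
    if gate.kind == "polygon":
        poly = shapely.Polygon(gate.parameters["vertices"])
        pts = shapely.points(np.column_stack([x, y]))
        return shapely.covers(poly, pts)
    # ratio_band
    return _ratio_band_mask(x, y, gate.parameters)


def _ratio_band_mask(area: np.ndarray, height: np.ndarray, params: dict) -> np.ndarray:
    r_lo, r_hi = float(params["r_lo"]), float(params["r_hi"])
    normalize = params.get("normalize", "median")
    ok = height > 0
    ratio = np.full(area.shape, np.inf)
    ratio[ok] = area[ok] / height[ok]
    if normalize == "median" and ok.any():
        med = float(np.median(ratio[ok]))
        if med > 0:
            ratio = ratio / med
    return ok & (ratio >= r_lo) & (ratio <= r_hi)


def gate_viability(
    table: EventTable, channel: str | None = None, threshold: float = None
) -> np.ndarray:
    """Keep events at or below the viability-dye threshold (bright = dead)."""
    if channel is None:
        via = table.channels_with_role("viability")
        if not via:
            raise ConfigError(
                "strategy viability_dye requires a viability channel"
            )
        channel = via[0]
    if table.channels[table.channel_index(channel)].role != "viability":
        raise ConfigError(f"channel {channel!r} is not a viability channel")
    if threshold is None:
        raise ConfigError("viability gating requires an explicit threshold")
    return table.column(channel) <= float(threshold)


def gate_singlets(
    table: EventTable,
    r_lo: float = 0.8,
    r_hi: float = 1.25,
    normalize: str = "median",
) -> np.ndarray:
    """Keep events whose (median-normalized) FSC-A/FSC-H ratio lies in the band.

    Events with FSC-H = 0 are excluded, not an error.  The default band
    [0.8, 1.25] brackets singlets after median normalization; doublets
    (ratio ≈ 2) fall outside.
    """
    fsc_a = table.channels_with_role("FSC-A")
    fsc_h = table.channels_with_role("FSC-H")
    if not fsc_a or not fsc_h:
        raise MappingError("singlet gate requires FSC-A and FSC-H channels")
    gate = GateSpec(
        name="singlets",
        kind="ratio_band",
        channels=(fsc_a[0], fsc_h[0]),
        parameters={"r_lo": r_lo, "r_hi": r_hi, "normalize": normalize},
    )
    return apply_gate(table, gate)


def apply_hierarchy(table: EventTable, hierarchy: GateHierarchy) -> GatedPopulation:
    """Apply gates in order; each level's mask is ANDed with its predecessors."""
    running = np.ones(table.n_events, dtype=bool)
    names, masks, counts = [], [], []
    for gate in hierarchy.gates:
        mask = apply_gate(table, gate)
        running = running & mask
        names.append(gate.name)
        masks.append(running.copy())
        counts.append(int(running.sum()))
    if not masks:
        masks = [running.copy()]
        names = ["all_events"]
        counts = [int(running.sum())]
    return GatedPopulation(
        level_names=names, level_masks=masks, counts=counts, final_mask=running
    )


@dataclass(frozen=True)
class QCReport:
    passed: bool
    total_events: int
    minimum: int
    per_level: tuple[tuple[str, int], ...]


def qc_min_events(pop: GatedPopulation, minimum: int = 20_000) -> QCReport:
    """Fail when fewer events were acquired than the QC minimum (default 20,000)."""
    total = pop.n_total
    return QCReport(
        passed=total >= minimum,
        total_events=total,
        minimum=minimum,
        per_level=tuple(zip(pop.level_names, pop.counts)),
    )


# ---------------------------------------------------------------------------
# Default hierarchies
# ---------------------------------------------------------------------------


def scatter_hierarchy(
    fsc_h_min: float,
    fsc_width_max: float,
    r_lo: float = 0.8,
    r_hi: float = 1.25,
) -> GateHierarchy:
    """Scatter-only strategy: FSC-H/FSC-Width rectangle then singlet band."""
    debris = GateSpec(
        name="live",
        kind="rectangle",
        channels=("FSC-H", "FSC-Width"),
        parameters={"x": (fsc_h_min, np.inf), "y": (-np.inf, fsc_width_max)},
    )
    singlets = GateSpec(
        name="singlets",
        kind="ratio_band",
        channels=("FSC-A", "FSC-H"),
        parameters={"r_lo": r_lo, "r_hi": r_hi, "normalize": "median"},
    )
    return GateHierarchy(gates=(debris, singlets), strategy="scatter_only")


def viability_hierarchy(
    viability_channel: str,
    viability_threshold: float,
    fsc_h_min: float,
    r_lo: float = 0.8,
    r_hi: float = 1.25,
) -> GateHierarchy:
    """Viability-dye strategy: debris rectangle, dead-dye threshold, singlets."""
    debris = GateSpec(
        name="non_debris",
        kind="rectangle",
        channels=("FSC-H", "FSC-Width"),
        parameters={"x": (fsc_h_min, np.inf), "y": (-np.inf, np.inf)},
    )
    live = GateSpec(
        name="live",
        kind="threshold",
        channels=(viability_channel,),
        parameters={"value": viability_threshold, "keep": "below"},
    )
    singlets = GateSpec(
        name="singlets",
        kind="ratio_band",
        channels=("FSC-A", "FSC-H"),
        parameters={"r_lo": r_lo, "r_hi": r_hi, "normalize": "median"},
    )
    return GateHierarchy(gates=(debris, live, singlets), strategy="viability_dye")


def auto_place_scatter_gate(
    table: EventTable, debris_quantile: float = 0.05, width_quantile: float = 0.99
) -> tuple[float, float]:
    """Percentile-based helper for the scatter rectangle (off by default).

    Returns (fsc_h_min, fsc_width_max) cutting the lowest ``debris_quantile``
    of FSC-H and the extreme upper tail of FSC-Width.
    """
    fsc_h = table.column(table.channels_with_role("FSC-H")[0])
    width = table.column(table.channels_with_role("FSC-Width")[0])
    return float(np.quantile(fsc_h, debris_quantile)), float(
        np.quantile(width, width_quantile)
    )
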