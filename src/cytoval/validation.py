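"""Antibody-validation decisions: titration, specificity, sensitivity, ranking.

This layer turns raw staining statistics into the workflow's conclusions:

* **Titration** — for each tested antibody amount, tabulate the stain index
  and the fold change (ratio MFI) of antibody and isotype signal relative to
  the recommended amount.  The optimal amount is the *smallest* amount whose
  SI reaches a fraction θ (default 0.75) of the maximum SI across the
  series: beyond the binding saturation point extra antibody buys mostly
  isotype background, so near-maximal SI at minimal consumption wins.
* **Specificity** — a cross-reactivity profile aggregates blocking
  efficiencies per blocking protein.  An antibody is *specific* when its
  mean self-blocking (blocking by its own antigen) efficiency reaches
  ``self_threshold``; any other protein whose blocking efficiency reaches
  ``cross_threshold`` is flagged as a cross-reactant.
* **Sensitivity** — per cell type, SI is classed as detected / marginal /
  not_detected against a detection threshold and a floor.
* **Ranking** — antibodies are ordered lexicographically: specific first,
  then fewer cross-reactants, then higher mean self-blocking efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .stain_metrics import BlockingMeasurement, StainStatistics, ratio_mfi

SELF_BLOCKERS = ("aSyn_monomer", "aSyn_aggregate")


@dataclass(frozen=True)
class TitrationSeries:
    """SI/MFI statistics per tested amount, plus the recommended amount."""

    antibody: str
    points: tuple[tuple[float, StainStatistics], ...]
    recommended_amount: float

    def __post_init__(self) -> None:
        amounts = [a for a, _ in self.points]
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise SpecError("titration amounts must be strictly increasing")

    @property
    def amounts(self) -> list[float]:
        return [a for a, _ in self.points]


@dataclass(frozen=True)
class OptimalAmountPolicy:
    """Smallest amount reaching θ·max(SI), optionally capped on isotype gain."""

    theta: float = 0.75
    iso_ratio_cap: float = np.inf

    def __post_init__(self) -> None:
        if not (0 < self.theta <= 1):
            raise SpecError("theta must lie in (0, 1]")


def evaluate_titration(series: TitrationSeries) -> pd.DataFrame:
    """Per-amount table of SI and antibody/isotype ratio MFI.

    Ratio MFIs are fold changes relative to the recommended amount, which
    must be one of the tested amounts.
    """
    if len(series.points) < 2:
        raise SpecError("titration needs at least 2 amounts")
    ref = None
    for amount, stats in series.points:
        if amount == series.recommended_amount:
            ref = stats
    if ref is None:
        raise SpecError(
            f"recommended amount {series.recommended_amount} not in series"
        )
    rows = []
    for amount, stats in series.points:
        rows.append(
            {
                "antibody": series.antibody,
                "amount_ug": amount,
                "si": stats.si,
                "mfi_ab": stats.mfi_ab,
                "mfi_iso": stats.mfi_iso,
                "ratio_mfi_ab": ratio_mfi(stats.mfi_ab, ref.mfi_ab),
                "ratio_mfi_iso": ratio_mfi(stats.mfi_iso, ref.mfi_iso),
                "is_recommended": amount == series.recommended_amount,
            }
        )
    return pd.DataFrame(rows)


def select_optimal_amount(
    si_by_amount: Mapping[float, float] | TitrationSeries,
    policy: OptimalAmountPolicy | None = None,
    iso_ratio_by_amount: Mapping[float, float] | None = None,
) -> float:
    """Smallest amount whose SI reaches θ·max(SI) (and passes the isotype cap).

    Accepts either a plain {amount: SI} map (e.g. transcribed from an
    instrument report) or a :class:`TitrationSeries`.  If no amount
    satisfies the constraints the max-SI amount is returned with a warning.
    """
    policy = policy or OptimalAmountPolicy()
    if isinstance(si_by_amount, TitrationSeries):
        si_map = {a: s.si for a, s in si_by_amount.points}
    else:
        si_map = dict(si_by_amount)
    if not si_map:
        raise SpecError("empty titration series")
    max_si = max(si_map.values())
    cutoff = policy.theta * max_si
    for amount in sorted(si_map):
        if si_map[amount] < cutoff:
            continue
        if iso_ratio_by_amount is not None and np.isfinite(policy.iso_ratio_cap):
            if iso_ratio_by_amount.get(amount, 0.0) > policy.iso_ratio_cap:
                continue
        return amount
    best = max(sorted(si_map), key=lambda a: si_map[a])
    warnings.warn(
        "no amount satisfies the optimal-amount constraints; "
        f"falling back to the max-SI amount {best}",
        stacklevel=2,
    )
    return best


@dataclass(frozen=True)
class CrossReactivityProfile:
    """Blocking efficiencies of one antibody grouped by blocker."""

    antibody: str
    entries: tuple[dict, ...]  # blocker, cell_type, condition key, efficiency, flag

    def efficiencies(self, blocker: str) -> list[float]:
        return [e["efficiency"] for e in self.entries if e["blocker"] == blocker]

    def mean_efficiency(self, blocker: str) -> float:
        vals = self.efficiencies(blocker)
        return float(np.mean(vals)) if vals else float("nan")

    def blockers(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e["blocker"] not in seen:
                seen.append(e["blocker"])
        return seen

    def self_efficiencies(self) -> list[float]:
        return [
            e["efficiency"] for e in self.entries if e["blocker"] in SELF_BLOCKERS
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.entries))


def summarize_blocking_panel(
    measurements: Sequence[BlockingMeasurement], antibody: str
) -> CrossReactivityProfile:
    """Aggregate blocking measurements into a per-blocker profile.

    Duplicate (blocker, cell type, condition, replicate) keys are rejected;
    replicates are kept as separate entries and averaged on demand.
    """
    entries = []
    seen = set()
    for m in measurements:
        cond_key = (
            m.condition.fold_excess,
            m.condition.temperature,
            m.condition.duration_h,
        )
        key = (m.condition.blocker, m.cell_type, cond_key, m.replicate)
        if key in seen:
            raise SpecError(f"duplicate blocking measurement key {key}")
        seen.add(key)
        entries.append(
            {
                "blocker": m.condition.blocker,
                "cell_type": m.cell_type,
                "fold_excess": m.condition.fold_excess,
                "temperature": m.condition.temperature,
                "duration_h": m.condition.duration_h,
                "replicate": m.replicate,
                "efficiency": m.efficiency,
                "out_of_range": m.out_of_range,
            }
        )
    return CrossReactivityProfile(antibody=antibody, entries=tuple(entries))


def classify_specificity(
    profile: CrossReactivityProfile,
    self_threshold: float = 0.85,
    cross_threshold: float = 0.40,
) -> tuple[bool, set[str]]:
    """(specific?, cross-reactive blockers) from a cross-reactivity profile.

    Specific iff the mean self-blocking efficiency reaches
    ``self_threshold``.  Every non-self blocker whose mean efficiency
    reaches ``cross_threshold`` is flagged (mixtures containing the antigen
    itself are not counted as cross-reactants).
    """
    self_effs = profile.self_efficiencies()
    if not self_effs:
        raise SpecError("profile has no self-blocker entry")
    specific = float(np.mean(self_effs)) >= self_threshold
    cross = {
        b
        for b in profile.blockers()
        if b not in SELF_BLOCKERS
        and not b.startswith("mix")
        and profile.mean_efficiency(b) >= cross_threshold
    }
    return specific, cross


@dataclass(frozen=True)
class AntibodyAssessment:
    """Specificity, cross-reactivity and per-cell-type sensitivity verdicts."""

    antibody: str
    specific: bool
    cross_reactive_with: frozenset[str]
    mean_self_blocking: float
    sensitivity: dict = field(default_factory=dict)

    @property
    def rank_key(self) -> tuple:
        # specific first; fewer cross-reactants; stronger self-blocking
        return (
            0 if self.specific else 1,
            len(self.cross_reactive_with),
            -self.mean_self_blocking,
        )


def assess_antibody(
    profile: CrossReactivityProfile,
    si_per_cell_type: Mapping[str, float | None] | None = None,
    self_threshold: float = 0.85,
    cross_threshold: float = 0.40,
    detect_threshold: float = 1.5,
    floor: float = 0.5,
) -> AntibodyAssessment:
    specific, cross = classify_specificity(profile, self_threshold, cross_threshold)
    sens = (
        classify_expression(si_per_cell_type, detect_threshold, floor)[0]
        if si_per_cell_type is not None
        else {}
    )
    return AntibodyAssessment(
        antibody=profile.antibody,
        specific=specific,
        cross_reactive_with=frozenset(cross),
        mean_self_blocking=float(np.mean(profile.self_efficiencies())),
        sensitivity=sens,
    )


def classify_expression(
    si_per_cell_type: Mapping[str, float | None],
    detect_threshold: float = 1.5,
    floor: float = 0.5,
) -> tuple[dict, list[str]]:
    """Per-cell-type detection class plus SI-descending ordering.

    ``not_detected`` when SI is missing or ≤ floor, ``marginal`` between
    floor and the detection threshold, ``detected`` at or above it.
    Missing SIs sort last.
    """
    classes = {}
    for cell, si in si_per_cell_type.items():
        if si is None or not np.isfinite(si) or si <= floor:
            classes[cell] = "not_detected"
        elif si < detect_threshold:
            classes[cell] = "marginal"
        else:
            classes[cell] = "detected"
    order = sorted(
        si_per_cell_type,
        key=lambda c: (
            si_per_cell_type[c] is None or not np.isfinite(si_per_cell_type[c] or np.nan),
            -(si_per_cell_type[c] or -np.inf),
        ),
    )
    return classes, order


def rank_antibodies(
    assessments: Sequence[AntibodyAssessment],
) -> list[AntibodyAssessment]:
    """Stable lexicographic ranking; see :class:`AntibodyAssessment.rank_key`."""
    if not assessments:
        raise SpecError("need at least one assessment to rank")
    return sorted(assessments, key=lambda a: a.rank_key)
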