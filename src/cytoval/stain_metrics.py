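"""Staining statistics: MFI/SD, stain index, ratio/normalized MFI,
blocking efficiency, and immunoblot normalization arithmetic.

The stain index

    SI = (MFI_ab − MFI_iso) / (2 · SD_iso)

measures how far the antibody-stained population sits above the isotype
control background in units of background spread; it is invariant under any
affine rescaling of the intensity axis, which makes it comparable across
instruments and voltages.  Blocking efficiency

    E = (MFI_stained − MFI_blocked) / (MFI_stained − MFI_nostain)

is the fraction of the specific signal removed by pre-incubating the
antibody with excess antigen: 1 means the blocker absorbed all specific
binding, 0 means none.  Values outside [0, 1] are reported as-is with a QC
flag rather than clipped — "no detectable blocking" is a distinct outcome,
not a measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cytometry_io import EventTable
from .errors import DegenerateDataError, InsufficientDataError, SpecError

NormalizedForm = Literal["ratio", "difference"]


@dataclass(frozen=True)
class StainSample:
    """A stained/isotype (optionally no-stain) trio measured on one channel."""

    antibody_events: EventTable
    isotype_events: EventTable
    channel: str
    amount_ug: float
    nostain_events: EventTable | None = None
    antibody: str = ""


@dataclass(frozen=True)
class StainStatistics:
    """MFI/SD/SI bundle for one stained+isotype pair."""

    mfi_ab: float
    mfi_iso: float
    sd_iso: float
    si: float
    normalized_mfi: float
    normalized_form: NormalizedForm


@dataclass(frozen=True)
class BlockingCondition:
    """Pre-incubation condition for a blocking experiment."""

    blocker: str
    fold_excess: float
    temperature: str = "RT"
    duration_h: float = 2.0

    def __post_init__(self) -> None:
        if self.fold_excess <= 0:
            raise SpecError("fold excess must be positive")


#: the two standard pre-incubation conditions used throughout
CONDITION_300X = BlockingCondition("aSyn_monomer", 300, "37C", 1.0)
CONDITION_600X = BlockingCondition("aSyn_monomer", 600, "RT", 2.0)

KNOWN_BLOCKERS = (
    "aSyn_monomer",
    "aSyn_aggregate",
    "bSyn",
    "gSyn",
    "tubulin",
    "mix_ab",
    "mix_abg",
)


@dataclass(frozen=True)
class BlockingMeasurement:
    """(stained, blocked, no-stain) MFI triple and its efficiency."""

    mfi_stained: float
    mfi_blocked: float
    mfi_nostain: float
    condition: BlockingCondition
    efficiency: float
    out_of_range: bool
    cell_type: str = ""
    replicate: int = 0


@dataclass(frozen=True)
class WBMeasurement:
    """Densitometric band intensities for one immunoblot lane."""

    target_intensity: float
    actin_intensity: float
    reference_ratio: float

    def __post_init__(self) -> None:
        if self.actin_intensity <= 0 or self.reference_ratio <= 0:
            raise SpecError("actin intensity and reference ratio must be positive")
        if self.target_intensity < 0:
            raise SpecError("band intensity must be nonnegative")


def population_stats(
    events: EventTable | np.ndarray, channel: str | None = None, robust: bool = False
) -> tuple[float, float]:
    """(MFI, SD) of a gated population on one channel.

    MFI is the arithmetic mean (``robust=True`` switches to the median for
    sensitivity studies; never the default); SD uses the n−1 denominator.
    """
    if isinstance(events, EventTable):
        if channel is None:
            raise SpecError("channel required when passing an EventTable")
        x = events.column(channel)
    else:
        x = np.asarray(events, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError("need at least 2 events for MFI/SD")
    center = float(np.median(x)) if robust else float(np.mean(x))
    return center, float(np.std(x, ddof=1))


def stain_index(mfi_ab: float, mfi_iso: float, sd_iso: float) -> float:
    """SI = (MFI_ab − MFI_iso) / (2·SD_iso); may be negative."""
    if sd_iso <= 0:
        raise DegenerateDataError("stain index undefined for SD_iso = 0")
    return (mfi_ab - mfi_iso) / (2.0 * sd_iso)


def ratio_mfi(mfi_x: float, mfi_ref: float) -> float:
    """Fold change of an MFI relative to the reference-amount MFI."""
    if mfi_ref <= 0:
        raise DegenerateDataError("reference MFI must be positive")
    return mfi_x / mfi_ref


def normalized_mfi(
    mfi_ab: float, mfi_iso: float, form: NormalizedForm
) -> float:
    """Background-normalized MFI: ratio (MFI_ab/MFI_iso) or difference."""
    if form == "ratio":
        if mfi_iso == 0:
            raise DegenerateDataError("ratio-normalized MFI undefined for MFI_iso = 0")
        return mfi_ab / mfi_iso
    if form == "difference":
        return mfi_ab - mfi_iso
    raise SpecError(f"unknown normalized-MFI form {form!r}")


def blocking_efficiency(
    mfi_stained: float, mfi_blocked: float, mfi_nostain: float
) -> tuple[float, bool]:
    """(efficiency, out-of-range flag) of a blocking experiment.

    Raises when the stained signal does not exceed the no-stain background —
    the "no detectable blocking" regime where the statistic is undefined.
    """
    if mfi_stained <= mfi_nostain:
        raise DegenerateDataError(
            "no detectable specific signal: MFI_stained <= MFI_nostain"
        )
    eff = (mfi_stained - mfi_blocked) / (mfi_stained - mfi_nostain)
    return eff, not (0.0 <= eff <= 1.0)


def measure_blocking(
    stained: EventTable,
    blocked: EventTable,
    nostain: EventTable,
    channel: str,
    condition: BlockingCondition,
    cell_type: str = "",
    replicate: int = 0,
) -> BlockingMeasurement:
    """Blocking efficiency from three gated event tables on one channel."""
    mfi_s, _ = population_stats(stained, channel)
    mfi_b, _ = population_stats(blocked, channel)
    mfi_n, _ = population_stats(nostain, channel)
    eff, flagged = blocking_efficiency(mfi_s, mfi_b, mfi_n)
    return BlockingMeasurement(
        mfi_stained=mfi_s,
        mfi_blocked=mfi_b,
        mfi_nostain=mfi_n,
        condition=condition,
        efficiency=eff,
        out_of_range=flagged,
        cell_type=cell_type,
        replicate=replicate,
    )


def compute_stain_statistics(
    sample: StainSample, form: NormalizedForm = "ratio", robust: bool = False
) -> StainStatistics:
    """Full MFI/SD/SI/normalized-MFI bundle for a stained+isotype pair."""
    mfi_ab, _ = population_stats(sample.antibody_events, sample.channel, robust)
    mfi_iso, sd_iso = population_stats(sample.isotype_events, sample.channel, robust)
    return StainStatistics(
        mfi_ab=mfi_ab,
        mfi_iso=mfi_iso,
        sd_iso=sd_iso,
        si=stain_index(mfi_ab, mfi_iso, sd_iso),
        normalized_mfi=normalized_mfi(mfi_ab, mfi_iso, form),
        normalized_form=form,
    )


def wb_normalized_signal(wb: WBMeasurement) -> float:
    """Loading-control then reference normalization: (target/actin)/reference."""
    return (wb.target_intensity / wb.actin_intensity) / wb.reference_ratio
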