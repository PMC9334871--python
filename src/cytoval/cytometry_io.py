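"""Event-table I/O and spillover compensation.

The unit of all cytometry computation here is the :class:`EventTable`: an
n-events × k-channels matrix of raw (or compensated) intensities plus the
channel definitions and sample metadata (antibody, amount, condition label,
cell type).  Tables can be read from FCS 3.0/3.1 instrument files or from
plain CSV (the canonical, deterministic interchange format of this package;
a JSON sidecar carries channel roles and metadata).

Fluorescence spillover between detectors is removed by right-multiplying
the fluorescence block with the inverse of the spillover matrix
(row-vector convention, ``true = observed · S⁻¹``).  Negative values that
appear after compensation are retained — clipping would bias the mean
fluorescence intensity — but counted in a QC field.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MappingError, SpecError

CHANNEL_ROLES = ("FSC-A", "FSC-H", "FSC-Width", "SSC-A", "fluorescence", "viability")

#: closed vocabulary of condition labels; "blocked:<protein>" is also valid
CONDITIONS = ("stained", "isotype", "no-stain")


def valid_condition(label: str) -> bool:
    return label in CONDITIONS or label.startswith("blocked:")


@dataclass(frozen=True)
class ChannelDef:
    """One detector channel: short name, role, and instrument detector id."""

    name: str
    role: str
    detector_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise SpecError(f"unknown channel role {self.role!r} for {self.name!r}")


@dataclass
class EventTable:
    """Per-event channel intensities plus sample metadata."""

    events: np.ndarray
    channels: list[ChannelDef]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise SpecError("events must be a 2-D matrix")
        n, k = self.events.shape
        if n < 1 or k < 1:
            raise SpecError("need at least one event and one channel")
        if k != len(self.channels):
            raise SpecError("channel list does not match event matrix width")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise SpecError("channel names must be unique")
        if not self.meta.get("compensated") and np.any(self.events < 0):
            raise SpecError("negative raw intensities")
        cond = self.meta.get("condition")
        if cond is not None and not valid_condition(cond):
            raise SpecError(f"condition label {cond!r} not in the closed vocabulary")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MappingError(f"channel {name!r} not present") from None

    def column(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]

    def channels_with_role(self, role: str) -> list[str]:
        return [c.name for c in self.channels if c.role == role]

    def subset(self, mask: np.ndarray) -> "EventTable":
        """New table containing only the events selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_events,):
            raise SpecError("mask length does not match event count")
        if not mask.any():
            raise SpecError("mask selects no events")
        return EventTable(self.events[mask], list(self.channels), dict(self.meta))


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix over fluorescence/viability channels.

    Entry (i, j) is the fraction of channel i's true signal observed in
    detector j; the diagonal is 1 and off-diagonal entries lie in [0, 1).
    """

    matrix: np.ndarray
    channel_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        k = len(self.channel_order)
        if m.shape != (k, k):
            raise SpecError("spillover matrix shape does not match channel order")
        if not np.allclose(np.diag(m), 1.0):
            raise SpecError("spillover matrix must have unit diagonal")
        off = m[~np.eye(k, dtype=bool)]
        if off.size and (np.any(off < 0) or np.any(off >= 1)):
            raise SpecError("off-diagonal spillover entries must be in [0, 1)")
        if not np.isfinite(np.linalg.cond(m)):
            raise np.linalg.LinAlgError("spillover matrix is singular")


# ---------------------------------------------------------------------------
# Channel-role mapping
# ---------------------------------------------------------------------------

#: substrings (upper-case) that mark a viability-dye channel name
_VIABILITY_HINTS = ("LIVE", "DEAD", "VIAB", "L/D")
#: common fluorochrome tokens; names containing one are fluorescence channels
_FLUOR_HINTS = (
    "FITC", "PE", "APC", "AF488", "AF647", "AF405", "BV", "PERCP",
    "ALEXA", "FL1", "FL2", "FL3", "FL4", "GFP",
)


def infer_role(name: str, channel_map: Mapping[str, str] | None = None) -> str:
    """Map a channel name to its role; explicit mappings win over heuristics."""
    if channel_map and name in channel_map:
        role = channel_map[name]
        if role not in CHANNEL_ROLES:
            raise MappingError(f"mapped role {role!r} for {name!r} is not a role")
        return role
    upper = name.upper()
    if upper in ("FSC-A", "FSC-H", "SSC-A"):
        return upper
    if upper in ("FSC-W", "FSC-WIDTH"):
        return "FSC-Width"
    if any(h in upper for h in _VIABILITY_HINTS):
        return "viability"
    if any(h in upper for h in _FLUOR_HINTS):
        return "fluorescence"
    raise MappingError(
        f"channel name {name!r} has no default role; supply a channel_map entry"
    )


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 reading
# ---------------------------------------------------------------------------

_META_KEYWORDS = {
    "$SMNO": "sample_id",
    "$CYT": "instrument",
    "$SRC": "cell_type",
}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of delimited fields")
    out: dict[str, str] = {}
    for key, val in zip(parts[0::2], parts[1::2]):
        out[key.decode("utf-8", "replace").strip().upper()] = val.decode(
            "utf-8", "replace"
        ).strip()
    return out


def read_fcs(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Supports list-mode data with ``$DATATYPE`` F (float32), D (float64) or
    I (16/32-bit unsigned integers); other datatypes are rejected.  Channel
    roles are inferred from ``$PnN``/``$PnS`` names via :func:`infer_role`.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FormatError("HEADER segment truncated")
    version = blob[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r} in HEADER segment")

    def _offset(a: int, b: int) -> int:
        try:
            return int(blob[a:b].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise FormatError("malformed offsets in HEADER segment") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if not (0 < text_start < text_end < len(blob)):
        raise FormatError("TEXT segment offsets out of range")
    text = _parse_text_segment(blob[text_start : text_end + 1])

    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].upper()
        byteord = text["$BYTEORD"]
    except KeyError as exc:
        raise FormatError(f"TEXT segment missing required keyword {exc}") from exc
    if n_tot == 0:
        raise FormatError("empty event segment")
    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if not (0 < data_start <= data_end <= len(blob) - 1):
        raise FormatError("DATA segment offsets out of range")
    if datatype not in ("F", "D", "I"):
        raise FormatError(
            f"$DATATYPE {datatype!r} not supported (expected F, D or I)"
        )
    little = byteord.startswith("1")
    order = "<" if little else ">"

    bits = []
    names = []
    for p in range(1, n_par + 1):
        try:
            bits.append(int(text[f"$P{p}B"]))
        except KeyError:
            raise FormatError(f"TEXT segment missing $P{p}B") from None
        name = text.get(f"$P{p}N") or text.get(f"$P{p}S") or f"P{p}"
        names.append(name)

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FormatError("$DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(f"{order}f4")
        data = np.frombuffer(blob[data_start : data_end + 1], dtype=dtype)
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FormatError("$DATATYPE D requires 64-bit parameters")
        dtype = np.dtype(f"{order}f8")
        data = np.frombuffer(blob[data_start : data_end + 1], dtype=dtype)
    else:
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FormatError("$DATATYPE I supported only for uniform 16/32-bit")
        dtype = np.dtype(f"{order}u{bits[0] // 8}")
        data = np.frombuffer(blob[data_start : data_end + 1], dtype=dtype)

    if data.size < n_par * n_tot:
        raise FormatError("DATA segment truncated")
    events = np.array(data[: n_par * n_tot], dtype=float).reshape(n_tot, n_par)

    channels = [
        ChannelDef(name=nm, role=infer_role(nm, channel_map), detector_id=f"P{p}")
        for p, nm in enumerate(names, start=1)
    ]
    meta: dict = {"source": str(path), "fcs_version": version}
    for kw, key in _META_KEYWORDS.items():
        if kw in text:
            meta[key] = text[kw]
    return EventTable(events=events, channels=channels, meta=meta)


# ---------------------------------------------------------------------------
# CSV interchange (canonical for tests: one row per event, UTF-8, '.' decimal)
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_event_csv(
    table: EventTable, path: str | Path, float_format: str = "%.17g"
) -> None:
    """Write an event table as CSV plus a JSON metadata sidecar.

    The default ``%.17g`` format round-trips IEEE doubles exactly, so
    write → read reproduces the event matrix bit for bit.
    """
    path = Path(path)
    df = pd.DataFrame(table.events, columns=table.channel_names)
    df.to_csv(path, index=False, float_format=float_format)
    sidecar = {
        "channels": [
            {"name": c.name, "role": c.role, "detector_id": c.detector_id}
            for c in table.channels
        ],
        "meta": {k: v for k, v in table.meta.items() if _json_safe(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_event_csv(
    path: str | Path, channel_map: Mapping[str, str] | None = None
) -> EventTable:
    """Read a CSV event table (with optional JSON sidecar) back."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header or all(_is_number(tok) for tok in header.split(",")):
        raise FormatError(f"{path}: missing header row naming channels")
    df = pd.read_csv(path, float_precision="round_trip")
    arr = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            arr[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy() & df[col].notna().to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r}"
            ) from None

    side = _sidecar_path(path)
    if side.exists():
        info = json.loads(side.read_text())
        channels = [
            ChannelDef(c["name"], c["role"], c.get("detector_id", ""))
            for c in info["channels"]
        ]
        if [c.name for c in channels] != list(df.columns):
            raise MappingError(f"{path}: sidecar channels disagree with CSV header")
        meta = dict(info.get("meta", {}))
    else:
        channels = [
            ChannelDef(name, infer_role(name, channel_map)) for name in df.columns
        ]
        meta = {"source": str(path)}
    return EventTable(events=arr, channels=channels, meta=meta)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------


def compensate(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Remove spectral spillover: ``true = observed · S⁻¹`` per event row.

    Only the channels named in the spillover matrix (which must all be
    fluorescence or viability channels of the table) are transformed;
    scatter channels are untouched.  The result is flagged
    ``meta["compensated"]`` and carries the count of negative
    post-compensation values in ``meta["qc_negative_after_compensation"]``.
    """
    allowed = set(table.channels_with_role("fluorescence")) | set(
        table.channels_with_role("viability")
    )
    missing = [c for c in spill.channel_order if c not in allowed]
    if missing:
        raise MappingError(
            f"spillover channels {missing} are not fluorescence/viability "
            "channels of the table"
        )
    idx = [table.channel_index(c) for c in spill.channel_order]
    observed = table.events[:, idx]
    # y·S = x  =>  y = x·S⁻¹ ; solve S'·y' = x' instead of forming the inverse
    corrected = np.linalg.solve(spill.matrix.T, observed.T).T
    events = table.events.copy()
    events[:, idx] = corrected
    meta = dict(table.meta)
    meta["compensated"] = True
    meta["qc_negative_after_compensation"] = int(np.sum(corrected < 0))
    return EventTable(events=events, channels=list(table.channels), meta=meta)
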