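"""Pairwise protein alignment for epitope cross-reactivity screening.

Antibody cross-reactivity with an off-target protein can often be traced to
local sequence similarity between the antibody's epitope and the off-target.
This module provides the two classical pairwise alignments used for such
screens — Smith–Waterman (local, "Water"-style) and Needleman–Wunsch
(global, "Needle"-style) — with affine gap penalties and a BLOSUM62
substitution matrix, plus helpers to cut epitopes out of an antigen and to
tabulate epitope-vs-target similarity.

The dynamic program is Gotoh's three-state recursion with a deterministic
traceback.  Two affine gap-cost conventions are supported, because reference
tools differ in whether the first gapped residue is charged the extension
penalty on top of the opening penalty:

* ``"open"``        — a gap of length g costs  open + (g − 1) · extend
* ``"open+extend"`` — a gap of length g costs  open + g · extend

The convention in force is recorded on every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .errors import SpecError

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_NEG = -math.inf


def _load_blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


_BLOSUM62 = _load_blosum62()


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence (uppercase, 20 amino acids plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SpecError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ALPHABET
        if bad:
            raise SpecError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the affine-gap dynamic program.

    Defaults follow the common reference-tool settings: BLOSUM62,
    gap open 10, gap extend 0.5, and (in global mode) free end gaps.
    """

    matrix: Mapping[tuple[str, str], float] = field(default_factory=lambda: _BLOSUM62)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    mode: str = "local"
    end_gap_penalty: bool = False
    gap_convention: str = "open"  # "open" or "open+extend"

    def __post_init__(self) -> None:
        if self.mode not in ("local", "global"):
            raise SpecError(f"unknown alignment mode {self.mode!r}")
        if self.gap_convention not in ("open", "open+extend"):
            raise SpecError(f"unknown gap convention {self.gap_convention!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise SpecError("require gap_open >= gap_extend >= 0")

    @property
    def first_gap_cost(self) -> float:
        if self.gap_convention == "open":
            return self.gap_open
        return self.gap_open + self.gap_extend

    def gap_cost(self, length: int) -> float:
        """Total cost of one gap of the given length under this convention."""
        if length <= 0:
            return 0.0
        return self.first_gap_cost + (length - 1) * self.gap_extend


@dataclass(frozen=True)
class EpitopeSpec:
    """A 1-based inclusive residue range on an antigen."""

    antibody: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SpecError(f"invalid epitope range {self.start}-{self.end}")


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal pairwise alignment and its summary statistics.

    ``identity_pct`` and ``similarity_pct`` use the full alignment length
    (gap columns included) as denominator; ``gaps`` counts gap characters.
    Spans are 1-based inclusive ranges of the aligned region on each input.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps: int
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    mode: str
    gap_convention: str

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def alignment_stats(
    aligned_a: str,
    aligned_b: str,
    matrix: Mapping[tuple[str, str], float] = _BLOSUM62,
) -> tuple[float, float, int]:
    """(identity %, similarity %, gap character count) of an aligned pair.

    Identity counts columns with identical residues; similarity counts
    columns whose substitution score is positive (which includes all
    identity columns for BLOSUM62).  Both are percentages of the full
    alignment length including gap columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise SpecError("aligned strings differ in length")
    n = len(aligned_a)
    if n == 0:
        return 0.0, 0.0, 0
    ident = sim = gaps = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            ident += 1
        if matrix[(x, y)] > 0:
            sim += 1
    return 100.0 * ident / n, 100.0 * sim / n, gaps


def score_alignment(
    aligned_a: str, aligned_b: str, params: AlignmentParams
) -> float:
    """Affine-gap score of an explicit alignment (used as an audit path)."""
    score = 0.0
    run_a = run_b = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise SpecError("double-gap column")
        if x == "-":
            run_a += 1
            if run_b:
                score -= params.gap_cost(run_b)
                run_b = 0
        elif y == "-":
            run_b += 1
            if run_a:
                score -= params.gap_cost(run_a)
                run_a = 0
        else:
            if run_a:
                score -= params.gap_cost(run_a)
                run_a = 0
            if run_b:
                score -= params.gap_cost(run_b)
                run_b = 0
            score += params.matrix[(x, y)]
    score -= params.gap_cost(run_a) + params.gap_cost(run_b)
    return score


def _validate(seq: SequenceRecord | str, name: str) -> str:
    if isinstance(seq, SequenceRecord):
        return seq.residues
    rec = SequenceRecord(id=name, residues=seq)
    return rec.residues


# ---------------------------------------------------------------------------
# Gotoh three-state dynamic program
# ---------------------------------------------------------------------------
# States: M  — a[i] aligned to b[j]
#         X  — a[i] aligned to a gap (gap in B)
#         Y  — b[j] aligned to a gap (gap in A)
# Gap-to-gap transitions (X<->Y) are allowed and charged as a fresh opening,
# matching an exhaustive enumeration over all gapped alignments.


def _dp(a: str, b: str, params: AlignmentParams, local: bool):
    n, m = len(a), len(b)
    go = params.first_gap_cost
    ge = params.gap_extend
    mat = params.matrix
    free_ends = (not params.end_gap_penalty) and not local

    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    # traceback: for each state, which predecessor state
    tbM = [[0] * (m + 1) for _ in range(n + 1)]
    tbX = [[0] * (m + 1) for _ in range(n + 1)]
    tbY = [[0] * (m + 1) for _ in range(n + 1)]
    S_M, S_X, S_Y, S_START = 1, 2, 3, 0

    M[0][0] = 0.0
    # in local mode the borders stay at -inf: a local alignment never starts
    # or ends in a gap state, and restarts are the 0 option of the M recursion
    if not local:
        for i in range(1, n + 1):
            if free_ends:
                X[i][0] = 0.0
                tbX[i][0] = S_START
            else:
                X[i][0] = -params.gap_cost(i)
                tbX[i][0] = S_X if i > 1 else S_START
        for j in range(1, m + 1):
            if free_ends:
                Y[0][j] = 0.0
                tbY[0][j] = S_START
            else:
                Y[0][j] = -params.gap_cost(j)
                tbY[0][j] = S_Y if j > 1 else S_START

    best_local = 0.0
    best_pos = (0, 0)

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        tbMi, tbXi, tbYi = tbM[i], tbX[i], tbY[i]
        for j in range(1, m + 1):
            s = mat[(ai, b[j - 1])]
            # M state: tie order diagonal M > X > Y (> local restart)
            vm, vx, vy = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            best, state = vm, S_M
            if vx > best:
                best, state = vx, S_X
            if vy > best:
                best, state = vy, S_Y
            if local and 0.0 >= best:
                best, state = 0.0, S_START
            Mi[j] = best + s
            tbMi[j] = state
            # X state: consume a[i], gap in b; predecessors at (i-1, j)
            vm, vx, vy = Mp[j] - go, Xp[j] - ge, Yp[j] - go
            best, state = vm, S_M
            if vx > best:
                best, state = vx, S_X
            if vy > best:
                best, state = vy, S_Y
            Xi[j] = best
            tbXi[j] = state
            # Y state: consume b[j], gap in a; predecessors at (i, j-1)
            vm, vy, vx = Mi[j - 1] - go, Yi[j - 1] - ge, Xi[j - 1] - go
            best, state = vm, S_M
            if vy > best:
                best, state = vy, S_Y
            if vx > best:
                best, state = vx, S_X
            Yi[j] = best
            tbYi[j] = state
            if local and Mi[j] > best_local:
                best_local = Mi[j]
                best_pos = (i, j)

    return M, X, Y, tbM, tbX, tbY, best_local, best_pos


def _traceback_states(i, j, state, tbM, tbX, tbY, a, b, local):
    S_M, S_X, S_Y, S_START = 1, 2, 3, 0
    cols_a: list[str] = []
    cols_b: list[str] = []
    while state != S_START and (i > 0 or j > 0):
        if state == S_M:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            state = tbM[i][j]
            i, j = i - 1, j - 1
        elif state == S_X:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            state = tbX[i][j]
            i -= 1
        elif state == S_Y:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            state = tbY[i][j]
            j -= 1
        else:
            break
        if local and state == S_START:
            break
    return "".join(reversed(cols_a)), "".join(reversed(cols_b)), i, j


def _finish(
    a: str,
    b: str,
    aligned_a: str,
    aligned_b: str,
    start_i: int,
    start_j: int,
    score: float,
    params: AlignmentParams,
) -> AlignmentResult:
    used_a = len(aligned_a) - aligned_a.count("-")
    used_b = len(aligned_b) - aligned_b.count("-")
    span_a = (start_i + 1, start_i + used_a) if used_a else (0, 0)
    span_b = (start_j + 1, start_j + used_b) if used_b else (0, 0)
    ident, sim, gaps = alignment_stats(aligned_a, aligned_b, params.matrix)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity_pct=ident,
        similarity_pct=sim,
        gaps=gaps,
        span_a=span_a,
        span_b=span_b,
        mode=params.mode,
        gap_convention=params.gap_convention,
    )


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: AlignmentParams | None = None,
) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch) alignment under affine gaps.

    With ``end_gap_penalty=False`` (default) terminal gaps are free, but the
    returned alignment still covers both sequences end to end and identity
    is computed over the full alignment length.
    """
    params = params or AlignmentParams(mode="global")
    if params.mode != "global":
        params = replace(params, mode="global")
    sa, sb = _validate(a, "a"), _validate(b, "b")
    n, m = len(sa), len(sb)
    M, X, Y, tbM, tbX, tbY, _, _ = _dp(sa, sb, params, local=False)

    S_M, S_X, S_Y = 1, 2, 3
    if params.end_gap_penalty:
        candidates = [(M[n][m], S_M, n, m), (X[n][m], S_X, n, m), (Y[n][m], S_Y, n, m)]
    else:
        # free trailing end gaps: best cell on the last row or column
        candidates = []
        for i in range(n + 1):
            for sc, st in ((M[i][m], S_M), (X[i][m], S_X), (Y[i][m], S_Y)):
                candidates.append((sc, st, i, m))
        for j in range(m + 1):
            for sc, st in ((M[n][j], S_M), (X[n][j], S_X), (Y[n][j], S_Y)):
                candidates.append((sc, st, n, j))
    score, state, ei, ej = max(candidates, key=lambda t: (t[0], t[2] + t[3], -t[1]))

    core_a, core_b, si, sj = _traceback_states(ei, ej, state, tbM, tbX, tbY, sa, sb, local=False)
    # pad free end gaps so the alignment covers both full sequences
    lead_a, lead_b = sa[:si], sb[:sj]
    tail_a, tail_b = sa[ei:], sb[ej:]
    aligned_a = lead_a + "-" * len(lead_b) + core_a + tail_a + "-" * len(tail_b)
    aligned_b = "-" * len(lead_a) + lead_b + core_b + "-" * len(tail_a) + tail_b
    return _finish(sa, sb, aligned_a, aligned_b, 0, 0, score, params)


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    params: AlignmentParams | None = None,
) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment under affine gaps.

    The score is never negative; when no positive-scoring residue pair
    exists the empty alignment with score 0 is returned.
    """
    params = params or AlignmentParams(mode="local")
    if params.mode != "local":
        params = replace(params, mode="local")
    sa, sb = _validate(a, "a"), _validate(b, "b")
    M, X, Y, tbM, tbX, tbY, best, (ei, ej) = _dp(sa, sb, params, local=True)
    if best <= 0.0:
        return _finish(sa, sb, "", "", 0, 0, 0.0, params)
    aligned_a, aligned_b, si, sj = _traceback_states(
        ei, ej, 1, tbM, tbX, tbY, sa, sb, local=True
    )
    return _finish(sa, sb, aligned_a, aligned_b, si, sj, best, params)


def align(a, b, params: AlignmentParams) -> AlignmentResult:
    return local_align(a, b, params) if params.mode == "local" else global_align(a, b, params)


# ---------------------------------------------------------------------------
# Epitopes and cross-reactivity tables
# ---------------------------------------------------------------------------


def extract_epitope(seq: SequenceRecord, spec: EpitopeSpec) -> SequenceRecord:
    """Cut a 1-based inclusive residue range out of an antigen sequence."""
    if spec.end > len(seq):
        raise SpecError(
            f"epitope {spec.antibody} range {spec.start}-{spec.end} exceeds "
            f"sequence {seq.id!r} of length {len(seq)}"
        )
    return SequenceRecord(
        id=f"{seq.id}[{spec.start}-{spec.end}]",
        residues=seq.residues[spec.start - 1 : spec.end],
    )


def epitope_crossreactivity_table(
    antigen: SequenceRecord,
    epitopes: Sequence[EpitopeSpec],
    targets: Sequence[SequenceRecord],
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Local + global alignment of every epitope against every target.

    Also aligns the full antigen against each target and reports the antigen
    span of the best local alignment, so epitope overlap with the most
    similar antigen region can be assessed.
    """
    base = params or AlignmentParams()
    rows = []
    full_spans: dict[str, tuple[int, int]] = {}
    for tgt in targets:
        res = local_align(antigen, tgt, replace(base, mode="local"))
        full_spans[tgt.id] = res.span_a
    for spec in epitopes:
        pep = extract_epitope(antigen, spec)
        for tgt in targets:
            loc = local_align(pep, tgt, replace(base, mode="local"))
            glo = global_align(pep, tgt, replace(base, mode="global"))
            span = full_spans[tgt.id]
            rows.append(
                {
                    "antibody": spec.antibody,
                    "epitope": f"{spec.start}-{spec.end}",
                    "target": tgt.id,
                    "local_score": loc.score,
                    "local_identity_pct": loc.identity_pct,
                    "local_similarity_pct": loc.similarity_pct,
                    "local_gaps": loc.gaps,
                    "global_score": glo.score,
                    "global_identity_pct": glo.identity_pct,
                    "antigen_best_local_start": span[0],
                    "antigen_best_local_end": span[1],
                    "epitope_overlaps_best_region": not (
                        span[1] < spec.start or span[0] > spec.end
                    ),
                }
            )
    return pd.DataFrame(rows)


def format_alignment(a_id: str, b_id: str, result: AlignmentResult) -> str:
    """Human-readable pairwise alignment block (header + aligned pair)."""
    match_line = []
    for x, y in zip(result.aligned_a, result.aligned_b):
        if x == "-" or y == "-":
            match_line.append(" ")
        elif x == y:
            match_line.append("|")
        elif _BLOSUM62[(x, y)] > 0:
            match_line.append(":")
        else:
            match_line.append(".")
    header = (
        f"# {a_id} vs {b_id}  mode={result.mode} convention={result.gap_convention}\n"
        f"# Length: {result.length}  Score: {result.score:.1f}\n"
        f"# Identity: {result.identity_pct:.1f}%  Similarity: "
        f"{result.similarity_pct:.1f}%  Gaps: {result.gaps}\n"
        f"# Span A: {result.span_a[0]}-{result.span_a[1]}  "
        f"Span B: {result.span_b[0]}-{result.span_b[1]}\n"
    )
    return header + result.aligned_a + "\n" + "".join(match_line) + "\n" + result.aligned_b + "\n"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Load protein sequences from a FASTA file."""
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SpecError(f"no sequences found in {path}")
    return records


def bundled_sequence_path(name: str) -> Path:
    """Path to a FASTA file shipped with the package."""
    p = Path(__file__).parent / "data" / f"{name}.fasta"
    if not p.exists():
        raise FileNotFoundError(p)
    return p
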