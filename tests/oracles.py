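"""Independent brute-force oracles for the alignment and threshold tests.

These deliberately share no code with the package: alignments are scored by
enumerating every gapped column sequence, and the threshold oracle scans
every candidate cut of the histogram.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def affine_score(cols: list[tuple[str, str]], matrix, gap_open, gap_extend, first_gap_cost) -> float:
    """Score an explicit alignment, charging each gap run open+(len-1)*ext
    style costs via the supplied first-gap cost."""
    score = 0.0
    prev = None  # 'a' gap-in-a, 'b' gap-in-b, 'm' match
    for x, y in cols:
        if x == "-":
            score -= first_gap_cost if prev != "a" else gap_extend
            prev = "a"
        elif y == "-":
            score -= first_gap_cost if prev != "b" else gap_extend
            prev = "b"
        else:
            score += matrix[(x, y)]
            prev = "m"
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (list of columns) of a and b."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def global_oracle(a, b, matrix, gap_open, gap_extend, first_gap_cost, free_end_gaps=True):
    """Optimal global score by exhaustive enumeration."""
    best = -math.inf
    for cols in enumerate_alignments(a, b):
        s = affine_score(cols, matrix, gap_open, gap_extend, first_gap_cost)
        if free_end_gaps:
            # refund terminal gap runs; a run must sit in one sequence only
            def _gap_row(col):
                return 0 if col[0] == "-" else (1 if col[1] == "-" else None)

            lead = 0
            row = _gap_row(cols[0]) if cols else None
            while row is not None and lead < len(cols) and _gap_row(cols[lead]) == row:
                lead += 1
            tail = 0
            row = _gap_row(cols[-1]) if cols else None
            while (
                row is not None
                and tail < len(cols) - lead
                and _gap_row(cols[len(cols) - 1 - tail]) == row
            ):
                tail += 1
            core = cols[lead : len(cols) - tail]
            s = affine_score(core, matrix, gap_open, gap_extend, first_gap_cost)
        best = max(best, s)
    return best


def local_oracle(a, b, matrix, gap_open, gap_extend, first_gap_cost):
    """Optimal local score: best global score over all substring pairs."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_oracle(
                        a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend,
                        first_gap_cost, free_end_gaps=False,
                    )
                    best = max(best, s)
    return best


def li_criterion(x: np.ndarray, t: float) -> float:
    """Cross entropy of thresholding positive values at t (oracle copy)."""
    lo, hi = x[x <= t], x[x > t]
    total = 0.0
    for part in (lo, hi):
        if part.size:
            mu = part.mean()
            if mu > 0:
                total -= part.sum() * math.log(mu)
    return total


def li_scan_oracle(image: np.ndarray) -> float:
    """Best threshold by scanning midpoints of all adjacent intensity pairs."""
    x = np.asarray(image, dtype=float).ravel()
    vals = np.unique(x)
    assert vals.size >= 2
    shift = -vals[0] + 1e-12 if vals[0] <= 0 else 0.0
    x = x + shift
    vals = vals + shift
    cands = (vals[:-1] + vals[1:]) / 2
    scores = [li_criterion(x, t) for t in cands]
    return float(cands[int(np.argmin(scores))] - shift)
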