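"""Alignment engine: brute-force oracles, reference cross-checks, epitopes."""

from __future__ import annotations

import itertools
import random
import warnings

import pytest

from cytoval.epitope_align import (
    AlignmentParams,
    EpitopeSpec,
    SequenceRecord,
    alignment_stats,
    bundled_sequence_path,
    epitope_crossreactivity_table,
    extract_epitope,
    global_align,
    local_align,
    read_fasta,
    score_alignment,
)
from cytoval.errors import SpecError

from .oracles import global_oracle, local_oracle

ALPHABET = "ACGT"  # 4-letter test alphabet (valid amino-acid letters)


def _params(mode, convention="open"):
    return AlignmentParams(mode=mode, gap_convention=convention)


def _matrix():
    return AlignmentParams().matrix


@pytest.mark.parametrize("convention", ["open", "open+extend"])
def test_global_scores_match_enumeration_oracle(convention):
    """DP global scores equal exhaustive enumeration over all alignments."""
    p = _params("global", convention)
    mat = p.matrix
    seqs_short = ["".join(s) for n in (1, 2) for s in itertools.product(ALPHABET, repeat=n)]
    pairs = [(a, b) for a in seqs_short for b in seqs_short]
    rng = random.Random(0)
    for _ in range(40):
        a = "".join(rng.choice(ALPHABET) for _ in range(rng.randint(3, 6)))
        b = "".join(rng.choice(ALPHABET) for _ in range(rng.randint(3, 6)))
        pairs.append((a, b))
    for a, b in pairs:
        expected = global_oracle(a, b, mat, p.gap_open, p.gap_extend, p.first_gap_cost)
        got = global_align(a, b, p)
        assert got.score == pytest.approx(expected), (a, b)


@pytest.mark.parametrize("convention", ["open", "open+extend"])
def test_local_scores_match_substring_oracle(convention):
    """DP local scores equal the exhaustive substring-pair oracle."""
    p = _params("local", convention)
    mat = p.matrix
    seqs_short = ["".join(s) for n in (1, 2) for s in itertools.product(ALPHABET, repeat=n)]
    pairs = [(a, b) for a in seqs_short for b in seqs_short]
    rng = random.Random(1)
    for _ in range(12):
        a = "".join(rng.choice(ALPHABET) for _ in range(rng.randint(3, 5)))
        b = "".join(rng.choice(ALPHABET) for _ in range(rng.randint(3, 5)))
        pairs.append((a, b))
    for a, b in pairs:
        expected = local_oracle(a, b, mat, p.gap_open, p.gap_extend, p.first_gap_cost)
        got = local_align(a, b, p)
        assert got.score == pytest.approx(expected), (a, b)


@pytest.mark.parametrize("mode", ["local", "global"])
def test_scores_match_reference_aligner(mode):
    """Scores agree with Biopython's PairwiseAligner on random protein pairs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = mode
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    if mode == "global":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
    p = _params(mode, "open")
    rng = random.Random(2)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    fn = local_align if mode == "local" else global_align
    for _ in range(150):
        a = "".join(rng.choice(aa) for _ in range(rng.randint(1, 18)))
        b = "".join(rng.choice(aa) for _ in range(rng.randint(1, 18)))
        assert fn(a, b, p).score == pytest.approx(aligner.score(a, b)), (a, b)


def test_self_alignment_is_perfect():
    seq = "MDVFMKGLSKAKEG"
    mat = _matrix()
    for fn, mode in ((local_align, "local"), (global_align, "global")):
        res = fn(seq, seq, _params(mode))
        assert res.identity_pct == 100.0
        assert res.score == pytest.approx(sum(mat[(c, c)] for c in seq))
        assert res.gaps == 0


def test_score_is_symmetric():
    a, b = "EQVTNVGGAVVTG", "MDVFMKGLSK"
    for mode in ("local", "global"):
        p = _params(mode)
        fa = local_align if mode == "local" else global_align
        assert fa(a, b, p).score == pytest.approx(fa(b, a, p).score)


def test_reported_stats_match_recomputation_from_aligned_strings():
    """identity/similarity/gaps recomputed from the alignment match the fields."""
    rng = random.Random(3)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for mode in ("local", "global"):
        p = _params(mode)
        fn = local_align if mode == "local" else global_align
        for _ in range(30):
            a = "".join(rng.choice(aa) for _ in range(rng.randint(4, 20)))
            b = "".join(rng.choice(aa) for _ in range(rng.randint(4, 20)))
            res = fn(a, b, p)
            if not res.aligned_a:
                continue
            ident, sim, gaps = alignment_stats(res.aligned_a, res.aligned_b, p.matrix)
            assert res.identity_pct == pytest.approx(ident)
            assert res.similarity_pct == pytest.approx(sim)
            assert res.gaps == gaps
            assert res.identity_pct <= res.similarity_pct <= 100.0
            # de-gapped local alignment rows are substrings of the inputs
            assert res.aligned_a.replace("-", "") in a
            assert res.aligned_b.replace("-", "") in b
            if mode == "local" and res.score > 0:
                assert score_alignment(res.aligned_a, res.aligned_b, p) == pytest.approx(res.score)


def test_local_score_monotone_under_extension():
    """Extending either sequence can never lower the optimal local score."""
    rng = random.Random(4)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    p = _params("local")
    for _ in range(20):
        a = "".join(rng.choice(aa) for _ in range(8))
        b = "".join(rng.choice(aa) for _ in range(8))
        base = local_align(a, b, p).score
        assert local_align(a + rng.choice(aa), b, p).score >= base
        assert local_align(a, rng.choice(aa) + b, p).score >= base


def test_empty_local_alignment_when_nothing_scores_positive():
    # glycine vs tryptophan scores negative under BLOSUM62
    res = local_align("G", "W", _params("local"))
    assert res.score == 0.0
    assert res.aligned_a == "" and res.aligned_b == ""


def test_invalid_residues_rejected():
    with pytest.raises(SpecError):
        local_align("ACDB1", "ACD", _params("local"))


# ---------------------------------------------------------------------------
# Epitopes and the bundled sequences
# ---------------------------------------------------------------------------


def test_extract_epitope_ranges():
    asyn = read_fasta(bundled_sequence_path("syua_human"))[0]
    assert len(asyn) == 140
    cases = {"LB509": (115, 122, 8), "2A7": (61, 95, 35), "MJFR1": (118, 123, 6)}
    for name, (start, end, length) in cases.items():
        pep = extract_epitope(asyn, EpitopeSpec(name, start, end))
        assert len(pep) == length
    assert extract_epitope(asyn, EpitopeSpec("all", 1, 140)).residues == asyn.residues
    with pytest.raises(SpecError):
        extract_epitope(asyn, EpitopeSpec("oob", 100, 141))


def test_epitope_self_table_and_empty_targets():
    asyn = read_fasta(bundled_sequence_path("syua_human"))[0]
    spec = EpitopeSpec("LB509", 115, 122)
    table = epitope_crossreactivity_table(asyn, [spec], [asyn])
    assert len(table) == 1
    assert table.iloc[0]["local_identity_pct"] == 100.0
    assert bool(table.iloc[0]["epitope_overlaps_best_region"])
    empty = epitope_crossreactivity_table(asyn, [spec], [])
    assert empty.empty


def test_full_antigen_vs_neuronal_tubulin_best_region_overlaps_c_terminal_epitopes():
    """The most aSyn-similar tubulin-β3 region covers the LB509/MJFR1 epitopes."""
    asyn = read_fasta(bundled_sequence_path("syua_human"))[0]
    tubs = {t.id: t for t in read_fasta(bundled_sequence_path("tubulins_synthetic"))}
    res = local_align(asyn, tubs["TBB3_HUMAN_SYNTHETIC"], _params("local"))
    start, end = res.span_a
    assert start <= 115 and end >= 122  # covers the LB509 epitope
    assert res.identity_pct == pytest.approx(100 * 6 / 18, abs=0.5)
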