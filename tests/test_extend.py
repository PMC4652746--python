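"""Extension kernels: one-gap semi-global DP, affine SW, banded traceback,
fallback threshold and SW rationing."""

import numpy as np
import pytest

from conftest import random_seq
from oracles import gotoh_local, gotoh_semiglobal

from coralign.extend import (DpParams, SwBudget, banded_traceback, extend_hit,
                             semi_global_one_gap, sw_score)
from coralign.index import build_index
from coralign.io import Genome
from coralign.scoring import DEFAULT_SCHEME, alignment_score, max_score
from coralign.seedsearch import SeedScan


def _rand_case(rng, n_lo=30, n_hi=60, m_lo=90, m_hi=170, mutate=True):
    m = int(rng.integers(m_lo, m_hi))
    ref = random_seq(rng, m)
    n = int(rng.integers(n_lo, n_hi))
    if mutate and rng.random() < 0.75:
        p = int(rng.integers(0, m - n - 8))
        read = list(ref[p:p + n])
        for _ in range(int(rng.integers(0, 5))):
            read[int(rng.integers(0, n))] = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.5:
            j = int(rng.integers(2, n - 8))
            g = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                read = read[:j] + list(random_seq(rng, g)) + read[j:]
            else:
                read = read[:j] + read[j + g:]
        read = "".join(read)[:n]
    else:
        read = random_seq(rng, n)
    quals = rng.integers(2, 41, len(read)).tolist()
    return read, quals, ref


# --- semi-global one-gap -------------------------------------------------------

def test_semiglobal_exact_read_is_all_match(rng):
    ref = random_seq(rng, 200)
    read = ref[60:135]
    quals = [40] * 75
    res = semi_global_one_gap(read, quals, ref, d=10)
    assert str(res.cigar) == "75M"
    assert res.score == pytest.approx(max_score(quals))
    assert res.ref_start == 60


def test_semiglobal_recovers_deletion_and_matches_dp(rng):
    ref = random_seq(rng, 220)
    read = ref[60:100] + ref[102:137]  # 2 bp deleted at offset 40 of 75
    quals = [40] * 75
    res = semi_global_one_gap(read, quals, ref, d=10)
    assert str(res.cigar) == "40M2D35M"
    dp, runs, longest = gotoh_semiglobal(read, quals, ref, DEFAULT_SCHEME)
    assert res.score == pytest.approx(dp)


def test_semiglobal_score_self_consistent(rng):
    for _ in range(15):
        read, quals, ref = _rand_case(rng)
        res = semi_global_one_gap(read, quals, ref, d=10)
        rec = alignment_score(read, quals, res.cigar,
                              ref[res.ref_start:res.ref_end], DEFAULT_SCHEME)
        assert res.score == pytest.approx(rec)


def test_semiglobal_equals_dp_in_one_gap_class(rng):
    """Equal to the affine DP optimum whenever that optimum has <= 1 gap run
    within d; never above it otherwise."""
    d = 30
    agree = 0
    for _ in range(40):
        read, quals, ref = _rand_case(rng)
        dp, runs, longest = gotoh_semiglobal(read, quals, ref, DEFAULT_SCHEME)
        res = semi_global_one_gap(read, quals, ref, d)
        if runs <= 1 and longest <= d:
            assert res.score == pytest.approx(dp)
            agree += 1
        else:
            assert res.score <= dp + 1e-9
    assert agree >= 20  # the generator mostly produces one-gap cases


def test_semiglobal_window_shorter_than_read_errors():
    with pytest.raises(ValueError):
        semi_global_one_gap("ACGTACGTACGTACGT", [40] * 16, "ACGTACG", d=5)


# --- SW score ------------------------------------------------------------------

def test_sw_identical_sequences_closed_form():
    seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
    score, end = sw_score(seq, [40] * 30, seq)
    assert score == pytest.approx(30 * float(DEFAULT_SCHEME.match_bonus(40)))
    assert end == (30, 30)


def test_sw_disjoint_alphabets_scores_zero():
    score, _ = sw_score("A" * 20, [40] * 20, "C" * 20)
    assert score == 0.0


def test_sw_matches_naive_gotoh(rng):
    for _ in range(25):
        read, quals, ref = _rand_case(rng, n_hi=45, m_hi=120)
        assert sw_score(read, quals, ref)[0] == \
            pytest.approx(gotoh_local(read, quals, ref, DEFAULT_SCHEME))


# --- banded traceback ----------------------------------------------------------

def test_traceback_exact_match(rng):
    ref = random_seq(rng, 100)
    read = ref[20:60]
    quals = [40] * 40
    score, end = sw_score(read, quals, ref)
    res = banded_traceback(read, quals, ref, end, band=8, expected_score=score)
    assert str(res.cigar) == "40M"
    assert res.score == pytest.approx(score)


def test_traceback_recovers_insertion(rng):
    ref = random_seq(rng, 120)
    read = ref[20:45] + "TTT" + ref[45:70]  # 3 bp inserted
    read = read.replace("N", "A")
    quals = [40] * len(read)
    score, end = sw_score(read, quals, ref)
    res = banded_traceback(read, quals, ref, end, band=8, expected_score=score)
    assert "3I" in str(res.cigar)
    rec = alignment_score(read, quals, res.cigar,
                          ref[res.ref_start:res.ref_end], DEFAULT_SCHEME)
    assert rec == pytest.approx(score)


def test_traceback_band_doubles_until_scores_agree(rng):
    ref = random_seq(rng, 120)
    read = ref[20:50] + ref[53:80]  # 3 bp deletion; band 1 cannot hold it
    quals = [40] * len(read)
    score, end = sw_score(read, quals, ref)
    res = banded_traceback(read, quals, ref, end, band=1, expected_score=score)
    assert res.score == pytest.approx(score)  # succeeded only by widening


def test_traceback_rejects_when_band_capped(rng):
    ref = random_seq(rng, 200)
    read = ref[10:50] + ref[80:120]  # 30 bp deletion
    quals = [40] * len(read)
    score, end = sw_score(read, quals, ref)
    with pytest.raises(RuntimeError):
        banded_traceback(read, quals, ref, end, band=1, expected_score=score,
                         band_max=2)


# --- extend_hit ----------------------------------------------------------------

def _hit_for(idx, seed):
    step, hits = SeedScan(idx, seed).first_hits()
    assert hits
    return hits[0]


def test_extend_clean_read_stays_semiglobal(rng):
    gseq = random_seq(rng, 4000)
    idx = build_index(Genome({"c1": gseq}))
    read = gseq[1000:1100]
    quals = [40] * 100
    cand = extend_hit(read, quals, _hit_for(idx, read[:75]), idx, DpParams())
    assert cand.result.method == "semiglobal"
    assert cand.result.clip_left == cand.result.clip_right == 0
    assert cand.pos == 1000


def test_extend_breakpoint_read_soft_clips_65m35s(rng):
    gseq = random_seq(rng, 6000)
    idx = build_index(Genome({"c1": gseq}))
    read = gseq[1000:1065] + gseq[4000:4035]  # right 35 bp from elsewhere
    quals = [40] * 100
    # seed hit anchors the true left part; the foreign tail gets clipped
    cand = extend_hit(read, quals, _hit_for(idx, read[:60]), idx, DpParams())
    assert cand.result.method == "sw"
    assert str(cand.result.cigar) == "65M35S"


def test_ninety_percent_rule_flips_method_deterministically(rng):
    """2 mismatches at Q40 keep exactly 90% of the max score (semi-global);
    a third pushes below and triggers the SW fallback."""
    gseq = random_seq(rng, 4000)
    idx = build_index(Genome({"c1": gseq}))
    base = gseq[2000:2100]
    quals = [40] * 100  # max 200; each Q40 mismatch costs 2 + 8 = 10
    for k, method in ((2, "semiglobal"), (3, "sw")):
        read = list(base)
        for i in np.linspace(10, 90, k).astype(int):
            read[i] = next(b for b in "ACGT" if b != read[i])
        read = "".join(read)
        cand = extend_hit(read, quals, _hit_for(idx, read[:75]), idx, DpParams())
        assert cand.result.method == method, k


def test_sw_budget_caps_extensions(rng):
    gseq = random_seq(rng, 3000)
    idx = build_index(Genome({"c1": gseq}))
    params = DpParams(sw_budget=8, stall_limit=100)
    budget = SwBudget(sw_budget=8, stall_limit=100)
    # a read far from every hit forces the SW path on each candidate
    read = random_seq(rng, 80)
    quals = [40] * 80
    hit = _hit_for(idx, gseq[500:575])
    for _ in range(20):
        extend_hit(read, quals, hit, idx, params, budget=budget)
    assert budget.used <= 8
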