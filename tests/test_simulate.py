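"""Synthetic data generators: determinism, truth bookkeeping, error caps,
rearrangement invertibility."""

import numpy as np
import pytest

from coralign.io import revcomp
from coralign.simulate import (ERROR_CAP, QualityProfile, SVEvent, apply_events,
                               breakpoints_of, make_genome, rearrange_genome,
                               reads_spanning_breakpoints, simulate_pairs,
                               simulate_reads, spike_indels, truth_from_tsv,
                               truth_to_tsv)


# --- genome ------------------------------------------------------------------

def test_make_genome_deterministic_and_sized():
    g1 = make_genome(50_000, 2, 0.1, seed=7)
    g2 = make_genome(50_000, 2, 0.1, seed=7)
    assert g1.sequences == g2.sequences
    assert g1.total_length == 50_000
    assert make_genome(50_000, 2, 0.1, seed=8).sequences != g1.sequences


def test_make_genome_gc_content():
    g = make_genome(100_000, 1, 0.0, seed=3)
    seq = g["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.41) < 0.02


def test_make_genome_repeat_free_has_unique_30mers():
    g = make_genome(30_000, 1, 0.0, seed=5)
    seq = g["chr1"]
    kmers = [seq[i:i + 30] for i in range(0, len(seq) - 30, 7)]
    assert len(set(kmers)) == len(kmers)


def test_make_genome_repeat_fraction_duplicates_content():
    g = make_genome(50_000, 1, 0.2, seed=7)
    seq = g["chr1"]
    kmers = {}
    for i in range(0, len(seq) - 30):
        kmers.setdefault(seq[i:i + 30], []).append(i)
    dup_positions = sum(len(v) for v in kmers.values() if len(v) > 1)
    assert dup_positions / len(seq) >= 0.15


def test_make_genome_rejects_tiny():
    with pytest.raises(ValueError):
        make_genome(5000, 1, 0.0, seed=1)


# --- reads --------------------------------------------------------------------

def test_error_free_reads_are_exact_substrings():
    g = make_genome(20_000, 2, 0.0, seed=2)
    reads, truths = simulate_reads(g, 50, 80, QualityProfile(sub_rate=0.0), seed=4)
    assert len(reads) == len(truths) == 50
    assert {r.id for r in reads} == {t.read_id for t in truths}  # bijection
    for r, t in zip(reads, truths):
        slice_ = g[t.chrom][t.pos:t.pos + 80]
        expected = slice_ if t.strand == "+" else revcomp(slice_)
        assert r.bases == expected
        assert t.n_mismatches == 0


def test_substitution_rate_matches_target():
    g = make_genome(50_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 4000, 100, QualityProfile(sub_rate=0.01), seed=4)
    total_mm = sum(t.n_mismatches for t in truths)
    rate = total_mm / (4000 * 100)
    assert 0.008 <= rate <= 0.012


def test_error_cap_respected():
    g = make_genome(20_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 300, 50, QualityProfile(sub_rate=0.08), seed=4)
    reads, truths = spike_indels(reads, truths, g, 0.01, "mixed", seed=4)
    for t in truths:
        err = t.n_mismatches + sum(g_ for _, g_, _ in t.indels)
        assert err <= int(ERROR_CAP * 50)


def test_spike_indels_rate_zero_is_identity():
    g = make_genome(20_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 20, 100, QualityProfile(sub_rate=0.0), seed=4)
    reads2, truths2 = spike_indels(reads, truths, g, 0.0, "mixed", seed=4)
    assert [r.bases for r in reads2] == [r.bases for r in reads]
    assert all(not t.indels for t in truths2)


def test_spike_indels_delete_mode_counts():
    g = make_genome(200_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 5000, 100, QualityProfile(sub_rate=0.0), seed=4)
    _, truths2 = spike_indels(reads, truths, g, 0.001, "delete", seed=4)
    dels = sum(1 for t in truths2 for _, _, k in t.indels if k == "D")
    ins = sum(1 for t in truths2 for _, _, k in t.indels if k == "I")
    assert ins == 0
    # ~500 expected events at 0.001/base over 500k bases
    assert 380 <= dels <= 620


def test_spiked_deletion_bookkeeping_exact():
    """With zero substitutions, a deleted read must equal its reference span
    with the deleted bases removed, on both strands."""
    g = make_genome(30_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 200, 100, QualityProfile(sub_rate=0.0), seed=4)
    reads2, truths2 = spike_indels(reads, truths, g, 0.004, "delete", seed=4)
    checked = 0
    for r, t in zip(reads2, truths2):
        if len(t.indels) != 1:
            continue
        o, gl, kind = t.indels[0]
        assert kind == "D"
        assert len(r.bases) == 100
        span = g[t.chrom][t.pos:t.pos + 100 + gl]
        oriented = span if t.strand == "+" else revcomp(span)
        assert r.bases == oriented[:o] + oriented[o + gl:]
        checked += 1
    assert checked >= 10


def test_spiked_insertion_bookkeeping_exact():
    g = make_genome(30_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 200, 100, QualityProfile(sub_rate=0.0), seed=4)
    reads2, truths2 = spike_indels(reads, truths, g, 0.004, "insert", seed=4)
    checked = 0
    for r, t in zip(reads2, truths2):
        if len(t.indels) != 1:
            continue
        o, gl, kind = t.indels[0]
        assert kind == "I"
        span = g[t.chrom][t.pos:t.pos + 100 - gl]
        oriented = span if t.strand == "+" else revcomp(span)
        assert r.bases[:o] == oriented[:o]
        assert r.bases[o + gl:] == oriented[o:]
        checked += 1
    assert checked >= 10


# --- pairs --------------------------------------------------------------------

def test_concordant_pairs_insert_statistics():
    g = make_genome(100_000, 1, 0.0, seed=2)
    r1, r2, truths = simulate_pairs(g, 1000, 100, 500, 50, False, seed=4,
                                    profile=QualityProfile(sub_rate=0.0))
    t1 = {t.read_id: t for t in truths if t.strand == "+"}
    inserts = []
    for t in truths:
        if t.strand == "-":
            frag = t.pos + 100 - t1[t.read_id].pos
            inserts.append(frag)
    mean = np.mean(inserts)
    assert abs(mean - 500) <= 5
    assert all(f >= 200 for f in inserts)  # no overlapping ends


def test_discordant_pairs_cross_chromosomes():
    g = make_genome(40_000, 2, 0.0, seed=2)
    r1, r2, truths = simulate_pairs(g, 200, 100, discordant=True, seed=4,
                                    profile=QualityProfile(sub_rate=0.0))
    by_id = {}
    for t in truths:
        by_id.setdefault(t.read_id, []).append(t.chrom)
    assert all(len(set(v)) == 2 for v in by_id.values())


def test_overlapping_ends_rejected():
    g = make_genome(40_000, 1, 0.0, seed=2)
    with pytest.raises(ValueError):
        simulate_pairs(g, 10, 250, 400, 50, False, seed=4)


# --- rearrangement --------------------------------------------------------------

def test_single_deletion_arithmetic():
    g = make_genome(30_000, 1, 0.0, seed=2)
    ev = [SVEvent("deletion", "chr1", 10_000, 10_500)]
    out, blocks = apply_events(g, ev)
    assert out.total_length == g.total_length - 500
    assert len(breakpoints_of(blocks)) == 1
    assert breakpoints_of(blocks)[0] == ("chr1", 10_000)


def test_rearranged_genome_deterministic_and_invertible():
    g = make_genome(60_000, 2, 0.0, seed=3)
    out1, ev1, bp1 = rearrange_genome(g, 20, seed=5)
    out2, ev2, bp2 = rearrange_genome(g, 20, seed=5)
    assert out1.sequences == out2.sequences and bp1 == bp2
    # replaying the recorded events reproduces the rearranged genome exactly
    replay, _ = apply_events(g, ev1)
    assert replay.sequences == out1.sequences


def test_inversion_produces_two_breakpoints():
    g = make_genome(30_000, 1, 0.0, seed=2)
    _, blocks = apply_events(g, [SVEvent("inversion", "chr1", 8000, 9000)])
    assert len(breakpoints_of(blocks)) == 2


def test_translocation_moves_sequence_between_chromosomes():
    g = make_genome(40_000, 2, 0.0, seed=2)
    seg = g["chr1"][5000:5400]
    out, _ = apply_events(g, [SVEvent("translocation", "chr1", 5000, 5400,
                                      target_chrom="chr2", target_pos=3000)])
    assert seg not in out["chr1"]
    assert seg in out["chr2"]
    assert out.total_length == g.total_length


def test_breakpoint_reads_have_min_flank():
    g = make_genome(60_000, 2, 0.0, seed=3)
    re_g, ev, bps = rearrange_genome(g, 10, seed=5)
    reads, truths = reads_spanning_breakpoints(re_g, bps, 40, 100, 25, seed=6)
    bpset = dict()
    for c, p in bps:
        bpset.setdefault(c, []).append(p)
    for t in truths:
        assert any(t.pos + 25 <= p <= t.pos + 75 for p in bpset[t.chrom])


# --- truth TSV -------------------------------------------------------------------

def test_truth_tsv_roundtrip(tmp_path):
    g = make_genome(20_000, 1, 0.0, seed=2)
    reads, truths = simulate_reads(g, 30, 60, QualityProfile(sub_rate=0.02), seed=4)
    reads, truths = spike_indels(reads, truths, g, 0.01, "mixed", seed=4)
    p = tmp_path / "t.tsv"
    truth_to_tsv(truths, p)
    back = truth_from_tsv(p)
    assert [(t.read_id, t.klass, t.chrom, t.pos, t.strand, t.n_mismatches, t.indels)
            for t in back] == \
        [(t.read_id, t.klass, t.chrom, t.pos, t.strand, t.n_mismatches, t.indels)
         for t in truths]
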