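"""Whole-read single-end alignment.

Seeds are taken as non-overlapping 75-bp segments from the 5' end (one seed
for reads under 150 bp), searched in cost order, deep-scanned for runner-up
hits, extended to full-read alignments, and ranked by the quality-aware
score — never by raw mismatch count, which is exactly the trap this design
avoids: a read simulated with k mismatches can have a decoy locus at fewer
mismatches, and only quality-aware ranking over a candidate set that still
contains the true origin can resolve it.

Mapping quality comes from the two best full-read scores.  When a primary
alignment soft-clips more than 20 bp, the clipped tail is re-placed by an
exact 20-mer scan and a local realignment, producing a supplementary record
so that the two records together represent the whole read across an SV
breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import io as cio
from .extend import DpParams, ExtendedCandidate, SwBudget, banded_traceback, extend_hit, sw_score
from .index import GenomeIndex, find_exact
from .io import Cigar, Read, revcomp
from .scoring import DEFAULT_SCHEME, ScoringScheme, compute_mapq, max_score
from .seedsearch import Penalties, SearchBudget, SeedScan, deep_scan

__all__ = ["Alignment", "CandidateSet", "AlignParams", "choose_seeds",
           "align_single", "rank_and_emit", "realign_clip", "align_read",
           "unmapped_alignment"]

SEED_LEN = 75
LONG_READ_LEN = 150
CLIP_TRIGGER = 20   # supplementary realignment when clip exceeds this
CLIP_SCAN_LEN = 20  # exact-scan length within the clipped tail


@dataclass
class AlignParams:
    budget: SearchBudget = field(default_factory=SearchBudget)
    penalties: Penalties = field(default_factory=Penalties)
    dp: DpParams = field(default_factory=DpParams)
    seed_len: int = SEED_LEN  # seed segment length
    depth: int = 1            # extra non-empty cost steps for the deep scan
    repeat_cap: int = 64      # H: step hits beyond this force mapQ 0
    max_extensions: int = 16  # candidate loci extended per read
    confident_mapq: int = 20
    # 'end' scans the clipped 20-mer furthest from the primary alignment;
    # 'breakpoint' scans the 20-mer adjacent to it
    clip_scan_from: str = "end"


@dataclass
class Alignment:
    """A placed read: SAM-ready primary or supplementary record."""

    read_id: str
    chrom: str
    pos: int                  # 0-based leftmost
    strand: str
    cigar: Cigar
    score: float
    mapq: int
    read_bases: str           # original (FASTQ) orientation
    read_quals: list[int]
    is_supplementary: bool = False
    is_unmapped: bool = False
    method: str = "semiglobal"
    rescued: bool = False
    # pairing attributes, set by the paired pipeline
    paired: bool = False
    proper_pair: bool = False
    mate_unmapped: bool = False
    mate_reverse: bool = False
    read_index: int = 0       # 1 or 2 within a pair
    mate_rname: str = "*"
    mate_pos: int | None = None
    tlen: int = 0

    @property
    def flag(self) -> int:
        f = 0
        if self.paired:
            f |= cio.FLAG_PAIRED
            if self.proper_pair:
                f |= cio.FLAG_PROPER
            if self.mate_unmapped:
                f |= cio.FLAG_MATE_UNMAPPED
            if self.mate_reverse:
                f |= cio.FLAG_MATE_REVERSE
            if self.read_index == 1:
                f |= cio.FLAG_READ1
            elif self.read_index == 2:
                f |= cio.FLAG_READ2
        if self.is_unmapped:
            return f | cio.FLAG_UNMAPPED
        if self.strand == "-":
            f |= cio.FLAG_REVERSE
        if self.is_supplementary:
            f |= cio.FLAG_SUPPLEMENTARY
        return f

    @property
    def ref_end(self) -> int:
        return self.pos + self.cigar.ref_len

    def read_span(self) -> tuple[int, int]:
        """Aligned (M/I-consuming) read interval, in original read coordinates."""
        lo = self.cigar.clip_left
        hi = len(self.read_bases) - self.cigar.clip_right
        if self.strand == "-":
            L = len(self.read_bases)
            lo, hi = L - hi, L - lo
        return lo, hi


def unmapped_alignment(read: Read) -> Alignment:
    return Alignment(read_id=read.id, chrom="*", pos=0, strand="+",
                     cigar=Cigar(()), score=0.0, mapq=0,
                     read_bases=read.bases, read_quals=list(read.quals),
                     is_unmapped=True)


@dataclass
class CandidateSet:
    read_id: str
    candidates: list[ExtendedCandidate]  # ranked by descending score
    repeat_flag: bool
    max_score: float


def choose_seeds(read: Read, seed_len: int = SEED_LEN) -> list[tuple[int, int]]:
    """Seed segments as (offset, length) pairs.

    Reads under twice the seed length get one seed: the first
    min(seed_len, len) bases.  Longer reads are split into floor(len/seed_len)
    consecutive non-overlapping segments from the 5' end; any shorter
    remainder joins extension only.
    """
    L = len(read)
    if L < 12:
        raise ValueError("read shorter than 12 bp cannot be seeded")
    if L < 2 * seed_len:
        return [(0, min(seed_len, L))]
    return [(i * seed_len, seed_len) for i in range(L // seed_len)]


def _scaled_budget(budget: SearchBudget, seed_len: int, index_k: int = 8,
                   full_len: int = SEED_LEN) -> SearchBudget:
    """Mismatch budget proportional to seed length, constrained so the
    pigeonhole candidate generation stays feasible (chunks no shorter than
    the index k-mer and than the allowed gap length minus one); an
    infeasible gap allowance is dropped rather than falling back to a
    genome-wide scan."""
    if seed_len >= full_len:
        return budget
    mm = min(budget.mm_max, max(0, (budget.mm_max * seed_len) // full_len))
    d = min(budget.d_seed, max(1, seed_len // 4))
    if budget.allow_gap:
        while mm >= 0:
            chunk = seed_len // (mm + 3)
            if chunk >= index_k:
                return SearchBudget(mm_max=mm, allow_gap=True,
                                    d_seed=max(1, min(d, chunk + 1)))
            mm -= 1
        mm = min(budget.mm_max, max(0, (budget.mm_max * seed_len) // full_len))
    while mm > 0 and seed_len // (mm + 1) < index_k:
        mm -= 1
    return SearchBudget(mm_max=mm, allow_gap=False, d_seed=1)


def _segment_hits(index: GenomeIndex, seg: str, params: AlignParams,
                  allow_split: bool = True) -> tuple[list, list, bool]:
    """Seed one segment: ([(hit, offset-in-segment)...] first hits,
    same-shaped deep-scan hits, repeat flag).

    A segment that straddles an SV breakpoint can exceed the mismatch budget
    outright; when the full segment yields nothing within budget, each half
    is re-seeded with a proportionally scaled budget (a read with >= 25 bp
    on each side of a breakpoint always has one clean half), so the intact
    part of the read still anchors a clipped primary alignment.
    """
    budget = _scaled_budget(params.budget, len(seg))
    try:
        scan = SeedScan(index, seg, budget, params.penalties)
    except ValueError:
        return [], [], False
    step, first = scan.first_hits()
    if step is None:
        if allow_split and len(seg) >= 24:
            half = len(seg) // 2
            firsts, extras, rep = [], [], False
            for off2, sub in ((0, seg[:half]), (half, seg[half:])):
                f2, e2, r2 = _segment_hits(index, sub, params, allow_split=False)
                firsts.extend((h, off2 + o) for h, o in f2)
                extras.extend((h, off2 + o) for h, o in e2)
                rep = rep or r2
            return firsts, extras, rep
        return [], [], False
    repeat = len(first) > params.repeat_cap
    if repeat:
        return [(h, 0) for h in first[: params.repeat_cap]], [], True
    extra = deep_scan(index, seg, step, first, depth=params.depth,
                      budget=budget, penalties=params.penalties, scan=scan)
    if len(first) > 1:  # deep_scan returns first_hits unchanged in this branch
        extra = []
    return [(h, 0) for h in first], [(h, 0) for h in extra], False


def _locus_key(chrom: str, strand: str, pos: int, radius: int) -> tuple:
    return (chrom, strand, pos // max(1, radius))


def align_single(read: Read, index: GenomeIndex, params: AlignParams = AlignParams(),
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> CandidateSet:
    """Seed, deep-scan and extend one read into a ranked candidate set."""
    ms = max_score(read.quals, scheme)
    if set(read.bases) <= {"N"}:
        return CandidateSet(read.id, [], False, ms)
    seeds = choose_seeds(read, params.seed_len)
    seg_results = []
    repeat_flag = False
    for off, ln in seeds:
        seg = read.bases[off:off + ln]
        if set(seg) <= {"N"}:
            continue
        first, extra, rep = _segment_hits(index, seg, params)
        repeat_flag = repeat_flag or rep
        seg_results.append((off, ln, first, extra))

    # candidate loci for full-read extension: (seed hit, offset in read)
    loci: list[tuple] = []
    if len(seg_results) > 1:
        # long read: if every segment's best hit is unique and they are
        # mutually local, extend the whole read over that locus once
        tops = [(off + o2, h) for off, ln, first, _ in seg_results if len(first) == 1
                for h, o2 in first]
        local = len(tops) == len(seg_results) == len(seeds) and len(tops) > 1
        if local:
            o0, h0 = tops[0]
            for off, h in tops[1:]:
                expected = off - o0
                if (h.chrom != h0.chrom or h.strand != h0.strand):
                    local = False
                    break
                delta = (h.pos - h0.pos - expected) if h0.strand == "+" \
                    else (h0.pos - h.pos - expected)
                if abs(delta) > len(read) + params.dp.d:
                    local = False
                    break
        if local:
            o0, h0 = tops[0]
            loci.append((h0, o0))
            for off, ln, first, extra in seg_results:
                for h, o2 in extra:
                    loci.append((h, off + o2))
        else:
            for off, ln, first, extra in seg_results:
                for h, o2 in first + extra:
                    loci.append((h, off + o2))
    else:
        for off, ln, first, extra in seg_results:
            for h, o2 in first + extra:
                loci.append((h, off + o2))

    # deduplicate loci that would extend over the same window
    seen: set = set()
    unique_loci = []
    for h, off in loci:
        oso = off if h.strand == "+" else len(read) - off - h.seed_cigar.read_len
        key = _locus_key(h.chrom, h.strand, h.pos - oso, params.dp.d)
        if key in seen:
            continue
        seen.add(key)
        unique_loci.append((h, off))
    unique_loci = unique_loci[: params.max_extensions]

    budget = SwBudget(sw_budget=params.dp.sw_budget, stall_limit=params.dp.stall_limit)
    cands: list[ExtendedCandidate] = []
    for h, off in unique_loci:
        try:
            cand = extend_hit(read.bases, read.quals, h, index, params.dp,
                              scheme, budget=budget, seed_offset=off)
        except ValueError:
            continue
        cands.append(cand)

    # collapse identical placements surfaced via different seeds/signatures
    best_at: dict[tuple, ExtendedCandidate] = {}
    for c in cands:
        key = (c.chrom, c.strand, c.pos)
        if key not in best_at or c.score > best_at[key].score:
            best_at[key] = c
    ranked = sorted(best_at.values(),
                    key=lambda c: (-c.score, c.chrom, c.pos, c.strand))
    return CandidateSet(read.id, ranked, repeat_flag, ms)


def rank_and_emit(candidates: CandidateSet, read: Read,
                  scheme: ScoringScheme = DEFAULT_SCHEME) -> list[Alignment]:
    """Primary alignment (best score, deterministic tie-break) with mapQ from
    the two best candidate scores."""
    if not candidates.candidates:
        return [unmapped_alignment(read)]
    best = candidates.candidates[0]
    second = candidates.candidates[1].score if len(candidates.candidates) > 1 else None
    mapq = compute_mapq(best.score, second, candidates.max_score,
                        repeat_flag=candidates.repeat_flag, scheme=scheme)
    aln = Alignment(read_id=read.id, chrom=best.chrom, pos=best.pos,
                    strand=best.strand, cigar=best.result.cigar, score=best.score,
                    mapq=mapq, read_bases=read.bases, read_quals=list(read.quals),
                    method=best.result.method)
    return [aln]


def realign_clip(alignment: Alignment, read: Read, index: GenomeIndex,
                 params: AlignParams = AlignParams(),
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> Alignment | None:
    """Supplementary alignment of a soft-clipped tail longer than 20 bp.

    An exact scan of 20 bp of the clipped tail (by default the 20 bp
    furthest from the primary alignment) proposes loci; the read is then
    locally realigned at each and the best complementary placement is
    emitted as a supplementary record.
    """
    cig = alignment.cigar
    clip_l, clip_r = cig.clip_left, cig.clip_right
    if max(clip_l, clip_r) <= CLIP_TRIGGER:
        return None
    use_left = clip_l >= clip_r
    clip_len = clip_l if use_left else clip_r
    if clip_len < CLIP_SCAN_LEN:
        return None

    # oriented read = read as it aligns to the forward reference
    oread = read.bases if alignment.strand == "+" else revcomp(read.bases)
    oquals = list(read.quals) if alignment.strand == "+" else list(read.quals)[::-1]
    L = len(oread)
    if use_left:
        tail, t_lo, t_hi = oread[:clip_l], 0, clip_l
    else:
        tail, t_lo, t_hi = oread[L - clip_r:], L - clip_r, L
    tquals = oquals[t_lo:t_hi]

    # 0-mismatch scan of a 20-mer of the clipped tail: outermost first (or
    # junction-side first, per config), the other end as fallback
    outer = tail[:CLIP_SCAN_LEN] if use_left else tail[-CLIP_SCAN_LEN:]
    inner = tail[-CLIP_SCAN_LEN:] if use_left else tail[:CLIP_SCAN_LEN]
    probes = [outer, inner] if params.clip_scan_from == "end" else [inner, outer]
    cand_loci: list[tuple[str, int, str]] = []
    for probe in probes:
        for strand in "+-":
            for chrom, pos in find_exact(index, probe, strand):
                cand_loci.append((chrom, pos, strand))
        if cand_loci:
            break
    if not cand_loci:
        return None
    cand_loci.sort()

    results = []
    for chrom, pos, strand in cand_loci[: params.max_extensions]:
        # the tail (not the whole read) is realigned, so the supplementary
        # always complements the primary; strand '-' of the probe scan means
        # the tail lands in flipped orientation relative to the primary
        sup_strand = alignment.strand if strand == "+" \
            else ("-" if alignment.strand == "+" else "+")
        if strand == "+":
            stail, stquals = tail, tquals
        else:
            stail, stquals = revcomp(tail), tquals[::-1]
        chrom_seq = index.genome[chrom]
        w_start = max(0, pos - len(tail) - params.dp.d)
        w_end = min(len(chrom_seq), pos + len(tail) + params.dp.d + CLIP_SCAN_LEN)
        window = chrom_seq[w_start:w_end]
        if len(window) < CLIP_SCAN_LEN:
            continue
        try:
            score, end = sw_score(stail, stquals, window, scheme)
            if score <= 0:
                continue
            res = banded_traceback(stail, stquals, window, end, params.dp.band,
                                   scheme, expected_score=score,
                                   band_max=params.dp.band_max)
        except (ValueError, RuntimeError):
            continue
        # tail interval in supplementary-oriented read coordinates
        same = sup_strand == alignment.strand
        a, b = (t_lo, t_hi) if same else (L - t_hi, L - t_lo)
        ops = ([(a + res.cigar.clip_left, "S")]
               + [(n, c) for n, c in res.cigar.ops if c != "S"]
               + [(L - b + res.cigar.clip_right, "S")])
        sup = Alignment(read_id=read.id, chrom=chrom, pos=w_start + res.ref_start,
                        strand=sup_strand, cigar=Cigar.from_ops(ops), score=res.score,
                        mapq=0, read_bases=read.bases, read_quals=list(read.quals),
                        is_supplementary=True, method="sw")
        results.append(sup)
    if not results:
        return None
    results.sort(key=lambda a: (-a.score, a.chrom, a.pos, a.strand))
    best = results[0]
    second = results[1].score if len(results) > 1 else None
    # the supplementary places only the clipped tail, so its no-runner-up
    # floor is measured against the tail's maximum score, capped by the
    # primary's confidence
    best.mapq = min(alignment.mapq,
                    compute_mapq(best.score, second, max_score(tquals, scheme),
                                 scheme=scheme))
    return best


def align_read(read: Read, index: GenomeIndex, params: AlignParams = AlignParams(),
               scheme: ScoringScheme = DEFAULT_SCHEME) -> list[Alignment]:
    """Full single-end pipeline: primary alignment plus any supplementary."""
    try:
        cands = align_single(read, index, params, scheme)
    except ValueError:
        return [unmapped_alignment(read)]
    out = rank_and_emit(cands, read, scheme)
    primary = out[0]
    if not primary.is_unmapped:
        sup = realign_clip(primary, read, index, params, scheme)
        if sup is not None:
            out.append(sup)
    return out
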