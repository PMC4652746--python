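"""Cost-ordered seed search and next-best deep scan.

Instead of extending low-cost short seeds, the aligner searches the
reference directly for the best placements of a long seed (75 bp by
default), enumerating candidate hits in increasing order of alignment cost:
up to ``mm_max`` mismatches and at most one internal gap run of length up to
``d_seed``.  The enumeration order over (mismatches, gap) *cost steps* is
precomputed from the penalty constants; scanning then reports, step by step,
every genomic position whose best placement signature equals that step.

Hit generation is a pigeonhole scheme: the seed is cut into
``mm_max + 3`` chunks, so that any placement within budget (each mismatch
breaks one chunk, a gap run of length <= chunk+1 breaks at most two) leaves
at least one chunk matching the reference exactly.  Exact chunk hits from
the genome index, expanded by the +-d_seed shift a gap can introduce,
give the complete candidate position set; every signature is then evaluated
exactly at each candidate with a vectorized cumulative-mismatch scan.  When
a seed is too short to chunk at the index k-mer size, the same evaluator
runs at every genome position instead.

After the least-cost step has produced hits, the *deep scan* keeps
enumerating further non-empty steps: the runner-up hits it surfaces both
guard against the "fewer mismatches elsewhere" trap and feed the
two-best-hit mapping quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .index import GenomeIndex, encode_seq, _exact_positions_one_chrom
from .io import Cigar, revcomp

__all__ = [
    "Penalties",
    "SearchBudget",
    "CostStep",
    "SeedHit",
    "enumerate_cost_steps",
    "reverse_align_seed",
    "deep_scan",
    "SeedScan",
    "best_signatures_at",
]

MIN_SEED_LEN = 12


@dataclass(frozen=True)
class Penalties:
    """Unit costs that define the enumeration order of cost steps.

    These order the search only; the quality-aware scheme in
    :mod:`coralign.scoring` ranks the extended alignments.
    """

    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if min(self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("penalties must be positive")

    def of(self, mismatches: int, gap_length: int) -> int:
        p = mismatches * self.mismatch
        if gap_length > 0:
            p += self.gap_open + (gap_length - 1) * self.gap_extend
        return p


@dataclass(frozen=True)
class SearchBudget:
    """Limits of the seed search space: <= mm_max mismatches, <= 1 gap <= d_seed."""

    mm_max: int = 5
    allow_gap: bool = True
    d_seed: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.mm_max <= 5):
            raise ValueError("mm_max must be in 0..5")
        if self.d_seed < 1:
            raise ValueError("d_seed must be >= 1")


@dataclass(frozen=True)
class CostStep:
    mismatches: int
    gaps: int
    gap_length: int
    rank: int
    penalty: int

    def signature(self) -> tuple[int, int, int]:
        return (self.mismatches, self.gaps, self.gap_length)


@dataclass(frozen=True)
class SeedHit:
    chrom: str
    pos: int            # 0-based leftmost reference offset of the seed placement
    strand: str         # '+' or '-'
    step: CostStep
    seed_cigar: Cigar   # in forward-reference orientation


def enumerate_cost_steps(penalties: Penalties, d_seed: int, mm_max: int = 5,
                         allow_gap: bool = True) -> list[CostStep]:
    """All (mm, gap) cost steps, sorted by non-decreasing penalty.

    Ties are broken deterministically: fewer gaps first, then fewer
    mismatches, then shorter gap.
    """
    combos: list[tuple[int, int, int]] = [(mm, 0, 0) for mm in range(mm_max + 1)]
    if allow_gap:
        combos += [(mm, 1, g) for mm in range(mm_max + 1) for g in range(1, d_seed + 1)]
    combos.sort(key=lambda c: (penalties.of(c[0], c[2]), c[1], c[0], c[2]))
    return [CostStep(mm, gaps, gl, rank, penalties.of(mm, gl))
            for rank, (mm, gaps, gl) in enumerate(combos)]


# --- exact signature evaluation at candidate positions ----------------------

def best_signatures_at(ref_enc: np.ndarray, seed_enc: np.ndarray,
                       positions: np.ndarray, budget: SearchBudget,
                       penalties: Penalties) -> dict[int, tuple[int, int, str, int]]:
    """Best placement signature of the seed at each candidate leftmost position.

    For every position p the seed can be placed ungapped (mismatch count =
    Hamming distance) or with one internal gap run: a deletion of length g
    splits the seed at j (1 <= j <= L-1) and aligns the suffix g bases
    further right; an insertion of length g omits seed bases j..j+g-1
    (1 <= j, j+g <= L-1, so the run is strictly internal).  The minimum-
    penalty signature wins; ties prefer no gap, then deletion over
    insertion, then shorter gap, then the leftmost split.

    Returns {pos: (mismatches, gap_length, gap_type, split)} for positions
    whose best signature fits the budget; gap_type is 'D', 'I' or '' and
    split is the read offset of the gap (0 when ungapped).
    """
    L = len(seed_enc)
    G = len(ref_enc)
    d = budget.d_seed if budget.allow_gap else 0
    positions = np.unique(np.asarray(positions, dtype=np.int64))
    positions = positions[(positions >= 0) & (positions <= G - L + d)]
    if len(positions) == 0:
        return {}
    # bound the (2d+1, P, L) working set for full-scan callers
    block = max(1, (1 << 22) // ((2 * d + 1) * L))
    if len(positions) > block:
        out: dict[int, tuple[int, int, str, int]] = {}
        for i in range(0, len(positions), block):
            out.update(best_signatures_at(ref_enc, seed_enc,
                                          positions[i:i + block], budget, penalties))
        return out
    P = len(positions)

    # widest gather reaches position (G - L + d) + (L - 1) + d on the right
    # and -d on the left; sentinel 5 mismatches every seed code
    pad = 2 * d + 1
    ref_pad = np.concatenate([np.full(pad, 5, np.uint8), ref_enc,
                              np.full(pad, 5, np.uint8)])
    # one gather for every diagonal offset -d..d
    offs = np.arange(-d, d + 1)
    base3 = positions[None, :, None] + np.arange(L)[None, None, :] \
        + offs[:, None, None] + pad
    r3 = ref_pad[base3]
    seed_row = seed_enc[None, None, :]
    mism3 = (r3 != seed_row) | (r3 > 3) | (seed_row > 3)
    # prefix3[o, p, j] = mismatches of seed[:j] at diagonal offset o-d
    prefix3 = np.concatenate([np.zeros((2 * d + 1, P, 1), np.int64),
                              np.cumsum(mism3, axis=2)], axis=2)

    INF = np.int64(2 ** 50)

    def pack(pen: np.ndarray, gaps: int, mm: np.ndarray, gl: int, tp: int,
             split: np.ndarray) -> np.ndarray:
        """Composite minimization key: penalty, then the deterministic tie order
        (fewer gaps, fewer mismatches, shorter gap, deletion before insertion,
        leftmost split)."""
        key = np.asarray(pen, np.int64)
        key = key * 2 + gaps
        key = key * 128 + np.asarray(mm, np.int64)
        key = key * 32 + gl
        key = key * 2 + tp
        key = key * 256 + np.asarray(split, np.int64)
        return key

    pref0 = prefix3[d]
    mm0 = pref0[:, L]
    valid0 = positions + L <= G

    best_packed = np.where(valid0, pack(mm0 * penalties.mismatch, 0, mm0, 0, 0,
                                        np.zeros(P, np.int64)), INF)
    best_info = np.zeros((P, 4), dtype=np.int64)  # mm, gap_len, type(0/1=D/2=I), split
    best_info[:, 0] = mm0

    def consider(pen, gaps, mm, gl, tp, split, valid):
        nonlocal best_packed
        packed = np.where(valid, pack(pen, gaps, mm, gl, tp, split), INF)
        upd = packed < best_packed
        if upd.any():
            best_packed = np.where(upd, packed, best_packed)
            sel = np.flatnonzero(upd)
            best_info[sel, 0] = mm[sel]
            best_info[sel, 1] = gl
            best_info[sel, 2] = tp + 1
            best_info[sel, 3] = split[sel]

    for g in range(1, d + 1):
        gap_pen = penalties.of(0, g)
        # deletion of g reference bases at split j (1 <= j <= L-1):
        # mismatches = pref0[:, j] + suffix mismatches of seed[j:] vs ref at +g
        prefg = prefix3[d + g]
        totD = pref0[:, 1:L] + (prefg[:, L:L + 1] - prefg[:, 1:L])
        jD = np.argmin(totD, axis=1)
        mmD = totD[np.arange(P), jD]
        consider(mmD * penalties.mismatch + gap_pen, 1, mmD, g, 0, jD + 1,
                 positions + L + g <= G)

        # insertion of g read bases starting at split j (1 <= j, j+g <= L-1):
        # suffix seed[j+g:] aligns to ref at offset -g
        if L - g - 1 >= 1:
            prefi = prefix3[d - g]
            js = np.arange(1, L - g)
            totI = pref0[:, js] + (prefi[:, L:L + 1] - prefi[:, js + g])
            jI = np.argmin(totI, axis=1)
            mmI = totI[np.arange(P), jI]
            consider(mmI * penalties.mismatch + gap_pen, 1, mmI, g, 1, jI + 1,
                     positions + L - g <= G)

    out: dict[int, tuple[int, int, str, int]] = {}
    for i in range(P):
        mm, gl, tp, split = best_info[i]
        if best_packed[i] >= INF or mm > budget.mm_max:
            continue
        out[int(positions[i])] = (int(mm), int(gl),
                                  "" if tp == 0 else ("D" if tp == 1 else "I"),
                                  int(split))
    return out


def _seed_cigar(L: int, mm: int, gap_len: int, gap_type: str, split: int) -> Cigar:
    if gap_len == 0:
        return Cigar.from_ops([(L, "M")])
    if gap_type == "D":
        return Cigar.from_ops([(split, "M"), (gap_len, "D"), (L - split, "M")])
    return Cigar.from_ops([(split, "M"), (gap_len, "I"), (L - split - gap_len, "M")])


def _chunk_bounds(L: int, n_chunks: int) -> list[tuple[int, int]]:
    cuts = np.linspace(0, L, n_chunks + 1).astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(n_chunks)]


class SeedScan:
    """One seed's complete cost-ordered scan over both strands.

    The full signature table is computed once; :meth:`steps` then yields
    (CostStep, hits) in enumeration order.  Penalties of yielded steps are
    non-decreasing by construction.
    """

    def __init__(self, index: GenomeIndex, seed: str,
                 budget: SearchBudget = SearchBudget(),
                 penalties: Penalties = Penalties()) -> None:
        seed = seed.upper()
        if len(seed) < MIN_SEED_LEN:
            raise ValueError(f"seed of {len(seed)} bp is unseedable (< {MIN_SEED_LEN})")
        self.index = index
        self.seed = seed
        self.budget = budget
        self.penalties = penalties
        self.cost_steps = enumerate_cost_steps(
            penalties, budget.d_seed if budget.allow_gap else 1,
            budget.mm_max, budget.allow_gap)
        self._buckets: dict[tuple[int, int, int], list[SeedHit]] = {}
        self._scan()

    # -- candidate generation -------------------------------------------
    def _candidates(self, chrom: str, seed_enc: np.ndarray) -> np.ndarray:
        L = len(seed_enc)
        b = self.budget
        n_chunks = b.mm_max + (3 if b.allow_gap else 1)
        chunk_min = L // n_chunks
        k = self.index.k
        # pigeonhole validity: chunks must be index-queryable and no gap run
        # may span three chunks
        if chunk_min < k or (b.allow_gap and b.d_seed > chunk_min + 1):
            enc = self.index.encoded[chrom]
            d = b.d_seed if b.allow_gap else 0
            return np.arange(max(0, len(enc) - L + d + 1), dtype=np.int64)
        d = b.d_seed if b.allow_gap else 0
        shifts = np.arange(-d, d + 1, dtype=np.int64)
        cands: list[np.ndarray] = []
        for s, e in _chunk_bounds(L, n_chunks):
            hits = _exact_positions_one_chrom(self.index, chrom, seed_enc[s:e])
            if len(hits):
                cands.append((hits[:, None] - s + shifts[None, :]).ravel())
        if not cands:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(cands))

    def _scan(self) -> None:
        for strand in "+-":
            oriented = self.seed if strand == "+" else revcomp(self.seed)
            seed_enc = encode_seq(oriented)
            for chrom in self.index.chrom_names():
                ref_enc = self.index.encoded[chrom]
                if len(ref_enc) < len(seed_enc) - (self.budget.d_seed
                                                   if self.budget.allow_gap else 0):
                    continue
                cand = self._candidates(chrom, seed_enc)
                sigs = best_signatures_at(ref_enc, seed_enc, cand,
                                          self.budget, self.penalties)
                for pos, (mm, gl, tp, split) in sigs.items():
                    key = (mm, 1 if gl else 0, gl)
                    hit = SeedHit(chrom=chrom, pos=pos, strand=strand,
                                  step=None,  # filled when yielded
                                  seed_cigar=_seed_cigar(len(seed_enc), mm, gl, tp, split))
                    self._buckets.setdefault(key, []).append(hit)

    # -- iteration -------------------------------------------------------
    def steps(self) -> Iterator[tuple[CostStep, list[SeedHit]]]:
        """Yield every cost step in enumeration order with its complete hit set."""
        for step in self.cost_steps:
            hits = self._buckets.get(step.signature(), [])
            hits = sorted(hits, key=lambda h: (h.strand == "-", h.chrom, h.pos))
            hits = [SeedHit(h.chrom, h.pos, h.strand, step, h.seed_cigar) for h in hits]
            yield step, hits

    def first_hits(self) -> tuple[CostStep | None, list[SeedHit]]:
        """The least-cost non-empty step and its hits (None if nothing in budget)."""
        for step, hits in self.steps():
            if hits:
                return step, hits
        return None, []


def reverse_align_seed(index: GenomeIndex, seed_read: str,
                       budget: SearchBudget = SearchBudget(),
                       penalties: Penalties = Penalties()
                       ) -> Iterator[tuple[CostStep, list[SeedHit]]]:
    """Stream (cost step, complete hit set) pairs in increasing cost order."""
    yield from SeedScan(index, seed_read, budget, penalties).steps()


def deep_scan(index: GenomeIndex, seed_read: str, first_step: CostStep,
              first_hits: Sequence[SeedHit], depth: int = 1,
              budget: SearchBudget = SearchBudget(),
              penalties: Penalties = Penalties(),
              scan: SeedScan | None = None,
              shadow_radius: int | None = None) -> list[SeedHit]:
    """Next-best hits past the least-cost step.

    If the least-cost step already produced multiple hits they are returned
    unchanged; otherwise enumeration continues for ``depth`` further cost
    steps that contain hits at *new* loci, and those hits are returned
    (possibly none).  Gap-shifted re-descriptions of the least-cost locus
    itself — placements within ``shadow_radius`` (default: the maximum gap
    length) on the same strand — are not next-best hits: they extend to the
    same alignment, so they would otherwise stall the scan before the real
    runner-up and corrupt the two-best-hit mapping quality.
    """
    if len(first_hits) > 1:
        return list(first_hits)
    if scan is None:
        scan = SeedScan(index, seed_read, budget, penalties)
    if shadow_radius is None:
        shadow_radius = budget.d_seed if budget.allow_gap else 1

    def is_shadow(h: SeedHit) -> bool:
        return any(f.chrom == h.chrom and f.strand == h.strand
                   and abs(f.pos - h.pos) <= shadow_radius for f in first_hits)

    extra: list[SeedHit] = []
    seen_fresh = 0
    for step, hits in scan.steps():
        if step.rank <= first_step.rank:
            continue
        fresh = [h for h in hits if not is_shadow(h)]
        if fresh:
            extra.extend(fresh)
            seen_fresh += 1
            if seen_fresh >= depth:
                break
    return extra
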