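"""Seed extension: one-gap semi-global alignment with an affine-SW fallback.

The default extension aligns the whole read inside a reference window
allowing at most one internal gap run (of length <= d): conceptually the
read is divided into two halves, the gap is assumed to be in one of them,
the other half must then align mismatch-only, and the displaced half is
tried j = 1..d bases away.  Implemented here as a vectorized maximization
over (window placement, gap length, gap side, split point) — exactly the
optimum over that restricted alignment class under the quality-aware score.

When the semi-global score drops below 90% of the read's maximum attainable
score (the all-match score), the extension falls back to a full affine-gap
local alignment: a score-only pass finds the best cell, then a banded
traceback recovers the CIGAR; bases outside the local alignment become soft
clips.  The fallback is rationed per read (``sw_budget``), stops early when
the best score stalls (``stall_limit``), and skips the costly traceback for
candidates that already score below the current best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .index import encode_seq
from .io import Cigar, revcomp
from .scoring import DEFAULT_SCHEME, ScoringScheme, max_score
from .seedsearch import SeedHit

__all__ = [
    "DpParams",
    "ExtensionResult",
    "ExtendedCandidate",
    "SwBudget",
    "semi_global_one_gap",
    "sw_score",
    "banded_traceback",
    "extend_hit",
]

NEG = -1e18


@dataclass
class DpParams:
    """Extension tunables: max indel d, traceback band, SW rationing."""

    d: int = 30
    band: int = 16
    band_max: int = 256
    sw_budget: int = 32
    stall_limit: int = 8
    semiglobal_fraction: float = 0.9  # SW fallback threshold vs max score

    def __post_init__(self) -> None:
        if min(self.d, self.band, self.band_max, self.sw_budget, self.stall_limit) <= 0:
            raise ValueError("DpParams fields must be positive")


@dataclass
class ExtensionResult:
    cigar: Cigar
    score: float
    method: str                 # 'semiglobal' or 'sw'
    ref_start: int              # 0-based half-open, window coordinates
    ref_end: int
    clip_left: int = 0
    clip_right: int = 0


@dataclass
class ExtendedCandidate:
    """A seed hit extended to a full-read alignment (chromosome coordinates)."""

    chrom: str
    pos: int
    strand: str
    result: ExtensionResult
    hit: SeedHit | None = None

    @property
    def score(self) -> float:
        return self.result.score


@dataclass
class SwBudget:
    """Per-read SW rationing state shared across a read's candidate hits."""

    sw_budget: int = 32
    stall_limit: int = 8
    used: int = 0
    stall: int = 0
    best_sw: float = NEG
    tracebacks: int = 0

    def exhausted(self) -> bool:
        return self.used >= self.sw_budget or self.stall >= self.stall_limit


def _col_scores(read: str, quals, scheme: ScoringScheme):
    """Per-read-position match bonus and mismatch penalty vectors."""
    q = np.asarray(list(quals), dtype=float)
    mb = scheme.match_bonus(q).astype(float)
    mp = scheme.mismatch_penalty(q).astype(float)
    mp0 = float(scheme.mismatch_penalty(0))
    return encode_seq(read.upper()), mb, mp, mp0


def semi_global_one_gap(read: str, quals, ref_window: str, d: int,
                        scheme: ScoringScheme = DEFAULT_SCHEME) -> ExtensionResult:
    """Best full-length placement of the read with at most one gap run <= d.

    The read is never clipped: all L bases are aligned (inserted bases score
    as a gap).  Ties prefer no gap, then shorter gap, deletion before
    insertion, then the leftmost window placement and split.
    """
    L = len(read)
    W = len(ref_window)
    if W < L:
        raise ValueError(f"window of {W} bp shorter than read of {L} bp")
    enc_read, mb, mp, mp0 = _col_scores(read, quals, scheme)
    enc_ref = encode_seq(ref_window.upper())

    positions = np.arange(0, W - L + d + 1, dtype=np.int64)
    P = len(positions)
    pad = 2 * d + 1
    ref_pad = np.concatenate([np.full(pad, 5, np.uint8), enc_ref,
                              np.full(pad, 5, np.uint8)])
    base = positions[:, None] + np.arange(L)[None, :] + pad
    seed_row = enc_read[None, :]

    def pref_at(offset: int) -> np.ndarray:
        """Cumulative column scores of the read against ref shifted by offset:
        out[p, j] = score of read[:j] aligned at pos+offset."""
        r = ref_pad[base + offset]
        n_col = (r > 3) | (seed_row > 3)
        eq = (r == seed_row) & ~n_col
        col = np.where(eq, mb[None, :], -np.where(n_col, mp0, mp[None, :]))
        return np.concatenate([np.zeros((P, 1)), np.cumsum(col, axis=1)], axis=1)

    pref0 = pref_at(0)
    all_match = float(np.sum(mb))

    best_score = NEG
    best_make = None

    s0 = np.where(positions + L <= W, pref0[:, L], NEG)
    i = int(np.argmax(s0))
    if s0[i] > best_score:
        best_score = float(s0[i])
        best_make = (int(positions[i]), Cigar.from_ops([(L, "M")]), 0)

    for g in range(1, d + 1):
        # no alignment with a length-g gap can beat all-match minus its gap
        # cost, so once the running best reaches that bound we can stop
        if best_score >= all_match - scheme.gap_cost(g):
            break
        gcost = scheme.gap_cost(g)
        # deletion: suffix scored g further right, split j in 1..L-1
        prefg = pref_at(g)
        totD = pref0[:, 1:L] + (prefg[:, L:L + 1] - prefg[:, 1:L]) - gcost
        vD = (positions + L + g <= W)[:, None]
        totD = np.where(vD, totD, NEG)
        i = int(np.argmax(totD))
        if totD.flat[i] > best_score + 1e-12:
            p, j = divmod(i, L - 1)
            j += 1
            best_score = float(totD.flat[i])
            best_make = (int(positions[p]),
                         Cigar.from_ops([(j, "M"), (g, "D"), (L - j, "M")]), g)

        # insertion: read bases j..j+g-1 unaligned, split j in 0..L-g (runs
        # touching the read boundary included — the unconstrained optimum can
        # leave edge bases gapped when no window base suits them)
        if L - g >= 1:
            prefi = pref_at(-g)
            js = np.arange(0, L - g + 1)
            totI = pref0[:, js] + (prefi[:, L:L + 1] - prefi[:, js + g]) - gcost
            vI = (positions + L - g <= W)[:, None]
            totI = np.where(vI, totI, NEG)
            i = int(np.argmax(totI))
            if totI.flat[i] > best_score + 1e-12:
                p, j = divmod(i, len(js))
                best_score = float(totI.flat[i])
                best_make = (int(positions[p]),
                             Cigar.from_ops([(j, "M"), (g, "I"), (L - j - g, "M")]),
                             -g)

    if best_score <= NEG / 2 or best_make is None:
        raise ValueError("no valid placement of the read in the window")
    pos, cig, gdelta = best_make
    return ExtensionResult(cigar=cig, score=best_score, method="semiglobal",
                           ref_start=pos, ref_end=pos + L + max(gdelta, 0)
                           - max(-gdelta, 0))


def _sub_matrix_row(enc_read_i: int, mb_i: float, mp_i: float, mp0: float,
                    enc_ref: np.ndarray) -> np.ndarray:
    n_col = (enc_ref > 3) | (enc_read_i > 3)
    eq = (enc_ref == enc_read_i) & ~n_col
    return np.where(eq, mb_i, -np.where(n_col, mp0, mp_i))


def sw_score(read: str, quals, ref_window: str,
             scheme: ScoringScheme = DEFAULT_SCHEME) -> tuple[float, tuple[int, int]]:
    """Affine-gap local alignment optimum (score only) with its end cell.

    Returns (score, (read_end, ref_end)) where the ends are 1-based counts of
    consumed read/reference bases at the best cell.  A score of 0 means no
    positive-scoring local alignment exists.
    """
    enc_read, mb, mp, mp0 = _col_scores(read, quals, scheme)
    enc_ref = encode_seq(ref_window.upper())
    n, m = len(enc_read), len(enc_ref)
    if n == 0 or m == 0:
        raise ValueError("empty input to sw_score")
    open_, ext = scheme.gap_open, scheme.gap_extend

    H_prev = np.zeros(m + 1)
    F_prev = np.full(m + 1, NEG)
    jj = np.arange(m + 1, dtype=float)
    best, best_cell = 0.0, (0, 0)
    for i in range(1, n + 1):
        sub = _sub_matrix_row(enc_read[i - 1], mb[i - 1], mp[i - 1], mp0, enc_ref)
        F = np.maximum(H_prev - open_, F_prev - ext)
        Hp = np.zeros(m + 1)
        Hp[1:] = np.maximum.reduce([np.zeros(m), H_prev[:-1] + sub, F[1:]])
        # E[j] = max_{k<=j-1}(Hp[k] - open - ext*(j-1-k)); chained horizontal
        # gaps never beat one longer gap because gap_open >= gap_extend
        run = np.maximum.accumulate(Hp + ext * jj)
        E = np.full(m + 1, NEG)
        E[1:] = run[:-1] - open_ - ext * (jj[1:] - 1)
        H = np.maximum(Hp, E)
        H[0] = 0.0
        j_best = int(np.argmax(H))
        if H[j_best] > best + 1e-12:
            best, best_cell = float(H[j_best]), (i, j_best)
        H_prev, F_prev = H, F
    return best, best_cell


def banded_traceback(read: str, quals, ref_window: str, end_coords: tuple[int, int],
                     band: int, scheme: ScoringScheme = DEFAULT_SCHEME,
                     expected_score: float | None = None,
                     band_max: int = 256) -> ExtensionResult:
    """Recover the optimal local-alignment CIGAR by a banded affine DP.

    The band is centered on the diagonal through the end cell; if the banded
    score disagrees with the score-only pass the band doubles (up to
    ``band_max``) before the alignment is rejected as an internal error.
    """
    if expected_score is None:
        expected_score, end_coords = sw_score(read, quals, ref_window, scheme)
    ie, je = end_coords
    if expected_score <= 0 or ie == 0:
        raise ValueError("no positive local alignment to trace back")
    while True:
        res = _banded_tb_once(read, quals, ref_window, ie, je, band, scheme)
        if res is not None and abs(res.score - expected_score) < 1e-6:
            return res
        if band >= band_max:
            raise RuntimeError(
                f"banded traceback (band {band}) cannot reach score {expected_score}")
        band = min(2 * band, band_max)


def _banded_tb_once(read: str, quals, ref_window: str, ie: int, je: int,
                    band: int, scheme: ScoringScheme) -> ExtensionResult | None:
    enc_read, mb, mp, mp0 = _col_scores(read, quals, scheme)
    enc_ref = encode_seq(ref_window.upper())
    open_, ext = scheme.gap_open, scheme.gap_extend
    diag = je - ie

    H: dict[tuple[int, int], float] = {}
    E: dict[tuple[int, int], float] = {}
    F: dict[tuple[int, int], float] = {}
    ptrH: dict[tuple[int, int], str] = {}
    ptrE: dict[tuple[int, int], bool] = {}  # True: opened from H
    ptrF: dict[tuple[int, int], bool] = {}

    def getH(i, j):
        if i == 0 or j == 0:
            return 0.0
        return H.get((i, j), NEG)

    for i in range(1, ie + 1):
        lo = max(1, i + diag - band)
        hi = min(je, i + diag + band)
        if lo > hi:
            continue
        subrow = _sub_matrix_row(int(enc_read[i - 1]), float(mb[i - 1]),
                                 float(mp[i - 1]), mp0,
                                 enc_ref[lo - 1:hi]).tolist()
        for j in range(lo, hi + 1):
            sub = subrow[j - lo]
            # F: vertical, consumes read base (I)
            f_open = getH(i - 1, j) - open_
            f_ext = F.get((i - 1, j), NEG) - ext
            fv = max(f_open, f_ext)
            F[(i, j)] = fv
            ptrF[(i, j)] = f_open >= f_ext
            # E: horizontal, consumes ref base (D)
            e_open = getH(i, j - 1) - open_
            e_ext = E.get((i, j - 1), NEG) - ext
            ev = max(e_open, e_ext)
            E[(i, j)] = ev
            ptrE[(i, j)] = e_open >= e_ext
            dv = getH(i - 1, j - 1) + float(sub)
            hv = max(0.0, dv, ev, fv)
            H[(i, j)] = hv
            if hv == 0.0:
                ptrH[(i, j)] = "0"
            elif hv == dv:
                ptrH[(i, j)] = "M"
            elif hv == ev:
                ptrH[(i, j)] = "E"
            else:
                ptrH[(i, j)] = "F"

    score = H.get((ie, je), NEG)
    if score <= NEG / 2:
        return None

    ops: list[tuple[int, str]] = []
    state, i, j = "H", ie, je
    while True:
        if state == "H":
            p = ptrH.get((i, j), "0")
            if p == "0" or i == 0 or j == 0:
                break
            if p == "M":
                ops.append((1, "M"))
                i, j = i - 1, j - 1
            elif p == "E":
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append((1, "D"))
            opened = ptrE[(i, j)]
            j -= 1
            if opened:
                state = "H"
        else:  # F
            ops.append((1, "I"))
            opened = ptrF[(i, j)]
            i -= 1
            if opened:
                state = "H"
    read_len = len(read)
    clip_left, clip_right = i, read_len - ie
    full_ops = ([(clip_left, "S")] if clip_left else []) + ops[::-1] \
        + ([(clip_right, "S")] if clip_right else [])
    cigar = Cigar.from_ops(full_ops)
    return ExtensionResult(cigar=cigar, score=float(score), method="sw",
                           ref_start=j, ref_end=je,
                           clip_left=clip_left, clip_right=clip_right)


def extend_hit(read: str, quals, seed_hit: SeedHit, index, params: DpParams,
               scheme: ScoringScheme = DEFAULT_SCHEME,
               budget: SwBudget | None = None,
               seed_offset: int = 0) -> ExtendedCandidate:
    """Extend one seed hit to a full-read alignment.

    Runs the one-gap semi-global extension first; if its score falls below
    ``semiglobal_fraction`` of the read's all-match score, an affine SW
    local alignment is attempted instead, subject to the shared per-read
    ``budget`` (when the budget is spent, or the SW score cannot beat the
    running best, the semi-global result is kept).
    """
    L = len(read)
    chrom_seq = index.genome[seed_hit.chrom]
    if seed_hit.strand == "-":
        oread = revcomp(read)
        oquals = list(quals)[::-1]
        seed_len = seed_hit.seed_cigar.read_len
        oso = L - seed_offset - seed_len
    else:
        oread, oquals, oso = read, list(quals), seed_offset
    read_left = seed_hit.pos - oso
    pad = params.d + 4
    w_start = max(0, read_left - pad)
    w_end = min(len(chrom_seq), read_left + L + pad)
    window = chrom_seq[w_start:w_end]

    ms = max_score(oquals, scheme)
    semi: ExtensionResult | None = None
    if len(window) >= L:
        semi = semi_global_one_gap(oread, oquals, window, params.d, scheme)
        if semi.score >= params.semiglobal_fraction * ms:
            return ExtendedCandidate(chrom=seed_hit.chrom, pos=w_start + semi.ref_start,
                                     strand=seed_hit.strand, result=semi, hit=seed_hit)

    if budget is None:
        budget = SwBudget(sw_budget=params.sw_budget, stall_limit=params.stall_limit)
    if budget.exhausted() and semi is not None:
        return ExtendedCandidate(seed_hit.chrom, w_start + semi.ref_start,
                                 seed_hit.strand, semi, seed_hit)

    score, end = sw_score(oread, oquals, window, scheme)
    budget.used += 1
    prev_best = budget.best_sw
    if score <= prev_best:
        budget.stall += 1
    else:
        budget.best_sw = score
        budget.stall = 0
    # traceback skipped only when strictly below the running best: an
    # equal-scoring candidate is a genuine tie and must keep its CIGAR so the
    # two-best-hit mapQ sees it
    if score < prev_best and semi is not None:
        return ExtendedCandidate(seed_hit.chrom, w_start + semi.ref_start,
                                 seed_hit.strand, semi, seed_hit)

    if score <= 0:
        # nothing alignable locally; fall back to whatever semi-global found
        if semi is not None:
            return ExtendedCandidate(seed_hit.chrom, w_start + semi.ref_start,
                                     seed_hit.strand, semi, seed_hit)
        raise ValueError("window shorter than read and no local alignment")
    budget.tracebacks += 1
    res = banded_traceback(oread, oquals, window, end, params.band, scheme,
                           expected_score=score, band_max=params.band_max)
    if semi is not None and semi.score > res.score:
        return ExtendedCandidate(seed_hit.chrom, w_start + semi.ref_start,
                                 seed_hit.strand, semi, seed_hit)
    return ExtendedCandidate(chrom=seed_hit.chrom, pos=w_start + res.ref_start,
                             strand=seed_hit.strand, result=res, hit=seed_hit)
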