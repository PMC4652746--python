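"""Independent reference implementations used to verify the aligner.

Everything here recomputes results from first principles — full-matrix
scans and textbook dynamic programming — sharing no code path with the
package internals it checks.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def naive_exact_scan(ref: str, pattern: str) -> set[int]:
    """All occurrences of pattern (over ACGT) in ref; N matches nothing."""
    out = set()
    m = len(pattern)
    for p in range(len(ref) - m + 1):
        seg = ref[p:p + m]
        if seg == pattern and "N" not in seg:
            out.add(p)
    return out


def naive_hamming_scan(ref: str, pattern: str, k: int) -> set[tuple[int, int]]:
    """(position, mismatches) for every placement within Hamming distance k."""
    out = set()
    m = len(pattern)
    for p in range(len(ref) - m + 1):
        mm = sum(1 for a, b in zip(pattern, ref[p:p + m])
                 if a != b or a == "N" or b == "N")
        if mm <= k:
            out.add((p, mm))
    return out


def brute_signature_scan(ref: str, seed: str, mm_max: int = 5, d: int = 10,
                         allow_gap: bool = True,
                         mismatch_pen: int = 4, open_pen: int = 6, ext_pen: int = 1
                         ) -> dict[int, tuple[int, int, str, int]]:
    """Best (minimal-penalty) placement signature of the seed at every
    reference position, by exhaustive evaluation.

    Signatures are (mismatches, gap_length, gap_type, split): the ungapped
    Hamming count, or one internal run of g deleted reference bases at split
    j (1 <= j <= L-1), or one run of g unaligned (inserted) seed bases at
    split j (1 <= j, j+g <= L-1).  Ties prefer no gap, then fewer
    mismatches, then shorter gap, deletion before insertion, leftmost split.
    Positions whose best signature exceeds mm_max are omitted.
    """
    L, G = len(seed), len(ref)
    if not allow_gap:
        d = 0
    # pad with N (mismatches everything) so shifted windows stay in range;
    # validity of each placement is enforced separately below
    padded = "N" * d + ref + "N" * (2 * d)
    enc_pad = np.array([_CODE[c] for c in padded], dtype=np.int64)
    enc_seed = np.array([_CODE[c] for c in seed], dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc_pad, L)
    P = np.arange(0, G - L + d + 1)

    def mism_rows(offset: int) -> np.ndarray:
        rows = win[P + offset + d]
        return ((rows != enc_seed[None, :]) | (rows == 4)
                | (enc_seed[None, :] == 4)).astype(np.int64)

    def penal(mm: np.ndarray, g: int) -> np.ndarray:
        return mm * mismatch_pen + (open_pen + (g - 1) * ext_pen if g else 0)

    TCODE = {"": 0, "D": 1, "I": 2}
    BIG = 10 ** 9
    nP = len(P)
    # lexicographic best per position over (penalty, gaps, mm, gap_len, type, split)
    fields = {name: np.full(nP, BIG, dtype=np.int64)
              for name in ("pen", "gaps", "mm", "g", "t", "split")}

    def offer_vec(mm: np.ndarray, g: int, typ: str, split: int, valid: np.ndarray):
        pen = np.where(valid, penal(mm, g), BIG)
        cand = {"pen": pen, "gaps": np.int64(1 if g else 0), "mm": mm,
                "g": np.int64(g), "t": np.int64(TCODE[typ]),
                "split": np.int64(split)}
        better = np.zeros(nP, dtype=bool)
        tied = np.ones(nP, dtype=bool)
        for name in ("pen", "gaps", "mm", "g", "t", "split"):
            better |= tied & (cand[name] < fields[name])
            tied &= cand[name] == fields[name]
        better &= valid
        if better.any():
            for name in fields:
                fields[name] = np.where(better, cand[name], fields[name])

    m0 = mism_rows(0)
    mm_ungapped = m0.sum(axis=1)
    offer_vec(mm_ungapped, 0, "", 0, P + L <= G)

    for g in range(1, d + 1):
        mg = mism_rows(g)
        valid_d = P + L + g <= G
        # deletion at split j: prefix j columns unshifted + suffix shifted by g;
        # walk j upward transferring one column at a time
        mm = mg.sum(axis=1)  # j = 0 would be a boundary gap; start transfers at j=1
        for j in range(1, L):
            mm = mm - mg[:, j - 1] + m0[:, j - 1]
            offer_vec(mm, g, "D", j, valid_d)
        if L - g - 1 >= 1:
            mi = mism_rows(-g)
            valid_i = P + L - g <= G
            # insertion at split j: prefix j columns + suffix from j+g shifted by -g
            mm = mi[:, g:].sum(axis=1)
            for j in range(1, L - g):
                mm = mm - mi[:, j + g - 1] + m0[:, j - 1]
                offer_vec(mm, g, "I", j, valid_i)

    out: dict[int, tuple[int, int, str, int]] = {}
    tname = {0: "", 1: "D", 2: "I"}
    for idx, p in enumerate(P):
        if fields["pen"][idx] >= BIG or fields["mm"][idx] > mm_max:
            continue
        out[int(p)] = (int(fields["mm"][idx]), int(fields["g"][idx]),
                       tname[int(fields["t"][idx])], int(fields["split"][idx]))
    return out


def gotoh_local(read: str, quals: list[int], ref: str, scheme) -> float:
    """Textbook affine-gap local alignment (Smith-Waterman-Gotoh), plain
    Python, quality-aware substitution scores."""
    n, m = len(read), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(read[i - 1], ref[j - 1], quals[i - 1], scheme)
            E[i][j] = max(H[i][j - 1] - scheme.gap_open, E[i][j - 1] - scheme.gap_extend)
            F[i][j] = max(H[i - 1][j] - scheme.gap_open, F[i - 1][j] - scheme.gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def gotoh_semiglobal(read: str, quals: list[int], ref: str, scheme
                     ) -> tuple[float, int, int]:
    """Affine DP, read aligned end-to-end, free start/end in the reference.

    Returns (score, number of gap runs, longest gap run) of the optimum, via
    pointer traceback, so callers can tell whether the optimum lies inside
    the one-gap class.
    """
    n, m = len(read), len(ref)
    NEG = float("-inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            if j > 0:
                E[i][j] = max(H[i][j - 1] - scheme.gap_open,
                              E[i][j - 1] - scheme.gap_extend)
            F[i][j] = max(H[i - 1][j] - scheme.gap_open, F[i - 1][j] - scheme.gap_extend)
            cand = [E[i][j], F[i][j]]
            if j > 0 and H[i - 1][j - 1] > NEG:
                cand.append(H[i - 1][j - 1]
                            + _sub(read[i - 1], ref[j - 1], quals[i - 1], scheme))
            H[i][j] = max(cand)
    je = max(range(m + 1), key=lambda j: H[n][j])
    score = H[n][je]
    # traceback to count gap runs
    i, j, state = n, je, "H"
    runs, cur_run, longest = 0, 0, 0
    while i > 0:
        if state == "H":
            if j > 0 and H[i][j] == E[i][j]:
                state, runs = "E", runs + 1
                cur_run = 0
            elif H[i][j] == F[i][j]:
                state, runs = "F", runs + 1
                cur_run = 0
            else:
                i, j = i - 1, j - 1
        elif state == "E":
            cur_run += 1
            longest = max(longest, cur_run)
            if H[i][j - 1] - scheme.gap_open >= E[i][j - 1] - scheme.gap_extend:
                state = "H"
            j -= 1
        else:
            cur_run += 1
            longest = max(longest, cur_run)
            if H[i - 1][j] - scheme.gap_open >= F[i - 1][j] - scheme.gap_extend:
                state = "H"
            i -= 1
    return score, runs, longest


def _sub(rb: str, gb: str, q: int, scheme) -> float:
    if rb == "N" or gb == "N":
        return -float(scheme.mismatch_penalty(0))
    if rb == gb:
        return float(scheme.match_bonus(q))
    return -float(scheme.mismatch_penalty(q))


def column_score(read: str, quals: list[int], cigar_ops, ref_slice: str, scheme
                 ) -> float:
    """Per-column recomputation of the quality-aware alignment score."""
    score, ri, gi = 0.0, 0, 0
    for n, c in cigar_ops:
        if c == "S":
            ri += n
        elif c == "M":
            for k in range(n):
                score += _sub(read[ri + k], ref_slice[gi + k], quals[ri + k], scheme)
            ri += n
            gi += n
        elif c == "I":
            score -= scheme.gap_open + (n - 1) * scheme.gap_extend
            ri += n
        elif c == "D":
            score -= scheme.gap_open + (n - 1) * scheme.gap_extend
            gi += n
    return score


def locus_scores(read: str, quals: list[int], ref: str, scheme) -> np.ndarray:
    """Gapless quality-aware score of the read at every reference offset —
    the all-locus scoring oracle for ranking checks on substitution-only
    fixtures (vectorized sliding-window scan)."""
    enc_ref = np.array([_CODE[c] for c in ref], dtype=np.int64)
    enc_read = np.array([_CODE[c] for c in read], dtype=np.int64)
    q = np.asarray(quals, dtype=float)
    mb = np.asarray(scheme.match_bonus(q), dtype=float)
    mp = np.asarray(scheme.mismatch_penalty(q), dtype=float)
    mp0 = float(scheme.mismatch_penalty(0))
    win = np.lib.stride_tricks.sliding_window_view(enc_ref, len(read))
    n_col = (win == 4) | (enc_read[None, :] == 4)
    eq = (win == enc_read[None, :]) & ~n_col
    col = np.where(eq, mb[None, :], -np.where(n_col, mp0, mp[None, :]))
    return col.sum(axis=1)
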