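"""Quality-aware alignment scoring and mapping quality.

The score of an aligned column depends on the base-call quality Q[i] of the
read base: a confident base (high Q) earns more for a match and costs more
for a mismatch, because a mismatch there is more likely a true variant or a
wrong placement than a sequencing error.  Gaps are charged with an affine
open/extend penalty.  Mapping quality (mapQ) is derived from the two best
candidate scores of a read: a large score margin means the placement is
trustworthy, a tie means ambiguity (mapQ 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ScoringScheme",
    "base_correct_prob",
    "miscall_prob_per_base",
    "alignment_score",
    "max_score",
    "compute_mapq",
]


def base_correct_prob(q) -> float:
    """P[i] = 1 - 10^(-Q[i]/10): probability the base call at i is correct."""
    return 1.0 - 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def miscall_prob_per_base(q) -> float:
    """(1 - P[i]) / 3: probability of one *specific* wrong base at i.

    Assumes no bias toward any particular nucleotide, so the total miscall
    probability 1 - P[i] is split evenly over the three wrong bases.
    """
    return (1.0 - base_correct_prob(q)) / 3.0


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap, quality-aware scoring constants.

    match/mismatch weights are simple Phred-inspired step functions of Q
    (exact constants are a package choice, exposed in config):

    * match_bonus(Q)      = ``match_hi`` for Q >= ``match_q_threshold`` else ``match_lo``
    * mismatch_penalty(Q) = max(``mismatch_min``, min(Q, ``q_cap``) / ``mismatch_div``)

    A gap run of length L costs ``gap_open + (L-1) * gap_extend``.
    Soft-clipped bases contribute 0.  An N base (read or reference) is a
    mismatch scored at Q = 0.
    """

    match_hi: float = 2.0
    match_lo: float = 1.0
    match_q_threshold: int = 10
    mismatch_min: float = 2.0
    mismatch_div: float = 5.0
    q_cap: int = 40
    gap_open: float = 12.0
    gap_extend: float = 2.0
    mapq_scale: float = 2.0
    mapq_max: int = 60
    # fraction of max_score used as the implicit runner-up when none exists
    floor_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_extend <= 0 or self.gap_open < self.gap_extend:
            raise ValueError("need gap_open >= gap_extend > 0")

    def match_bonus(self, q) -> np.ndarray:
        q = np.asarray(q)
        return np.where(q >= self.match_q_threshold, self.match_hi, self.match_lo)

    def mismatch_penalty(self, q) -> np.ndarray:
        q = np.minimum(np.asarray(q, dtype=float), self.q_cap)
        return np.maximum(self.mismatch_min, q / self.mismatch_div)

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        return self.gap_open + (length - 1) * self.gap_extend

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScoringScheme":
        return cls(**json.loads(text))


DEFAULT_SCHEME = ScoringScheme()


def max_score(quals, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Score of a perfect, gapless, unclipped alignment of the read."""
    return float(np.sum(scheme.match_bonus(np.asarray(quals))))


def alignment_score(read: str, quals, cigar, ref_slice: str,
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Recompute the quality-aware affine score of an explicit alignment.

    ``ref_slice`` must be exactly the reference bases the CIGAR consumes
    (M+D columns).  Raises ValueError on a CIGAR inconsistent with the
    read/reference lengths.
    """
    quals = list(quals)
    if cigar.read_len != len(read):
        raise ValueError(f"CIGAR {cigar} does not consume read of length {len(read)}")
    if cigar.ref_len != len(ref_slice):
        raise ValueError(f"CIGAR {cigar} does not consume ref slice of length {len(ref_slice)}")
    score = 0.0
    ri = 0  # read cursor
    gi = 0  # ref cursor
    for n, code in cigar.ops:
        if code == "S":
            ri += n
        elif code == "M":
            for k in range(n):
                b, r = read[ri + k], ref_slice[gi + k]
                q = quals[ri + k]
                if b == "N" or r == "N":
                    score -= float(scheme.mismatch_penalty(0))
                elif b == r:
                    score += float(scheme.match_bonus(q))
                else:
                    score -= float(scheme.mismatch_penalty(q))
            ri += n
            gi += n
        elif code == "I":
            score -= scheme.gap_cost(n)
            ri += n
        elif code == "D":
            score -= scheme.gap_cost(n)
            gi += n
        else:  # pragma: no cover - Cigar.validate rejects other codes
            raise ValueError(f"unsupported CIGAR code {code}")
    return score


def compute_mapq(best_score: float, second_score: float | None, max_score_value: float,
                 repeat_flag: bool = False,
                 scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Mapping quality from the two best candidate scores.

    * ambiguous placements (repeat_flag, or a score tie) -> 0
    * no runner-up: margin measured against ``floor_fraction * max_score``
    * otherwise: margin = best - second, scaled and capped at ``mapq_max``
    """
    if repeat_flag:
        return 0
    if second_score is None:
        margin = best_score - scheme.floor_fraction * max_score_value
    else:
        if second_score > best_score:
            raise ValueError("second_score exceeds best_score")
        margin = best_score - second_score
    q = int(round(scheme.mapq_scale * margin))
    return max(0, min(scheme.mapq_max, q))
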