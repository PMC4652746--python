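"""Alignment evaluation: correctness rule, mapQ-stratified ROC, F-measure,
and the concordance/discordance proxy used when no truth exists.

A primary alignment is *correct* when it lands on the truth chromosome and
strand with its leftmost position within 50 bp of the simulated origin (the
slack absorbs indel left-shifting and soft clips).  Ambiguous mappings
(mapQ = 0) are discarded before scoring.  Sensitivity = TP/(TP+FN),
accuracy = TP/(TP+FP) (used interchangeably with specificity in labels, as
there are no true negatives in simulation), and the F-measure is their
harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pipeline_single import Alignment
from .simulate import TruthRecord

__all__ = ["EvalSummary", "is_correct", "roc_by_mapq", "f_measure",
           "concordance_eval", "POSITION_TOLERANCE"]

POSITION_TOLERANCE = 50  # bp slack of the correctness rule
CONCORDANCE_DIST = 1000  # bp; pairs further apart count as discordant
CONCORDANCE_MAPQ = 10    # both ends must exceed this


@dataclass
class EvalSummary:
    """Cumulative (correct, wrong) counts by decreasing mapQ plus the
    full-spectrum sensitivity/accuracy/F."""

    points: list[tuple[int, int, int]] = field(default_factory=list)  # (mapq, cum_ok, cum_bad)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    sen: float = 0.0
    acc: float = 0.0
    f: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["mapq", "cum_correct", "cum_wrong"])


def is_correct(alignment: Alignment, truth: TruthRecord) -> bool:
    """Same chromosome and strand, leftmost position within 50 bp of truth."""
    if truth is None:
        raise ValueError(f"no truth record for read {alignment.read_id}")
    if alignment.is_unmapped:
        return False
    return (alignment.chrom == truth.chrom and alignment.strand == truth.strand
            and abs(alignment.pos - truth.pos) <= POSITION_TOLERANCE)


def f_measure(sen: float, acc: float) -> float:
    """Harmonic mean 2*SEN*ACC/(SEN+ACC); 0 when both are 0."""
    if sen == 0.0 and acc == 0.0:
        return 0.0
    return 2.0 * sen * acc / (sen + acc)


def roc_by_mapq(alignments: list[Alignment], truths: dict[str, TruthRecord]
                ) -> EvalSummary:
    """Cumulative correct/wrong counts by decreasing mapQ over primaries.

    mapQ = 0 alignments are dropped as ambiguous.  FN counts simulated reads
    with no mapQ > 0 primary alignment.
    """
    scored: list[tuple[int, bool]] = []
    seen: set[str] = set()
    for aln in alignments:
        if aln.is_supplementary:
            continue
        seen.add(aln.read_id)
        if aln.is_unmapped or aln.mapq == 0:
            continue
        scored.append((aln.mapq, is_correct(aln, truths.get(aln.read_id))))
    summary = EvalSummary()
    summary.tp = sum(1 for _, ok in scored if ok)
    summary.fp = len(scored) - summary.tp
    summary.fn = len(truths) - len(scored)
    scored.sort(key=lambda t: -t[0])
    cum_ok = cum_bad = 0
    i = 0
    while i < len(scored):
        q = scored[i][0]
        while i < len(scored) and scored[i][0] == q:
            cum_ok += scored[i][1]
            cum_bad += not scored[i][1]
            i += 1
        summary.points.append((q, cum_ok, cum_bad))
    denom_sen = summary.tp + summary.fn
    denom_acc = summary.tp + summary.fp
    summary.sen = summary.tp / denom_sen if denom_sen else 0.0
    summary.acc = summary.tp / denom_acc if denom_acc else 0.0
    summary.f = f_measure(summary.sen, summary.acc)
    return summary


def concordance_eval(alignments: list[Alignment]) -> pd.DataFrame:
    """Concordant/discordant pair counts from single-end alignments.

    Input: primary single-end alignments of paired reads (``read_index`` 1
    or 2 identifies the ends; ids match within a pair).  A pair is
    concordant iff both ends map on the same chromosome in FR orientation
    within 1000 bp of each other and both have mapQ > 10; both-mapped pairs
    failing any clause are discordant; pairs with an unmapped end are
    excluded.  Counts are cumulative, stratified by the head (read 1) mapQ.
    """
    ends: dict[str, dict[int, Alignment]] = {}
    for aln in alignments:
        if aln.is_supplementary:
            continue
        ends.setdefault(aln.read_id, {})[aln.read_index] = aln

    rows: list[tuple[int, bool]] = []
    for rid, pair in ends.items():
        if 1 not in pair or 2 not in pair:
            continue
        a1, a2 = pair[1], pair[2]
        if a1.is_unmapped or a2.is_unmapped:
            continue
        conc = False
        if a1.chrom == a2.chrom and a1.strand != a2.strand:
            fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
            conc = (fwd.pos <= rev.pos
                    and abs(a1.pos - a2.pos) <= CONCORDANCE_DIST
                    and a1.mapq > CONCORDANCE_MAPQ and a2.mapq > CONCORDANCE_MAPQ)
        rows.append((a1.mapq, conc))

    rows.sort(key=lambda t: -t[0])
    out = []
    cum_c = cum_d = 0
    i = 0
    while i < len(rows):
        q = rows[i][0]
        while i < len(rows) and rows[i][0] == q:
            cum_c += rows[i][1]
            cum_d += not rows[i][1]
            i += 1
        out.append((q, cum_c, cum_d))
    return pd.DataFrame(out, columns=["head_mapq", "cum_concordant", "cum_discordant"])
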