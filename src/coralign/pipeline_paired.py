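"""Unbiased paired-end mapping.

Both ends are first aligned independently, exactly as single-end reads.
Mate-pair information is applied only afterwards, and alignment scores
always precede it: a pair whose two ends are each confidently and uniquely
placed is reported as-is even when the placements are discordant (that is
the structural-variant signal), never displaced by a weaker combination
that happens to fit the insert-size model.  Pairing information is used
where it is legitimately informative — disambiguating a repetitive end
within the insert window, or rescuing an unmapped mate with a local SW
alignment near its anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extend import banded_traceback, sw_score
from .index import GenomeIndex
from .io import Read, revcomp
from .pipeline_single import (AlignParams, Alignment, CandidateSet, align_single,
                              rank_and_emit, unmapped_alignment)
from .scoring import DEFAULT_SCHEME, ScoringScheme, compute_mapq, max_score

__all__ = ["InsertModel", "AlignedPair", "estimate_insert", "pair_and_select",
           "rescue_mate", "align_pairs"]


@dataclass
class InsertModel:
    """FR library insert-size model (fragment length, outer distance)."""

    mean: float
    sd: float
    orientation: str = "FR"

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("insert mean must be > 0 and sd >= 0")
        self.sd = max(self.sd, 10.0)  # degenerate-library floor

    @property
    def window(self) -> float:
        return 4.0 * self.sd

    def rescue_span(self, mate_len: int) -> int:
        return int(self.mean + self.window + mate_len)


@dataclass
class AlignedPair:
    aln1: Alignment
    aln2: Alignment
    state: str                      # concordant | discordant | rescued_concordant |
    observed_insert: int | None     # half_mapped | both_unmapped


def estimate_insert(pairs_sample: list[tuple[Alignment, Alignment]],
                    nominal_mean: float | None = None,
                    nominal_sd: float | None = None,
                    min_pairs: int = 100, mapq_min: int = 20) -> InsertModel:
    """Robust insert model from uniquely mapped same-chromosome pairs.

    mean = median of observed fragment lengths, sd = 1.4826 * MAD.  Falls
    back to the nominal values when fewer than ``min_pairs`` qualify.
    """
    inserts = []
    for a1, a2 in pairs_sample:
        if a1.is_unmapped or a2.is_unmapped:
            continue
        if a1.mapq < mapq_min or a2.mapq < mapq_min or a1.chrom != a2.chrom:
            continue
        if a1.strand == a2.strand:
            continue
        frag = max(a1.ref_end, a2.ref_end) - min(a1.pos, a2.pos)
        if frag > 0:
            inserts.append(frag)
    if len(inserts) >= min_pairs:
        arr = np.asarray(inserts, dtype=float)
        med = float(np.median(arr))
        sd = float(1.4826 * np.median(np.abs(arr - med)))
        return InsertModel(mean=med, sd=sd)
    if nominal_mean is None:
        raise ValueError("too few qualifying pairs and no nominal insert size given")
    return InsertModel(mean=nominal_mean, sd=nominal_sd if nominal_sd is not None else 50.0)


def _fragment(a1: Alignment, a2: Alignment) -> int:
    return max(a1.ref_end, a2.ref_end) - min(a1.pos, a2.pos)


def _concordant(a1: Alignment, a2: Alignment, model: InsertModel) -> bool:
    if a1.is_unmapped or a2.is_unmapped or a1.chrom != a2.chrom:
        return False
    if a1.strand == a2.strand:
        return False
    fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
    if fwd.pos > rev.pos:  # FR: forward end upstream of reverse end
        return False
    return abs(_fragment(a1, a2) - model.mean) <= model.window


def _pair_flags(a1: Alignment, a2: Alignment, proper: bool) -> None:
    for me, other, idx in ((a1, a2, 1), (a2, a1, 2)):
        me.paired = True
        me.read_index = idx
        me.proper_pair = proper and not me.is_unmapped and not other.is_unmapped
        me.mate_unmapped = other.is_unmapped
        me.mate_reverse = (other.strand == "-") and not other.is_unmapped
        if other.is_unmapped or me.is_unmapped:
            me.mate_rname, me.mate_pos, me.tlen = "*", None, 0
        else:
            me.mate_rname = "=" if other.chrom == me.chrom else other.chrom
            me.mate_pos = other.pos
            if other.chrom == me.chrom:
                frag = _fragment(a1, a2)
                me.tlen = frag if me.pos <= other.pos else -frag
            else:
                me.tlen = 0


def _mk_alignment(read: Read, cand, mapq: int) -> Alignment:
    return Alignment(read_id=read.id, chrom=cand.chrom, pos=cand.pos,
                     strand=cand.strand, cigar=cand.result.cigar,
                     score=cand.score, mapq=mapq, read_bases=read.bases,
                     read_quals=list(read.quals), method=cand.result.method)


def pair_and_select(cands1: CandidateSet, cands2: CandidateSet,
                    read1: Read, read2: Read, model: InsertModel,
                    scheme: ScoringScheme = DEFAULT_SCHEME,
                    params: AlignParams = AlignParams()) -> AlignedPair:
    """Select the reported placements of a pair; scores precede pairing.

    Both ends confident (mapQ >= 20): their single-end placements are
    reported unchanged, concordant or not.  Otherwise the cross-product of
    candidates is searched for the best combined score, a concordant
    combination earning one gap-open unit of bonus, and the pair mapQ is
    recomputed from the two best combination scores.
    """
    a1 = rank_and_emit(cands1, read1, scheme)[0]
    a2 = rank_and_emit(cands2, read2, scheme)[0]
    conf = params.confident_mapq
    if not a1.is_unmapped and not a2.is_unmapped and a1.mapq >= conf and a2.mapq >= conf:
        concord = _concordant(a1, a2, model)
        _pair_flags(a1, a2, concord)
        state = "concordant" if concord else "discordant"
        return AlignedPair(a1, a2, state,
                           _fragment(a1, a2) if a1.chrom == a2.chrom else None)

    if cands1.candidates and cands2.candidates:
        bonus = scheme.gap_open
        top1 = cands1.candidates[: params.max_extensions]
        top2 = cands2.candidates[: params.max_extensions]
        scored: list[tuple[float, int, int, bool]] = []
        for i, c1 in enumerate(top1):
            t1 = _mk_alignment(read1, c1, 0)
            for j, c2 in enumerate(top2):
                t2 = _mk_alignment(read2, c2, 0)
                conc = _concordant(t1, t2, model)
                scored.append((c1.score + c2.score + (bonus if conc else 0.0),
                               i, j, conc))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        best_s, bi, bj, bconc = scored[0]
        second_s = scored[1][0] if len(scored) > 1 else None
        pair_mapq = compute_mapq(best_s, second_s,
                                 cands1.max_score + cands2.max_score,
                                 repeat_flag=cands1.repeat_flag and cands2.repeat_flag,
                                 scheme=scheme)
        c1, c2 = top1[bi], top2[bj]
        # an end kept at its own top hit keeps its single-end mapQ; a
        # re-picked end carries the pair-level mapQ
        m1 = a1.mapq if (bi == 0 and not a1.is_unmapped) else pair_mapq
        m2 = a2.mapq if (bj == 0 and not a2.is_unmapped) else pair_mapq
        a1 = _mk_alignment(read1, c1, m1)
        a2 = _mk_alignment(read2, c2, m2)
        _pair_flags(a1, a2, bconc)
        return AlignedPair(a1, a2, "concordant" if bconc else "discordant",
                           _fragment(a1, a2) if a1.chrom == a2.chrom else None)

    _pair_flags(a1, a2, False)
    if a1.is_unmapped and a2.is_unmapped:
        return AlignedPair(a1, a2, "both_unmapped", None)
    return AlignedPair(a1, a2, "half_mapped", None)


def rescue_mate(anchor: Alignment, mate_read: Read, genome,
                model: InsertModel, scheme: ScoringScheme = DEFAULT_SCHEME,
                rescue_min_fraction: float = 0.75,
                band: int = 16, band_max: int = 256) -> Alignment | None:
    """Local SW rescue of an unmapped/unpaired mate next to its anchor.

    The window extends mean + 4sd + mate-length from the anchor in the FR
    direction; the rescued alignment is accepted only if its score reaches
    ``rescue_min_fraction`` of the mate's maximum score, and it carries a
    mapQ no higher than the anchor's.
    """
    chrom_seq = genome[anchor.chrom]
    span = model.rescue_span(len(mate_read))
    if anchor.strand == "+":
        w_start, w_end = anchor.pos, min(len(chrom_seq), anchor.pos + span)
        mate_strand = "-"
    else:
        w_start, w_end = max(0, anchor.ref_end - span), anchor.ref_end
        mate_strand = "+"
    window = chrom_seq[w_start:w_end]
    if len(window) < 20:
        return None
    oread = mate_read.bases if mate_strand == "+" else revcomp(mate_read.bases)
    oquals = list(mate_read.quals) if mate_strand == "+" else list(mate_read.quals)[::-1]
    score, end = sw_score(oread, oquals, window, scheme)
    if score < rescue_min_fraction * max_score(mate_read.quals, scheme):
        return None
    try:
        res = banded_traceback(oread, oquals, window, end, band, scheme,
                               expected_score=score, band_max=band_max)
    except (ValueError, RuntimeError):
        return None
    mapq = min(anchor.mapq,
               compute_mapq(score, None, max_score(mate_read.quals, scheme),
                            scheme=scheme))
    return Alignment(read_id=mate_read.id, chrom=anchor.chrom,
                     pos=w_start + res.ref_start, strand=mate_strand,
                     cigar=res.cigar, score=score, mapq=mapq,
                     read_bases=mate_read.bases, read_quals=list(mate_read.quals),
                     method="sw", rescued=True)


def align_pairs(reads1: list[Read], reads2: list[Read], index: GenomeIndex,
                model: InsertModel | None = None,
                nominal_mean: float | None = None, nominal_sd: float | None = None,
                params: AlignParams = AlignParams(),
                scheme: ScoringScheme = DEFAULT_SCHEME,
                cand_pairs: list[tuple[CandidateSet, CandidateSet]] | None = None
                ) -> list[AlignedPair]:
    """Full paired-end pipeline over parallel read lists.

    ``cand_pairs`` may carry candidate sets already computed by
    :func:`align_single` for each pair, to avoid re-seeding.
    """
    if cand_pairs is None:
        cand_pairs = [(align_single(r1, index, params, scheme),
                       align_single(r2, index, params, scheme))
                      for r1, r2 in zip(reads1, reads2)]
    if model is None:
        sample = [(rank_and_emit(c1, r1, scheme)[0], rank_and_emit(c2, r2, scheme)[0])
                  for (c1, c2), r1, r2 in zip(cand_pairs, reads1, reads2)]
        model = estimate_insert(sample, nominal_mean, nominal_sd)

    out: list[AlignedPair] = []
    for (c1, c2), r1, r2 in zip(cand_pairs, reads1, reads2):
        pair = pair_and_select(c1, c2, r1, r2, model, scheme, params)
        pair = _try_rescue(pair, r1, r2, index, model, params, scheme)
        out.append(pair)
    return out


def _try_rescue(pair: AlignedPair, r1: Read, r2: Read, index: GenomeIndex,
                model: InsertModel, params: AlignParams,
                scheme: ScoringScheme) -> AlignedPair:
    """SW-rescue a half-mapped or weakly-placed discordant mate near its anchor.

    A mate that is itself confidently mapped is never rescued: a confident
    discordant placement is the SV signal and stands.  A rescued placement
    replaces a weak one only if it also wins on score (plus the small
    concordance bonus) — alignment scores precede mate-pair information.
    """
    if pair.state not in ("half_mapped", "discordant"):
        return pair
    conf = params.confident_mapq
    ends = [(pair.aln1, r1, 1), (pair.aln2, r2, 2)]
    anchors = [e for e in ends if not e[0].is_unmapped and e[0].mapq >= conf]
    weak = [e for e in ends
            if e[0].is_unmapped or e[0].mapq < conf]
    if len(anchors) != 1 or len(weak) != 1:
        return pair
    anchor, _, _ = anchors[0]
    weak_aln, mate_read, slot = weak[0]
    rescued = rescue_mate(anchor, mate_read, index.genome, model, scheme,
                          band=params.dp.band, band_max=params.dp.band_max)
    if rescued is None:
        return pair
    if not weak_aln.is_unmapped and rescued.score + scheme.gap_open <= weak_aln.score:
        return pair
    a1, a2 = (anchor, rescued) if slot == 2 else (rescued, anchor)
    if not _concordant(a1, a2, model):
        return pair
    _pair_flags(a1, a2, True)
    return AlignedPair(a1, a2, "rescued_concordant", _fragment(a1, a2))
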