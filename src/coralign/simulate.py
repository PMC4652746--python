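"""Synthetic genomes, reads, pairs and structural rearrangements with truth.

Desk-scale stand-ins for the usual simulation toolchain: a random genome
with optional duplicated (repeat) content, Illumina-like reads with a
position-dependent quality curve and quality-conditional substitution
errors, indel spiking, concordant/discordant read pairs, and a structural
rearranger (deletions, insertions, duplications, inversions,
translocations) that records every breakpoint.  Every read carries a
:class:`TruthRecord`; evaluation is driven entirely by these oracles.

All generators are deterministic under their seed; the RNG stream is split
per concern so adding reads does not perturb genome generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Genome, Read, revcomp

__all__ = [
    "TruthRecord",
    "SVEvent",
    "QualityProfile",
    "make_genome",
    "simulate_reads",
    "spike_indels",
    "simulate_pairs",
    "rearrange_genome",
    "apply_events",
    "breakpoints_of",
    "reads_spanning_breakpoints",
    "truth_to_tsv",
    "truth_from_tsv",
]

BASES = np.array(list("ACGT"))
# GC ~ 0.41, matching typical mammalian composition
BASE_PROBS = np.array([0.295, 0.205, 0.205, 0.295])
ERROR_CAP = 0.07  # max combined mismatch+indel fraction per read


@dataclass
class TruthRecord:
    read_id: str
    klass: str          # illumina | indel_spiked | pair_concordant | pair_discordant | sv
    chrom: str
    pos: int            # 0-based leftmost forward-reference coordinate
    strand: str
    n_mismatches: int = 0
    indels: list[tuple[int, int, str]] = field(default_factory=list)  # (read offset, len, I/D)


@dataclass
class SVEvent:
    type: str           # insertion | deletion | duplication | inversion | translocation
    chrom: str
    start: int          # donor (reference) coordinates, 0-based half-open
    end: int
    target_chrom: str = ""
    target_pos: int = -1
    seq: str = ""       # novel sequence for insertions

    @property
    def length(self) -> int:
        return (self.end - self.start) if self.type != "insertion" else len(self.seq)


@dataclass(frozen=True)
class QualityProfile:
    """Parametric quality-by-cycle curve with quality-conditional errors.

    Q starts near ``q_start``, decays toward ``q_end`` along the read, with
    logistic noise of scale ``noise``.  Substitution probability per base is
    the Phred error probability 10^(-Q/10), rescaled so the dataset-wide
    mean equals ``sub_rate`` when set (so low-Q cycles err more, as in
    empirical profiles, while the overall rate is controlled).
    """

    q_start: float = 38.0
    q_end: float = 25.0
    noise: float = 2.0
    sub_rate: float | None = None

    def draw_quals(self, length: int, rng: np.random.Generator) -> np.ndarray:
        t = np.linspace(0.0, 1.0, length)
        mean = self.q_start - (self.q_start - self.q_end) * t ** 1.3
        q = mean + rng.logistic(0.0, self.noise, size=length)
        return np.clip(np.round(q), 2, 40).astype(int)

    def sub_probs(self, quals: np.ndarray) -> np.ndarray:
        e = 10.0 ** (-quals / 10.0)
        if self.sub_rate is not None and e.mean() > 0:
            e = e * (self.sub_rate / e.mean())
        return np.clip(e, 0.0, 0.75)


def make_genome(length: int, n_chroms: int = 1, repeat_fraction: float = 0.0,
                seed: int = 0, gc: float = 0.41) -> Genome:
    """Random genome; ``repeat_fraction`` of the sequence is duplicated segments.

    Deterministic under ``seed``.  Duplications copy 200-2000 bp segments to
    random other locations (overwriting), creating the repeat structure that
    exercises multi-hit seeding and the deep scan.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = Genome()
    sizes = np.full(n_chroms, length // n_chroms)
    sizes[: length % n_chroms] += 1
    for ci, size in enumerate(sizes):
        arr = rng.choice(4, size=int(size), p=probs)
        target_dup = repeat_fraction * size
        dup = 0.0
        while dup < target_dup:
            seg_len = int(rng.integers(200, 2001))
            if 2 * seg_len >= size:
                break
            src = int(rng.integers(0, size - seg_len))
            dst = int(rng.integers(0, size - seg_len))
            if abs(dst - src) < seg_len:
                continue
            arr[dst:dst + seg_len] = arr[src:src + seg_len]
            dup += seg_len
        genome.sequences[f"chr{ci + 1}"] = "".join(BASES[arr])
    return genome


def _weighted_chrom(genome: Genome, rng: np.random.Generator, min_len: int) -> str:
    names = [n for n in genome.names() if len(genome[n]) >= min_len]
    if not names:
        raise ValueError("no chromosome long enough")
    lens = np.array([len(genome[n]) for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=lens / lens.sum()))]


def _apply_substitutions(bases: str, quals: np.ndarray, profile: QualityProfile,
                         rng: np.random.Generator, budget: int) -> tuple[str, int]:
    probs = profile.sub_probs(quals)
    hit = np.flatnonzero(rng.random(len(bases)) < probs)
    if len(hit) > budget:
        hit = rng.choice(hit, size=budget, replace=False)
    out = list(bases)
    for i in hit:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(3))]
    return "".join(out), len(hit)


def simulate_reads(genome: Genome, n: int, read_len: int,
                   profile: QualityProfile = QualityProfile(), seed: int = 0,
                   klass: str = "illumina", id_prefix: str = "r"
                   ) -> tuple[list[Read], list[TruthRecord]]:
    """Uniformly placed single-end reads from both strands, with truth records.

    Per-read errors are capped at 7% of the read length (mismatches +
    indels combined).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    reads: list[Read] = []
    truths: list[TruthRecord] = []
    cap = int(ERROR_CAP * read_len)
    for i in range(n):
        chrom = _weighted_chrom(genome, rng, read_len)
        seq = genome[chrom]
        pos = int(rng.integers(0, len(seq) - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        bases = seq[pos:pos + read_len]
        if strand == "-":
            bases = revcomp(bases)
        quals = profile.draw_quals(read_len, rng)
        bases, n_mm = _apply_substitutions(bases, quals, profile, rng, cap)
        rid = f"{id_prefix}{i}"
        reads.append(Read(id=rid, bases=bases, quals=quals.tolist()))
        truths.append(TruthRecord(read_id=rid, klass=klass, chrom=chrom, pos=pos,
                                  strand=strand, n_mismatches=n_mm))
    return reads, truths


def spike_indels(reads: list[Read], truths: list[TruthRecord], genome: Genome,
                 rate: float = 0.001, mode: str = "mixed", seed: int = 0,
                 max_len: int = 10) -> tuple[list[Read], list[TruthRecord]]:
    """Inject indels into simulated reads at ``rate`` per base.

    ``mode`` is 'insert', 'delete' or 'mixed'.  Indel lengths are geometric,
    truncated to 1..``max_len``.  Read length is preserved: a deletion
    re-extends the read's 3' end from the reference, an insertion trims it.
    The 7% combined error cap is enforced; indels that would breach it, or
    run off the chromosome, are skipped.  Truth positions and indel specs
    are updated so the records stay exact.
    """
    if mode not in ("insert", "delete", "mixed"):
        raise ValueError(f"bad indel mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out_reads: list[Read] = []
    out_truths: list[TruthRecord] = []
    for read, truth in zip(reads, truths):
        L = len(read)
        n_events = int(rng.binomial(L, rate))
        bases, pos = read.bases, truth.pos
        indels: list[tuple[int, int, str]] = []
        n_err = truth.n_mismatches
        chrom_seq = genome[truth.chrom]
        span = L  # forward-reference span of the read
        for _ in range(n_events):
            g = min(int(rng.geometric(0.5)), max_len)
            kind = mode if mode != "mixed" else ("insert" if rng.random() < 0.5 else "delete")
            if n_err + g > int(ERROR_CAP * L):
                continue
            if kind == "delete":
                o = int(rng.integers(1, L - g))  # gap strictly internal
                if truth.strand == "+":
                    ext_lo, ext_hi = pos + span, pos + span + g
                    if ext_hi > len(chrom_seq):
                        continue
                    ext = chrom_seq[ext_lo:ext_hi]
                else:
                    if pos - g < 0:
                        continue
                    ext = revcomp(chrom_seq[pos - g:pos])
                    pos -= g
                bases = bases[:o] + bases[o + g:] + ext
                span += g
                indels.append((o, g, "D"))
            else:
                o = int(rng.integers(1, L - g))
                ins = "".join(BASES[rng.integers(0, 4, size=g)])
                bases = bases[:o] + ins + bases[o:]
                bases = bases[:L]
                if truth.strand == "-":
                    pos += g
                span -= g
                indels.append((o, g, "I"))
            n_err += g
        new_truth = replace(truth, pos=pos, indels=truth.indels + indels,
                            klass="indel_spiked" if indels else truth.klass)
        out_reads.append(Read(id=read.id, bases=bases, quals=read.quals,
                              mate_index=read.mate_index))
        out_truths.append(new_truth)
    return out_reads, out_truths


def simulate_pairs(genome: Genome, n: int, read_len: int, mean: float = 500.0,
                   sd: float = 50.0, discordant: bool = False, seed: int = 0,
                   profile: QualityProfile = QualityProfile(), id_prefix: str = "p"
                   ) -> tuple[list[Read], list[Read], list[TruthRecord]]:
    """FR paired-end reads: concordant (insert ~ N(mean, sd)) or cross-chromosome.

    Concordant mode rejects fragments shorter than 2*read_len (overlapping
    ends are disallowed) and errors out if the nominal mean already violates
    that.  Discordant mode draws the two ends independently from two
    different chromosomes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    cap = int(ERROR_CAP * read_len)
    r1s: list[Read] = []
    r2s: list[Read] = []
    truths: list[TruthRecord] = []

    def finish(i, end, chrom, pos, strand, bases):
        quals = profile.draw_quals(read_len, rng)
        bases, n_mm = _apply_substitutions(bases, quals, profile, rng, cap)
        rid = f"{id_prefix}{i}"
        read = Read(id=rid, bases=bases, quals=quals.tolist(), mate_index=end)
        klass = "pair_discordant" if discordant else "pair_concordant"
        truths.append(TruthRecord(read_id=rid, klass=klass, chrom=chrom, pos=pos,
                                  strand=strand, n_mismatches=n_mm))
        (r1s if end == 1 else r2s).append(read)

    if discordant:
        names = genome.names()
        if len(names) < 2:
            raise ValueError("discordant pairs need >= 2 chromosomes")
        for i in range(n):
            c1, c2 = rng.choice(len(names), size=2, replace=False)
            for end, c in ((1, names[c1]), (2, names[c2])):
                seq = genome[c]
                if len(seq) < read_len:
                    raise ValueError(f"{c} shorter than the read length")
                pos = int(rng.integers(0, len(seq) - read_len + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                bases = seq[pos:pos + read_len]
                if strand == "-":
                    bases = revcomp(bases)
                finish(i, end, c, pos, strand, bases)
        return r1s, r2s, truths

    if mean < 2 * read_len:
        raise ValueError("mean insert shorter than twice the read length "
                         "(overlapping ends are disallowed)")
    min_chrom = int(mean + 4 * sd) + 2 * read_len
    for i in range(n):
        chrom = _weighted_chrom(genome, rng, min_chrom)
        seq = genome[chrom]
        while True:
            frag = int(round(rng.normal(mean, sd)))
            if 2 * read_len <= frag <= len(seq):
                break
        start = int(rng.integers(0, len(seq) - frag + 1))
        fragment = seq[start:start + frag]
        finish(i, 1, chrom, start, "+", fragment[:read_len])
        finish(i, 2, chrom, start + frag - read_len, "-",
               revcomp(fragment[frag - read_len:]))
    return r1s, r2s, truths


# --- structural rearrangement ----------------------------------------------

# a rearranged chromosome is a list of blocks; each block is either a
# reference slice (chrom, start, end, strand) or a novel sequence ("", seq)
_RefBlock = tuple[str, int, int, str]


def apply_events(genome: Genome, events: list[SVEvent]) -> tuple[Genome, dict[str, list]]:
    """Apply non-overlapping SV events to a reference, returning the
    rearranged genome and its block decomposition (reference provenance of
    every rearranged interval)."""
    blocks: dict[str, list] = {name: [(name, 0, len(seq), "+")]
                               for name, seq in genome.sequences.items()}

    def split_at(chrom: str, coord: int) -> int:
        """Split the block containing reference coord; return block index."""
        lst = blocks[chrom]
        for bi, b in enumerate(lst):
            if len(b) == 2:  # novel block, carries no reference coords
                continue
            c, s, e, st = b
            if c == chrom and s <= coord <= e and st == "+":
                if coord == s:
                    return bi
                if coord == e:
                    return bi + 1
                lst[bi:bi + 1] = [(c, s, coord, st), (c, coord, e, st)]
                return bi + 1
        raise ValueError(f"reference coord {chrom}:{coord} not found intact")

    def extract(chrom: str, start: int, end: int) -> list:
        i0 = split_at(chrom, start)
        i1 = split_at(chrom, end)
        seg = blocks[chrom][i0:i1]
        return i0, seg

    for ev in events:
        if ev.type == "deletion":
            i0, seg = extract(ev.chrom, ev.start, ev.end)
            del blocks[ev.chrom][i0:i0 + len(seg)]
        elif ev.type == "inversion":
            i0, seg = extract(ev.chrom, ev.start, ev.end)
            inv = [(c, s, e, "-" if st == "+" else "+") for c, s, e, st in seg[::-1]]
            blocks[ev.chrom][i0:i0 + len(seg)] = inv
        elif ev.type == "duplication":
            i0, seg = extract(ev.chrom, ev.start, ev.end)
            blocks[ev.chrom][i0 + len(seg):i0 + len(seg)] = [tuple(b) for b in seg]
        elif ev.type == "insertion":
            i0 = split_at(ev.chrom, ev.start)
            blocks[ev.chrom].insert(i0, ("", ev.seq))
        elif ev.type == "translocation":
            i0, seg = extract(ev.chrom, ev.start, ev.end)
            del blocks[ev.chrom][i0:i0 + len(seg)]
            ti = split_at(ev.target_chrom, ev.target_pos)
            blocks[ev.target_chrom][ti:ti] = seg
        else:
            raise ValueError(f"unknown SV type {ev.type!r}")

    out = Genome()
    for name in genome.names():
        parts = []
        for b in blocks[name]:
            if len(b) == 2:
                parts.append(b[1])
            else:
                c, s, e, st = b
                piece = genome[c][s:e]
                parts.append(piece if st == "+" else revcomp(piece))
        out.sequences[name] = "".join(parts)
    return out, blocks


def breakpoints_of(blocks: dict[str, list]) -> list[tuple[str, int]]:
    """Rearranged-coordinate positions where adjacent bases are not
    reference-adjacent (the SV junctions)."""
    bps: list[tuple[str, int]] = []
    for name, lst in blocks.items():
        offset = 0
        for bi, b in enumerate(lst):
            blen = len(b[1]) if len(b) == 2 else b[2] - b[1]
            if bi > 0:
                prev = lst[bi - 1]
                adjacent = (
                    len(b) == 4 and len(prev) == 4 and b[0] == prev[0]
                    and b[3] == prev[3]
                    and ((b[3] == "+" and prev[2] == b[1])
                         or (b[3] == "-" and b[2] == prev[1]))
                )
                if not adjacent:
                    bps.append((name, offset))
            offset += blen
    return bps


def rearrange_genome(genome: Genome, n_events: int, type_mix: dict[str, float] | None = None,
                     seed: int = 0, size_range: tuple[int, int] = (100, 2000)
                     ) -> tuple[Genome, list[SVEvent], list[tuple[str, int]]]:
    """Plan and apply ``n_events`` non-overlapping SVs; returns the
    rearranged genome, the event list and the breakpoints (rearranged
    coordinates)."""
    types = ["insertion", "deletion", "duplication", "inversion", "translocation"]
    if type_mix is None:
        type_mix = {t: 1.0 for t in types}
    names = genome.names()
    if len(names) < 2:
        type_mix = {t: w for t, w in type_mix.items() if t != "translocation"}
    tnames = list(type_mix)
    weights = np.array([type_mix[t] for t in tnames], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))

    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def reserve(chrom: str, start: int, end: int, margin: int = 50) -> bool:
        for s, e in taken[chrom]:
            if start - margin < e and s < end + margin:
                return False
        taken[chrom].append((start, end))
        return True

    events: list[SVEvent] = []
    attempts = 0
    while len(events) < n_events and attempts < 50 * n_events:
        attempts += 1
        t = tnames[int(rng.choice(len(tnames), p=weights))]
        chrom = names[int(rng.integers(len(names)))]
        clen = len(genome[chrom])
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if t == "insertion":
            p = int(rng.integers(1, clen - 1))
            if not reserve(chrom, p, p + 1):
                continue
            seq = "".join(BASES[rng.integers(0, 4, size=size)])
            events.append(SVEvent("insertion", chrom, p, p, seq=seq))
        elif t == "translocation":
            others = [n for n in names if n != chrom]
            tgt = others[int(rng.integers(len(others)))]
            if clen - size - 2 <= 1 or len(genome[tgt]) <= 2:
                continue
            s = int(rng.integers(1, clen - size - 1))
            tp = int(rng.integers(1, len(genome[tgt]) - 1))
            if not (reserve(chrom, s, s + size) and reserve(tgt, tp, tp + 1)):
                continue
            events.append(SVEvent("translocation", chrom, s, s + size,
                                  target_chrom=tgt, target_pos=tp))
        else:
            if clen - size - 2 <= 1:
                continue
            s = int(rng.integers(1, clen - size - 1))
            if not reserve(chrom, s, s + size):
                continue
            events.append(SVEvent(t, chrom, s, s + size))
    if len(events) < n_events:
        raise ValueError(f"could not place {n_events} non-overlapping events")
    rearranged, blocks = apply_events(genome, events)
    return rearranged, events, breakpoints_of(blocks)


def reads_spanning_breakpoints(rearranged: Genome, breakpoints: list[tuple[str, int]],
                               n: int, read_len: int, min_flank: int = 25,
                               profile: QualityProfile = QualityProfile(),
                               seed: int = 0, id_prefix: str = "sv"
                               ) -> tuple[list[Read], list[TruthRecord]]:
    """Reads from the rearranged genome, each spanning a breakpoint with at
    least ``min_flank`` bases on both sides.  Truth coordinates are in the
    rearranged genome."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    usable = [(c, p) for c, p in breakpoints
              if p - (read_len - min_flank) >= 0
              and p + (read_len - min_flank) <= len(rearranged[c])]
    if not usable:
        raise ValueError("no breakpoint has enough flanking sequence")
    cap = int(ERROR_CAP * read_len)
    reads, truths = [], []
    for i in range(n):
        c, p = usable[int(rng.integers(len(usable)))]
        lo = max(0, p - read_len + min_flank)
        hi = min(len(rearranged[c]) - read_len, p - min_flank)
        pos = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        bases = rearranged[c][pos:pos + read_len]
        if strand == "-":
            bases = revcomp(bases)
        quals = profile.draw_quals(read_len, rng)
        bases, n_mm = _apply_substitutions(bases, quals, profile, rng, cap)
        rid = f"{id_prefix}{i}"
        reads.append(Read(id=rid, bases=bases, quals=quals.tolist()))
        truths.append(TruthRecord(read_id=rid, klass="sv", chrom=c, pos=pos,
                                  strand=strand, n_mismatches=n_mm))
    return reads, truths


# --- truth TSV ---------------------------------------------------------------

def truth_to_tsv(truths: list[TruthRecord], path) -> None:
    rows = [{
        "read_id": t.read_id, "class": t.klass, "chrom": t.chrom, "pos": t.pos,
        "strand": t.strand, "n_mm": t.n_mismatches,
        "indel_spec": ";".join(f"{o}:{g}:{k}" for o, g, k in t.indels),
    } for t in truths]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def truth_from_tsv(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        indels = []
        if row["indel_spec"]:
            for part in str(row["indel_spec"]).split(";"):
                o, g, k = part.split(":")
                indels.append((int(o), int(g), k))
        out.append(TruthRecord(read_id=str(row["read_id"]), klass=row["class"],
                               chrom=str(row["chrom"]), pos=int(row["pos"]),
                               strand=row["strand"], n_mismatches=int(row["n_mm"]),
                               indels=indels))
    return out
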