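"""Sequence formats and alignment record plumbing.

Readers/writers for FASTA, FASTQ (Phred+33) and SAM, the CIGAR utilities
used throughout the aligner, and the core domain types (:class:`Genome`,
:class:`Read`, :class:`Cigar`).

Coordinates are 0-based half-open everywhere inside the package; the single
conversion to SAM's 1-based POS happens in :func:`write_sam`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "Genome",
    "Read",
    "Cigar",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "write_sam",
    "cigar_span",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
# CIGAR codes emitted by this aligner: M (aligned column), I (read insertion),
# D (read deletion), S (soft clip).  No =/X, no hard clips.
_CIGAR_RE = re.compile(r"(\d+)([MIDS])")


class FormatError(ValueError):
    """A malformed input file (FASTA/FASTQ syntax, record-level violations)."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Reference genome: an ordered map of sequence name -> ACGTN string."""

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def names(self) -> list[str]:
        return list(self.sequences.keys())


@dataclass
class Read:
    """A sequencing read: bases plus per-base Phred qualities Q[i].

    ``mate_index`` is 0 for single-end reads, 1 or 2 for the two ends of a
    pair.  Invariant: ``len(bases) == len(quals)`` and 0 <= Q[i] <= 93.
    """

    id: str
    bases: str
    quals: list[int]
    mate_index: int = 0

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Cigar:
    """Run-length alignment description, ops over {M, I, D, S}.

    Invariants: adjacent ops have distinct codes; S only at the ends;
    read-consuming ops (M, I, S) sum to the read length.
    """

    ops: tuple[tuple[int, str], ...]

    @classmethod
    def from_string(cls, text: str) -> "Cigar":
        ops = [(int(n), c) for n, c in _CIGAR_RE.findall(text)]
        if "".join(f"{n}{c}" for n, c in ops) != text:
            raise FormatError(f"bad CIGAR string: {text!r}")
        return cls(tuple(ops))

    @classmethod
    def from_ops(cls, ops: Iterable[tuple[int, str]]) -> "Cigar":
        """Build a Cigar, merging adjacent same-code runs and dropping empties."""
        merged: list[tuple[int, str]] = []
        for n, c in ops:
            if n == 0:
                continue
            if merged and merged[-1][1] == c:
                merged[-1] = (merged[-1][0] + n, c)
            else:
                merged.append((n, c))
        return cls(tuple(merged))

    def __str__(self) -> str:
        return "".join(f"{n}{c}" for n, c in self.ops)

    @property
    def read_len(self) -> int:
        return sum(n for n, c in self.ops if c in "MIS")

    @property
    def ref_len(self) -> int:
        return sum(n for n, c in self.ops if c in "MD")

    @property
    def clip_left(self) -> int:
        return self.ops[0][0] if self.ops and self.ops[0][1] == "S" else 0

    @property
    def clip_right(self) -> int:
        return self.ops[-1][0] if len(self.ops) > 1 and self.ops[-1][1] == "S" else 0

    def validate(self, read_length: int | None = None) -> None:
        for i, (n, c) in enumerate(self.ops):
            if n <= 0 or c not in "MIDS":
                raise FormatError(f"bad CIGAR op {n}{c}")
            if i and self.ops[i - 1][1] == c:
                raise FormatError(f"adjacent CIGAR ops share code in {self}")
            if c == "S" and i not in (0, len(self.ops) - 1):
                raise FormatError(f"internal soft clip in {self}")
        if read_length is not None and self.read_len != read_length:
            raise FormatError(
                f"CIGAR {self} consumes {self.read_len} read bases, expected {read_length}"
            )


def cigar_span(cigar: Cigar) -> tuple[int, int]:
    """(read bases consumed, reference bases consumed) of a CIGAR.

    Read span counts M+I+S; reference span counts M+D.
    """
    return cigar.read_len, cigar.ref_len


def read_fasta(path) -> Genome:
    """Parse a FASTA file into a :class:`Genome`.

    Lowercase input is uppercased; any character outside {A,C,G,T,N} (IUPAC
    ambiguity codes etc.) is mapped to N.
    """
    genome = Genome()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
        genome.sequences[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError("empty sequence name in FASTA")
                if name in genome.sequences:
                    raise FormatError(f"duplicate sequence name {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError("FASTA data before first header")
                chunks.append(line)
    flush()
    if not genome.sequences:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file (Phred+33)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"expected @header, got {header!r}")
            bases = fh.readline().rstrip("\n").upper()
            plus = fh.readline()
            if not plus.startswith("+"):
                raise FormatError(f"expected + line for {header!r}")
            qline = fh.readline().rstrip("\n")
            if len(qline) != len(bases):
                raise FormatError(
                    f"record {header!r}: {len(bases)} bases but {len(qline)} quality chars"
                )
            quals = [ord(c) - 33 for c in qline]
            if any(q < 0 or q > 93 for q in quals):
                raise FormatError(f"record {header!r}: Phred score out of [0, 93]")
            yield Read(id=header[1:].split()[0], bases=bases, quals=quals)


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")


# --- SAM output -----------------------------------------------------------

FLAG_PAIRED = 1
FLAG_PROPER = 2
FLAG_UNMAPPED = 4
FLAG_MATE_UNMAPPED = 8
FLAG_REVERSE = 16
FLAG_MATE_REVERSE = 32
FLAG_READ1 = 64
FLAG_READ2 = 128
FLAG_SUPPLEMENTARY = 2048


def _sam_record(aln, genome: Genome) -> str:
    """Render one alignment-like object (pipeline Alignment) as a SAM line."""
    if aln.is_unmapped:
        qline = "".join(chr(q + 33) for q in aln.read_quals)
        return "\t".join(
            [aln.read_id, str(aln.flag), "*", "0", "0", "*", "*", "0", "0",
             aln.read_bases, qline or "*"]
        )
    chrom_len = len(genome[aln.chrom])
    if aln.pos + aln.cigar.ref_len > chrom_len or aln.pos < 0:
        raise RuntimeError(
            f"alignment of {aln.read_id} at {aln.chrom}:{aln.pos} exceeds sequence end"
        )
    aln.cigar.validate(len(aln.read_bases))
    bases, quals = aln.read_bases, aln.read_quals
    if aln.strand == "-":
        bases = revcomp(bases)
        quals = quals[::-1]
    qline = "".join(chr(q + 33) for q in quals)
    return "\t".join(
        [
            aln.read_id,
            str(aln.flag),
            aln.chrom,
            str(aln.pos + 1),  # SAM POS is 1-based
            str(aln.mapq),
            str(aln.cigar),
            aln.mate_rname,
            str(aln.mate_pos + 1) if aln.mate_pos is not None else "0",
            str(aln.tlen),
            bases,
            qline,
        ]
    )


def write_sam(alignments: Iterable, genome: Genome, path, scheme_json: str | None = None) -> None:
    """Write alignment records with an @HD/@SQ header.

    ``alignments`` may contain unmapped placeholder records (FLAG 4).  The
    optional ``scheme_json`` is echoed into an @PG line for provenance.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        pg = "@PG\tID:coralign\tPN:coralign"
        if scheme_json:
            pg += f"\tDS:scheme={scheme_json}"
        fh.write(pg + "\n")
        for aln in alignments:
            fh.write(_sam_record(aln, genome) + "\n")
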