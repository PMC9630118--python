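"""Reading and writing the standard formats the pipeline touches.

All internal coordinates are 0-based half-open. SAM input (1-based) and the
mtDNA positions printed in reports (1-based inclusive, MitoMap convention)
are converted at the boundary. The mitochondrial contig is treated as
circular only where explicitly needed (interval normalization, D-loop
logic); alignments are taken as given on the linearized contig.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pysam
from Bio import SeqIO

#: default contig names recognised as mitochondrial
MT_NAMES = ("chrM", "MT", "chrMT", "M")

#: length of the human revised Cambridge Reference Sequence (rCRS)
RCRS_LENGTH = 16569

_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Inputs that disagree with each other (e.g. unknown contig)."""


class RangeError(ValueError):
    """Coordinate outside the valid range of its contig."""


@dataclass
class ReferenceGenome:
    """A combined nuclear + mitochondrial reference.

    contigs maps name -> uppercase sequence (A/C/G/T/N); ``mt_name`` flags
    the mitochondrial contig, which may be treated as circular.
    """

    contigs: dict[str, str]
    mt_name: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError("reference has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has empty sequence")
            bad = set(seq) - _ALPHABET
            if bad:
                raise FormatError(f"contig {name!r} has invalid characters {sorted(bad)}")
        if self.mt_name not in self.contigs:
            raise ConsistencyError(f"mt contig {self.mt_name!r} not in reference")

    @property
    def mt_length(self) -> int:
        return len(self.contigs[self.mt_name])

    @property
    def mt_sequence(self) -> str:
        return self.contigs[self.mt_name]

    def nuclear_names(self) -> list[str]:
        return [n for n in self.contigs if n != self.mt_name]


@dataclass
class AlignedRead:
    """One SAM alignment record, reduced to the fields the pipeline consumes.

    ``start`` is 0-based; ``cigar`` is a list of (op, length) with
    op in {M, I, D, S, H}; ``contig`` is None for unmapped reads.
    """

    read_id: str
    sample_id: str
    contig: Optional[str]
    start: int
    cigar: list[tuple[str, int]]
    strand: str  # "+" or "-"
    mapq: int
    mate_contig: Optional[str]
    mate_start: int
    is_supplementary: bool
    sequence: str
    is_read1: bool = True

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + sum(n for op, n in self.cigar if op in "MD")

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def clips(self) -> tuple[int, int]:
        """(left, right) soft-clip lengths."""
        left = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        right = self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0
        return left, right


@dataclass
class IntervalTrack:
    """A named set of genomic intervals, 0-based half-open, sorted per contig."""

    name: str
    intervals: list[tuple]  # (contig, start, end[, label])

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv[1] >= iv[2]:
                raise RangeError(f"empty/inverted interval {iv} in track {self.name!r}")
        self.intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2]))

    def by_contig(self, contig: str) -> list[tuple]:
        return [iv for iv in self.intervals if iv[0] == contig]


def read_fasta(path: str, mt_names: tuple[str, ...] = MT_NAMES) -> ReferenceGenome:
    """Read a FASTA into a :class:`ReferenceGenome`.

    The mt contig is identified by name (default ``chrM``/``MT``); sequences
    are uppercased. Raises :class:`FormatError` on an empty or malformed file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(path, "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
    except Exception as exc:  # Biopython raises ValueError with line context
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    mt = next((n for n in contigs if n in mt_names), None)
    if mt is None:
        # single-contig mt-only FASTA: take it as the mt contig
        if len(contigs) == 1:
            mt = next(iter(contigs))
        else:
            raise ConsistencyError(
                f"no mitochondrial contig (looked for {mt_names}) in {path}"
            )
    return ReferenceGenome(contigs=contigs, mt_name=mt)


def write_fasta(reference: ReferenceGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignments(
    path: str,
    reference: Optional[ReferenceGenome] = None,
    sample_id: Optional[str] = None,
) -> Iterator[AlignedRead]:
    """Stream SAM records as :class:`AlignedRead` in file order.

    Header @SQ contigs are checked against ``reference`` when given; soft and
    hard clips are preserved in the cigar. MAPQ-0 records are yielded —
    filtering is a detection-stage concern, not an I/O concern.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    mode = "rb" if path.endswith(".bam") else "r"
    try:
        af = pysam.AlignmentFile(path, mode, check_sq=False)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    with af:
        if reference is not None:
            for sq in af.header.get("SQ", []):
                name = sq["SN"]
                if name not in reference.contigs:
                    raise ConsistencyError(f"@SQ contig {name!r} absent from reference")
                if sq["LN"] != len(reference.contigs[name]):
                    raise ConsistencyError(
                        f"@SQ length for {name!r} ({sq['LN']}) != reference "
                        f"({len(reference.contigs[name])})"
                    )
        op_codes = "MIDNSHP=X"
        for rec in af:
            cigar = (
                [(op_codes[op], ln) for op, ln in rec.cigartuples]
                if rec.cigartuples
                else []
            )
            yield AlignedRead(
                read_id=rec.query_name,
                sample_id=sample_id,
                contig=None if rec.is_unmapped else rec.reference_name,
                start=-1 if rec.is_unmapped else rec.reference_start,
                cigar=cigar,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                mate_contig=None
                if (not rec.is_paired or rec.mate_is_unmapped)
                else rec.next_reference_name,
                mate_start=rec.next_reference_start if rec.is_paired else -1,
                is_supplementary=rec.is_supplementary,
                sequence=rec.query_sequence or "",
                is_read1=not rec.is_read2,
            )


def read_intervals(path: str, kind: str, mt_name: str = "chrM") -> IntervalTrack:
    """Read an annotation track.

    kind:
      * ``bed`` — BED3/BED4, 0-based half-open, sorted on load.
      * ``mito_deletions`` — mitoBreak-style TSV with columns del5/del3 holding
        1-based 5' and 3' deletion breakpoints on the mt genome; each row is
        stored as two single-base intervals (labelled del5/del3) on ``mt_name``.
      * ``known_numts`` — BED of previously reported NUMT loci.
    """
    if kind not in {"bed", "mito_deletions", "known_numts"}:
        raise ValueError(f"unknown track kind {kind!r}")
    name = os.path.splitext(os.path.basename(path))[0]
    intervals: list[tuple] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if kind in {"bed", "known_numts"}:
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: BED needs >=3 fields")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
                label = fields[3] if len(fields) > 3 else None
                iv = (fields[0], start, end) if label is None else (fields[0], start, end, label)
                intervals.append(iv)
            else:  # mito_deletions
                if not header_seen and not fields[0].lstrip("-").isdigit():
                    header_seen = True  # skip a del5/del3 header row
                    continue
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: deletion rows need del5 and del3")
                try:
                    d5, d3 = int(fields[0]), int(fields[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad breakpoint") from exc
                if d5 < 1 or d3 < 1:
                    raise RangeError(f"{path}:{lineno}: breakpoints are 1-based positive")
                # 1-based positions -> 0-based single-base intervals
                intervals.append((mt_name, d5 - 1, d5, "del5"))
                intervals.append((mt_name, d3 - 1, d3, "del3"))
    return IntervalTrack(name=name, intervals=intervals)


def write_intervals(track: IntervalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def normalize_mt_interval(start: int, end: int, mt_length: int) -> list[tuple[int, int]]:
    """Canonicalize a 1-based inclusive mt interval that may cross the origin.

    Returns a list of linear (start, end) 1-based inclusive sub-intervals:
    one for a linear interval, two when the interval wraps the circular
    origin. Idempotent on already-linear intervals.
    """
    if not (1 <= start <= mt_length and 1 <= end <= mt_length):
        raise RangeError(f"positions must lie in 1..{mt_length}, got ({start}, {end})")
    if start <= end:
        return [(start, end)]
    # crosses the origin
    return [(start, mt_length), (1, end)]


def mt_interval_length(start: int, end: int, mt_length: int) -> int:
    """Length (bp) of a 1-based inclusive, possibly origin-crossing mt interval."""
    return sum(e - s + 1 for s, e in normalize_mt_interval(start, end, mt_length))


def circular_distance(a: int, b: int, mt_length: int) -> int:
    """Minimal distance between two mt positions on the circle."""
    d = abs(a - b) % mt_length
    return min(d, mt_length - d)
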