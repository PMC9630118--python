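"""Base-pair breakpoint refinement from soft-clipped reads and junction typing.

Clipped segments are realigned by exhaustive local (infix) alignment over
both strands of the full mtDNA and of the nuclear candidate window —
a desk-scale stand-in for a genome-wide local aligner with an explicit
acceptance contract: aligned length >= 20 and identity >= 90%. Untemplated
junction bases are recovered by trimming the junction-adjacent end of the
clipped segment and charging one unit per trimmed base, so the minimal-cost
placement separates inserted bases from the templated mt (or nuclear)
segment.

Junction mechanism classes follow the double-strand-break repair taxonomy:
microhomology (>=1 shared base across the junction, MMEJ-like), blunt
(clean abutment, classical NHEJ), and insertion (untemplated bases at the
junction). The breakpoint is reported at the mtDNA-proximal end of any
homology tract and the homology length recorded, so consumers can recover
the placement ambiguity interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
from scipy.stats import binomtest

from .formats_io import AlignedRead, ReferenceGenome
from .synthetic_data import revcomp
from .detection import NumtCandidate, _arc_linear_parts

MIN_CLIP_BP = 20
SPLIT_SEARCH_BP = 1000
MIN_SPLIT_SUPPORT = 3
MIN_IDENTITY = 0.90
MAX_MICROHOMOLOGY_SCAN = 30
MAX_JUNCTION_INSERTION = 20


@dataclass
class SplitReadAlignment:
    """A read resolved into a primary segment and a realigned clipped segment."""

    read_id: str
    sample_id: str
    segment_a: tuple[str, tuple[int, int], str]  # primary (contig, 0-based interval, strand)
    segment_b: tuple[str, tuple[int, int], str]  # realigned clipped segment
    query_breakpoint: int  # clip boundary in the SAM-stored (ref-forward) read
    overlap_len: int
    unaligned_gap: int
    clip_side: str  # "left" | "right" relative to the primary alignment
    inserted_seq: str = ""

    @property
    def primary_junction_pos(self) -> int:
        """1-based position of the junction-adjacent base of the primary segment.

        For a right clip this is the last aligned base; for a left clip the
        first aligned base minus one — both equal the 1-based coordinate of
        the last nuclear base before the insertion when the primary segment
        is the nuclear anchor.
        """
        contig, (start, end), _ = self.segment_a
        return end if self.clip_side == "right" else start

    @property
    def clipped_junction_pos(self) -> int:
        """1-based mt (or nuclear) coordinate where the clipped segment meets
        the junction: its first base when alignment continues forward, its
        last base otherwise."""
        contig, (start, end), strand = self.segment_b
        if self.clip_side == "right":
            return start + 1 if strand == "+" else end
        return end if strand == "+" else start + 1


@dataclass
class Breakpoint:
    numt_id: str
    side: str  # nuclear | mt_left | mt_right
    contig: str
    position: int  # 1-based in reports
    split_support: int
    strand: str = "+"  # insert orientation at the breakpoint (mt sides)


@dataclass
class JunctionClassification:
    numt_id: str
    junction_side: str  # left | right
    junction_class: str  # microhomology | blunt | insertion
    microhomology_len: int
    inserted_seq: str

    def __post_init__(self) -> None:
        assert (self.junction_class == "microhomology") == (self.microhomology_len >= 1)
        assert (self.junction_class == "insertion") == (len(self.inserted_seq) >= 1)


def collect_split_reads(
    reads: Iterable[AlignedRead],
    candidate: NumtCandidate,
    mt_name: str,
    mt_length: int,
    min_clip: int = MIN_CLIP_BP,
    window: int = SPLIT_SEARCH_BP,
) -> list[AlignedRead]:
    """Soft-clipped reads whose aligned portion lies within ``window`` bp of
    the candidate's nuclear or mt span."""
    ns, ne = candidate.nuclear_span
    mt_parts = _arc_linear_parts(candidate.mt_span, mt_length)
    out = []
    for read in reads:
        if read.contig is None or read.mapq == 0:
            continue
        if max(read.clips()) < min_clip:
            continue
        if read.contig == candidate.nuclear_contig:
            if read.start < ne + window and read.end > ns - window:
                out.append(read)
        elif read.contig == mt_name:
            for s, e in mt_parts:
                if read.start < e + window and read.end > s - window:
                    out.append(read)
                    break
    return out


def _map_location(
    loc: tuple[int, int], strand: str, target_offset: int, target_len: int
) -> tuple[int, int]:
    """edlib inclusive location on a (possibly revcomp) target -> 0-based
    half-open interval on the forward reference."""
    s, e = loc[0], loc[1] + 1
    if strand == "+":
        return target_offset + s, target_offset + e
    return target_offset + target_len - e, target_offset + target_len - s


def realign_split_read(
    read: AlignedRead,
    reference: ReferenceGenome,
    candidate: Optional[NumtCandidate] = None,
    min_clip: int = MIN_CLIP_BP,
    targets: Optional[list[tuple[str, int, str]]] = None,
    window: int = SPLIT_SEARCH_BP,
    max_insertion: int = MAX_JUNCTION_INSERTION,
) -> Optional[SplitReadAlignment]:
    """Locally realign the clipped segment of a soft-clipped read.

    Search space: both strands of the full mtDNA plus, when a candidate is
    given, both strands of the nuclear window (+- ``window`` bp around the
    candidate span). Acceptance: aligned length >= 20 and identity >= 90%.
    Untemplated junction bases are recovered by trimming up to
    ``max_insertion`` junction-adjacent bases at one edit each; ties prefer
    fewer trimmed bases. Multiple equal-best placements -> None (ambiguous).
    """
    left, right = read.clips()
    if max(left, right) < min_clip:
        return None
    clip_side = "right" if right >= left else "left"
    clip_len = right if clip_side == "right" else left
    seq = read.sequence
    clipped = seq[-clip_len:] if clip_side == "right" else seq[:clip_len]
    if set(clipped) <= {"N"}:
        return None

    if targets is None:
        targets = [(reference.mt_name, 0, len(reference.mt_sequence))]
        if candidate is not None and candidate.nuclear_contig != reference.mt_name:
            ns, ne = candidate.nuclear_span
            ws = max(0, ns - window)
            we = min(len(reference.contigs[candidate.nuclear_contig]), ne + window)
            targets.append((candidate.nuclear_contig, ws, we - ws))
    search: list[tuple[str, int, int, str, str]] = []
    for contig, off, ln in targets:
        tseq = reference.contigs[contig][off : off + ln]
        search.append((contig, off, ln, "+", tseq))
        search.append((contig, off, ln, "-", revcomp(tseq)))

    best = None  # (cost, gap, dist, placements)
    max_ins = min(max_insertion, clip_len - 20)
    for gap in range(0, max(0, max_ins) + 1):
        # trim the junction-adjacent end: clip start for a right clip,
        # clip end for a left clip
        q = clipped[gap:] if clip_side == "right" else clipped[: clip_len - gap or None]
        placements = []
        dist_best = None
        # the acceptance contract (identity >= 90%) bounds the useful edit
        # distance, so cap the search for speed
        k_cap = int((1 - MIN_IDENTITY) * len(q)) + 1
        for contig, off, ln, strand, tseq in search:
            res = edlib.align(q, tseq, mode="HW", task="locations", k=k_cap)
            d = res["editDistance"]
            if d < 0:
                continue
            if dist_best is None or d < dist_best:
                dist_best = d
                placements = [(contig, off, ln, strand, loc) for loc in res["locations"]]
            elif d == dist_best:
                placements.extend(
                    (contig, off, ln, strand, loc) for loc in res["locations"]
                )
        if dist_best is None:
            continue
        cost = dist_best + gap
        # prefer lower total cost; at equal cost prefer the placement with
        # fewer edits (i.e. attribute mismatching junction-adjacent bases to
        # untemplated insertion rather than to alignment errors)
        if best is None or (cost, dist_best) < (best[0], best[2]):
            best = (cost, gap, dist_best, placements, q)
        if best is not None and gap >= best[0]:
            break  # larger gaps cost > best and cannot tie with fewer edits
    if best is None:
        return None
    cost, gap, dist, placements, q = best
    if len(q) < 20 or dist > (1 - MIN_IDENTITY) * len(q):
        return None
    # collapse duplicate reported locations (edlib may repeat equivalent ends)
    uniq = {(c, _map_location(loc, s, off, ln), s) for c, off, ln, s, loc in placements}
    if len(uniq) != 1:
        return None
    contig_b, interval_b, strand_b = next(iter(uniq))

    inserted = (
        clipped[:gap] if clip_side == "right" else clipped[clip_len - gap :]
    )
    return SplitReadAlignment(
        read_id=read.read_id,
        sample_id=read.sample_id,
        segment_a=(read.contig, (read.start, read.end), read.strand),
        segment_b=(contig_b, interval_b, strand_b),
        query_breakpoint=len(seq) - clip_len if clip_side == "right" else clip_len,
        overlap_len=0,
        unaligned_gap=gap,
        clip_side=clip_side,
        inserted_seq=inserted,
    )


def _modal(values: Iterable[int]) -> tuple[int, int]:
    """(mode, count); ties broken toward the smallest value."""
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top), top


def define_breakpoints(
    splits: list[SplitReadAlignment],
    candidate: NumtCandidate,
    numt_id: str,
    mt_name: str,
    min_support: int = MIN_SPLIT_SUPPORT,
) -> tuple[list[Breakpoint], bool, dict]:
    """Modal junction positions per side from nuclear-anchored split reads.

    A side is reported only with >= ``min_support`` concordant split reads.
    Right-clipped nuclear reads evidence the junction where nuclear DNA
    enters the insert (mt_left); left-clipped reads the far junction
    (mt_right). The candidate is flagged complex when more than one nuclear
    breakpoint position reaches the support threshold.
    """
    nuclear_positions: list[int] = []
    sides: dict[str, list[SplitReadAlignment]] = {"mt_left": [], "mt_right": []}
    for sp in splits:
        if sp.segment_a[0] != candidate.nuclear_contig or sp.segment_b[0] != mt_name:
            continue
        nuclear_positions.append(sp.primary_junction_pos)
        sides["mt_left" if sp.clip_side == "right" else "mt_right"].append(sp)

    breakpoints: list[Breakpoint] = []
    complex_flag = False
    evidence: dict = {"mt_left": [], "mt_right": []}
    if len(nuclear_positions) >= min_support:
        mode, _ = _modal(nuclear_positions)
        breakpoints.append(
            Breakpoint(
                numt_id, "nuclear", candidate.nuclear_contig, mode,
                len(nuclear_positions),
            )
        )
        counts = Counter(nuclear_positions)
        complex_flag = sum(1 for c in counts.values() if c >= min_support) > 1
    for side, members in sides.items():
        if len(members) < min_support:
            continue
        positions = [sp.clipped_junction_pos for sp in members]
        mode, support = _modal(positions)
        strand_mode, _ = _modal_str([sp.segment_b[2] for sp in members])
        breakpoints.append(Breakpoint(numt_id, side, mt_name, mode, support, strand_mode))
        evidence[side] = members
    return breakpoints, complex_flag, evidence


def _modal_str(values: list[str]) -> tuple[str, int]:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top), top


def classify_junction(
    nuclear_bp: Breakpoint,
    mt_bp: Breakpoint,
    junction_side: str,
    reference: ReferenceGenome,
    splits: Optional[list[SplitReadAlignment]] = None,
    max_scan: int = MAX_MICROHOMOLOGY_SCAN,
) -> JunctionClassification:
    """Assign the junction mechanism class.

    Microhomology = the longest identical overlap (up to ``max_scan`` bp)
    between the nuclear flank and the mt flank read across the junction in
    insert orientation; untemplated inserted bases come from the modal
    non-templated gap of the supporting split reads. The classes partition:
    insertion when inserted bases exist, else microhomology when >= 1 shared
    base, else blunt.
    """
    if nuclear_bp is None or mt_bp is None:
        raise ValueError("both breakpoints must be defined for classification")
    nuc = reference.contigs[nuclear_bp.contig]
    mt = reference.mt_sequence
    L = len(mt)
    p = nuclear_bp.position  # 1-based last nuclear base before the insert
    m = mt_bp.position  # 1-based junction-adjacent insert base on mt
    strand = mt_bp.strand

    def mt_before(k: int) -> str:
        """k mt bases preceding the junction-adjacent base, insert orientation."""
        if strand == "+":
            return "".join(mt[(m - 1 - k + i) % L] for i in range(k))
        return revcomp("".join(mt[(m + i) % L] for i in range(k)))

    def mt_after(k: int) -> str:
        """k mt bases following the junction-adjacent base, insert orientation."""
        if strand == "+":
            return "".join(mt[(m + i) % L] for i in range(k))
        return revcomp("".join(mt[(m - 1 - k + i) % L] for i in range(k)))

    mh = 0
    for k in range(1, max_scan + 1):
        if junction_side == "left":
            if p - k < 0:
                break
            if nuc[p - k : p] == mt_before(k):
                mh = k
            else:
                break
        else:
            if p + k > len(nuc):
                break
            if nuc[p : p + k] == mt_after(k):
                mh = k
            else:
                break

    inserted = ""
    if splits:
        gaps = [sp.inserted_seq for sp in splits]
        mode, _ = _modal_str(gaps)
        inserted = mode
    if inserted:
        cls = "insertion"
        mh = 0
    elif mh >= 1:
        cls = "microhomology"
    else:
        cls = "blunt"
    return JunctionClassification(
        numt_id=nuclear_bp.numt_id,
        junction_side=junction_side,
        junction_class=cls,
        microhomology_len=mh,
        inserted_seq=inserted,
    )


def breakpoint_sequence_context(
    breakpoints: list[Breakpoint],
    reference: ReferenceGenome,
    poly_c_ks: tuple[int, ...] = (2, 3, 4),
) -> dict:
    """Trinucleotide context tallies and poly-C extension statistics.

    (a) The trinucleotide centred on each breakpoint base (+-1 bp) is tallied
    into 64 classes, separately for nuclear-side and mt-side breakpoints;
    minus-strand (reverse-oriented insert) contexts are reverse-complemented
    before tallying. (b) For each k, breakpoints whose k bases immediately
    beyond the mt breakpoint (outside the insert) are all C — all G for a
    minus-strand insert — are counted against the i.i.d. mononucleotide
    expectation N * f_C**k, with a two-sided exact binomial p-value.
    """
    mt = reference.mt_sequence
    L = len(mt)
    tri: dict[str, Counter] = {"nuclear": Counter(), "mt": Counter()}
    skipped = 0
    mt_bps = []
    for bp in breakpoints:
        if bp.side == "nuclear":
            seq = reference.contigs[bp.contig]
            i = bp.position - 1
            if i - 1 < 0 or i + 2 > len(seq):
                skipped += 1
                continue
            tri["nuclear"][seq[i - 1 : i + 2]] += 1
        else:
            i = bp.position - 1
            ctx = "".join(mt[(i - 1 + j) % L] for j in range(3))
            if bp.strand == "-":
                ctx = revcomp(ctx)
            tri["mt"][ctx] += 1
            mt_bps.append(bp)

    f_c = mt.count("C") / L
    poly_c = {}
    for k in poly_c_ks:
        observed = 0
        for bp in mt_bps:
            i = bp.position - 1
            if bp.side == "mt_left":
                # beyond = the k mt bases upstream of the fragment start,
                # read in insert orientation
                if bp.strand == "+":
                    beyond = "".join(mt[(i - k + j) % L] for j in range(k))
                    target = "C" * k
                else:
                    beyond = "".join(mt[(i + 1 + j) % L] for j in range(k))
                    target = "G" * k
            else:
                if bp.strand == "+":
                    beyond = "".join(mt[(i + 1 + j) % L] for j in range(k))
                    target = "C" * k
                else:
                    beyond = "".join(mt[(i - k + j) % L] for j in range(k))
                    target = "G" * k
            if beyond == target:
                observed += 1
        n = len(mt_bps)
        expected = n * f_c**k
        fold = observed / expected if expected > 0 else float("nan")
        pval = binomtest(observed, n, f_c**k).pvalue if n else float("nan")
        poly_c[k] = {
            "observed": observed,
            "expected": expected,
            "fold": fold,
            "p_value": pval,
        }
    return {
        "trinucleotides": {side: dict(c) for side, c in tri.items()},
        "poly_c": poly_c,
        "skipped": skipped,
        "mt_c_frequency": f_c,
    }


def refine_candidate(
    reads: list[AlignedRead],
    candidate: NumtCandidate,
    reference: ReferenceGenome,
    numt_id: str,
    min_clip: int = MIN_CLIP_BP,
) -> dict:
    """Full per-candidate refinement: collect, realign, define, classify."""
    clipped = collect_split_reads(
        reads, candidate, reference.mt_name, reference.mt_length, min_clip=min_clip
    )
    splits = []
    for read in clipped:
        sp = realign_split_read(read, reference, candidate, min_clip=min_clip)
        if sp is not None:
            splits.append(sp)
    bps, complex_flag, evidence = define_breakpoints(
        splits, candidate, numt_id, reference.mt_name
    )
    by_side = {bp.side: bp for bp in bps}
    classifications = []
    for side, mt_side in (("left", "mt_left"), ("right", "mt_right")):
        if "nuclear" in by_side and mt_side in by_side:
            classifications.append(
                classify_junction(
                    by_side["nuclear"],
                    by_side[mt_side],
                    side,
                    reference,
                    splits=evidence[mt_side],
                )
            )
    return {
        "breakpoints": bps,
        "complex": complex_flag,
        "junctions": classifications,
        "n_split_reads": len(splits),
    }
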