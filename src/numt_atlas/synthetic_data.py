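"""Synthetic cohorts of paired-end reads with planted NUMTs and truth.

The generator emulates the statistical structure the analysis assumes: donor
haplotypes are nuclear contigs with mtDNA-derived inserts spliced in, and the
"aligner" is emulated exactly — every read is placed on the reference at the
position implied by its donor block, reads overlapping an insertion junction
become soft-clipped alignments, and mates anchored across the insert become
nuclear–mt discordant pairs. Read placement is uniform (no GC bias) and
sequencing errors are off by default; these are orthogonal to the count-based
detection thresholds under study.

Junction structure follows the three insertional mechanisms: microhomology
(shared bases counted once at the splice), blunt, and short untemplated
insertions. Post-insertion evolution is emulated two ways: explicit planted
single-nucleotide variants, and age-driven reversion — at sites where the
ancestral (chimpanzee-like) mt sequence differs from the mt reference, the
insert carries the ancestral allele with probability ``age_fraction``.
``age_fraction`` is therefore the expected fraction of informative sites on
which the NUMT disagrees with the modern mt sequence, so the expected
molecular age is ``age_fraction * 6`` Myr under the linear dating transform.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pysam

from .formats_io import (
    ReferenceGenome,
    normalize_mt_interval,
    write_fasta,
)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class DesignError(ValueError):
    """Inconsistent simulation design."""


class ConfigurationError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class SimulatedNumt:
    """Ground truth for one planted NUMT.

    segments are 1-based inclusive mt intervals (start may exceed end for a
    fragment crossing the circular origin); more than one segment means a
    concatenated NUMT with internal mtDNA–mtDNA junctions. ``nuclear_pos`` is
    the 0-based index before which the insert is spliced (so the last
    retained nuclear base is 1-based position ``nuclear_pos``).
    """

    numt_id: str
    nuclear_contig: str
    nuclear_pos: int
    segments: list[tuple[int, int, str]]
    microhomology_len: int = 0
    inserted_bases: str = ""
    planted_variants: list[tuple[int, str, str]] = field(default_factory=list)
    age_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise DesignError(f"{self.numt_id}: needs at least one mt segment")
        if self.microhomology_len > 0 and self.inserted_bases:
            raise DesignError(
                f"{self.numt_id}: microhomology and inserted bases are exclusive"
            )
        if not 0.0 <= self.age_fraction <= 1.0:
            raise DesignError(f"{self.numt_id}: age_fraction outside [0, 1]")


#: smallest plantable NUMT segment, matching the smallest insertions the
#: short-read approach can evidence
MIN_SEGMENT_BP = 24


@dataclass
class CohortDesign:
    """Cohort layout and sequencing parameters.

    carriers maps numt_id -> list of carrier sample ids. Trios are
    (child, father, mother) sample-id triples; tumour_pairs are
    (tumour, normal). Defaults mirror a typical short-read WGS cohort:
    150 bp paired-end reads, 30x depth, ~400 bp inserts.
    """

    n_samples: int
    carriers: dict[str, list[str]] = field(default_factory=dict)
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    tumour_pairs: list[tuple[str, str]] = field(default_factory=list)
    read_length: int = 150
    mean_depth: float = 30.0
    insert_mean: float = 400.0
    insert_sd: float = 60.0
    error_rate: float = 0.0
    decoy_regions: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        if self.read_length < 20:
            raise ConfigurationError("read_length too short")
        for child, father, mother in self.trios:
            if len({child, father, mother}) != 3:
                raise DesignError(f"trio members not distinct: {(child, father, mother)}")

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]


def packaged_mt_path() -> str:
    """Path of the bundled synthetic 16,569 bp mt reference stand-in."""
    return str(resources.files("numt_atlas").joinpath("data/synthetic_rcrs.fa"))


def _packaged_mt_sequence() -> str:
    with open(packaged_mt_path()) as fh:
        return "".join(line.strip() for line in fh if not line.startswith(">")).upper()


def build_toy_references(
    nuclear_sizes: dict[str, int],
    mt_length: int = 16569,
    seed: int = 0,
    mt_mode: str = "packaged",
    mt_name: str = "chrM",
) -> ReferenceGenome:
    """Random-base nuclear contigs plus an mt contig; deterministic per seed.

    mt_mode "packaged" uses the bundled synthetic stand-in for the human mt
    reference (16,569 bp); "random" draws a random sequence of ``mt_length``.
    """
    if not nuclear_sizes:
        raise ConfigurationError("need at least one nuclear contig")
    if mt_length < 1000:
        raise ConfigurationError(
            "mt_length < 1000 is incompatible with the packaged mt region table"
        )
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    contigs: dict[str, str] = {}
    for name, size in nuclear_sizes.items():
        if size < 1000:
            raise ConfigurationError(f"nuclear contig {name} too short ({size} bp)")
        contigs[name] = rng.choice(bases, size=size).tobytes().decode()
    if mt_mode == "packaged":
        mt_seq = _packaged_mt_sequence()
        if mt_length != len(mt_seq):
            raise ConfigurationError(
                f"packaged mt sequence is {len(mt_seq)} bp; pass mt_mode='random' "
                f"for mt_length={mt_length}"
            )
    elif mt_mode == "random":
        mt_seq = rng.choice(bases, size=mt_length).tobytes().decode()
    else:
        raise ConfigurationError(f"unknown mt_mode {mt_mode!r}")
    contigs[mt_name] = mt_seq
    return ReferenceGenome(contigs=contigs, mt_name=mt_name)


def make_ancestral_mt(
    reference: ReferenceGenome, divergence: float = 0.08, seed: int = 2020
) -> str:
    """Synthetic ancestral (chimpanzee-like) mt sequence.

    Substitutes a deterministic random ``divergence`` fraction of mt sites; a
    real ancestral mt FASTA can be used instead wherever a sequence of mt
    length is accepted. Divergence defaults to the rough human–chimp mtDNA
    distance so that short fragments still contain informative sites.
    """
    rng = np.random.default_rng(seed)
    mt = list(reference.mt_sequence)
    n_sites = int(round(divergence * len(mt)))
    sites = rng.choice(len(mt), size=n_sites, replace=False)
    for pos in sites:
        alts = [b for b in "ACGT" if b != mt[pos]]
        mt[pos] = alts[rng.integers(0, 3)]
    return "".join(mt)


# ---------------------------------------------------------------------------
# donor construction


@dataclass
class Block:
    """Maps a donor-contig slice back to the reference.

    ``ref_contig`` is None for untemplated inserted bases. For strand "-",
    donor offset o within the block corresponds to reference position
    ``ref_start + (length - 1 - o)``.
    """

    start: int
    end: int
    ref_contig: Optional[str]
    ref_start: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DonorContig:
    name: str
    sequence: str
    blocks: list[Block]


def _build_insert(
    numt: SimulatedNumt,
    reference: ReferenceGenome,
    ancestral_mt: str,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int, str]], list[int]]:
    """Insert sequence, its relative block map and realized reversion sites.

    Returned blocks are (rel_start, ref_start_0based, strand) triples of
    equal-length runs mapping insert offsets to mt coordinates; reversion
    sites are 1-based mt positions where the ancestral allele was planted.
    """
    mt = reference.mt_sequence
    L = reference.mt_length
    parts: list[str] = []
    rel_blocks: list[tuple[int, int, int, str]] = []  # rel_start, ref_start, length, strand
    offset = 0
    for seg_start, seg_end, orient in numt.segments:
        linear = normalize_mt_interval(seg_start, seg_end, L)
        seg_seq = "".join(mt[s - 1 : e] for s, e in linear)
        if len(seg_seq) < MIN_SEGMENT_BP:
            raise DesignError(
                f"{numt.numt_id}: segment {seg_start}-{seg_end} shorter than "
                f"{MIN_SEGMENT_BP} bp"
            )
        seg_blocks = [(s - 1, e - s + 1, "+") for s, e in linear]
        if orient == "-":
            seg_seq = revcomp(seg_seq)
            seg_blocks = [(s0, ln, "-") for s0, ln, _ in reversed(seg_blocks)]
        for s0, ln, strand in seg_blocks:
            rel_blocks.append((offset, s0, ln, strand))
            offset += ln
        parts.append(seg_seq)
    insert = list("".join(parts))

    def offsets_of(mt_pos0: int) -> list[tuple[int, str]]:
        out = []
        for rel, ref0, ln, strand in rel_blocks:
            if ref0 <= mt_pos0 < ref0 + ln:
                if strand == "+":
                    out.append((rel + (mt_pos0 - ref0), "+"))
                else:
                    out.append((rel + (ref0 + ln - 1 - mt_pos0), "-"))
        return out

    # age-driven reversion to the ancestral allele, one realization per NUMT
    reverted: list[int] = []
    if numt.age_fraction > 0:
        covered = sorted(
            {p for rel, ref0, ln, _ in rel_blocks for p in range(ref0, ref0 + ln)}
        )
        for mt_pos0 in covered:
            if ancestral_mt[mt_pos0] != mt[mt_pos0] and rng.random() < numt.age_fraction:
                reverted.append(mt_pos0 + 1)
                for off, strand in offsets_of(mt_pos0):
                    allele = ancestral_mt[mt_pos0]
                    insert[off] = allele if strand == "+" else revcomp(allele)

    for mt_pos, ref, alt in numt.planted_variants:
        if mt[mt_pos - 1] != ref:
            raise DesignError(
                f"{numt.numt_id}: planted variant ref {ref} != mt base at {mt_pos}"
            )
        for off, strand in offsets_of(mt_pos - 1):
            insert[off] = alt if strand == "+" else revcomp(alt)

    return "".join(insert), rel_blocks, reverted


def _resolve_microhomology(
    nuclear_seq: str, pos: int, insert: str, mh: int, search_window: int = 4000
) -> int:
    """Find the nearest splice point whose left flank ends with insert[:mh]."""
    want = insert[:mh]
    for delta in range(search_window):
        for cand in ((pos + delta), (pos - delta)) if delta else (pos,):
            if mh <= cand <= len(nuclear_seq) and nuclear_seq[cand - mh : cand] == want:
                return cand
    raise DesignError(
        f"no microhomology site for {want!r} within {search_window} bp of {pos}"
    )


def plant_numts(
    reference: ReferenceGenome,
    design: CohortDesign,
    numts: Sequence[SimulatedNumt],
    ancestral_mt: Optional[str] = None,
) -> tuple[dict[str, dict[str, DonorContig]], dict]:
    """Per-sample donor genomes plus a machine-readable truth dict.

    Microhomology splices count the shared bases once (donor gains
    ``len(insert) - mh`` bp); untemplated inserted bases are added between the
    nuclear flank and the mt-derived insert. When the requested splice point
    lacks the required homology the nearest position carrying it is used and
    recorded in the truth.
    """
    if ancestral_mt is None:
        ancestral_mt = make_ancestral_mt(reference)
    ids = set(design.sample_ids())
    for numt_id, carrier_list in design.carriers.items():
        missing = set(carrier_list) - ids
        if missing:
            raise DesignError(f"{numt_id}: unknown carriers {sorted(missing)}")

    # realize each insert once (shared by all carriers of the NUMT)
    realized: dict[str, dict] = {}
    for numt in numts:
        rng = np.random.default_rng(
            (design.seed * 1_000_003 + abs(hash(numt.numt_id))) % (2**31)
        )
        insert, blocks, reverted = _build_insert(numt, reference, ancestral_mt, rng)
        nuc_seq = reference.contigs[numt.nuclear_contig]
        pos = numt.nuclear_pos
        if not design.read_length <= pos <= len(nuc_seq) - design.read_length:
            raise DesignError(
                f"{numt.numt_id}: insertion point {pos} within a read length of a contig end"
            )
        mh = numt.microhomology_len
        if mh > 0:
            pos = _resolve_microhomology(nuc_seq, pos, insert, mh)
        realized[numt.numt_id] = {
            "numt": numt,
            "insert": insert,
            "blocks": blocks,
            "pos": pos,
            "reverted_sites": reverted,
        }

    donors: dict[str, dict[str, DonorContig]] = {}
    for sample in design.sample_ids():
        carried = [
            realized[nid]
            for nid in design.carriers
            if sample in design.carriers[nid]
        ]
        donors[sample] = _splice_sample(reference, design, carried, sample)

    truth = {
        "seed": design.seed,
        "n_samples": design.n_samples,
        "read_length": design.read_length,
        "mean_depth": design.mean_depth,
        "insert_mean": design.insert_mean,
        "insert_sd": design.insert_sd,
        "trios": [list(t) for t in design.trios],
        "tumour_pairs": [list(p) for p in design.tumour_pairs],
        "numts": [],
    }
    parent_of = {}
    for child, father, mother in design.trios:
        parent_of[child] = (father, mother)
    normal_of = dict(design.tumour_pairs)
    for numt in numts:
        info = realized[numt.numt_id]
        carrier_list = sorted(design.carriers.get(numt.numt_id, []))
        records = []
        for sample in carrier_list:
            de_novo = False
            if sample in parent_of:
                f, m = parent_of[sample]
                de_novo = f not in carrier_list and m not in carrier_list
            tumour_specific = (
                sample in normal_of and normal_of[sample] not in carrier_list
            )
            records.append(
                {"sample": sample, "de_novo": de_novo, "tumour_specific": tumour_specific}
            )
        truth["numts"].append(
            {
                "numt_id": numt.numt_id,
                "nuclear_contig": numt.nuclear_contig,
                "nuclear_pos": info["pos"],
                "segments": [list(s) for s in numt.segments],
                "microhomology_len": numt.microhomology_len,
                "inserted_bases": numt.inserted_bases,
                "insert_length": len(info["insert"]),
                "planted_variants": [list(v) for v in numt.planted_variants],
                "age_fraction": numt.age_fraction,
                "reverted_sites": info["reverted_sites"],
                "carriers": records,
                "frequency": len(carrier_list) / design.n_samples,
            }
        )
    return donors, truth


def _splice_sample(
    reference: ReferenceGenome,
    design: CohortDesign,
    carried: list[dict],
    sample: str,
) -> dict[str, DonorContig]:
    donor: dict[str, DonorContig] = {}
    by_contig: dict[str, list[dict]] = {}
    for info in carried:
        by_contig.setdefault(info["numt"].nuclear_contig, []).append(info)
    for name, seq in reference.contigs.items():
        events = sorted(by_contig.get(name, []), key=lambda i: i["pos"])
        if not events:
            donor[name] = DonorContig(
                name, seq, [Block(0, len(seq), name, 0, "+")]
            )
            continue
        positions = [e["pos"] for e in events]
        if len(set(positions)) != len(positions):
            raise DesignError(f"{sample}: overlapping planted NUMTs on {name}")
        pieces: list[str] = []
        blocks: list[Block] = []
        cursor = 0  # reference coordinate
        out = 0  # donor coordinate
        for info in events:
            numt: SimulatedNumt = info["numt"]
            pos = info["pos"]
            mh = numt.microhomology_len
            left = seq[cursor:pos]
            pieces.append(left)
            blocks.append(Block(out, out + len(left), name, cursor, "+"))
            out += len(left)
            if numt.inserted_bases:
                ins = numt.inserted_bases
                pieces.append(ins)
                blocks.append(Block(out, out + len(ins), None, 0, "+"))
                out += len(ins)
            insert = info["insert"][mh:]
            pieces.append(insert)
            rel_off = 0
            for rel, ref0, ln, strand in info["blocks"]:
                b_start, b_end = rel, rel + ln
                if b_end <= mh:
                    continue
                trim = max(0, mh - b_start)
                if strand == "+":
                    blocks.append(
                        Block(
                            out + rel_off,
                            out + rel_off + (ln - trim),
                            reference.mt_name,
                            ref0 + trim,
                            "+",
                        )
                    )
                else:
                    blocks.append(
                        Block(
                            out + rel_off,
                            out + rel_off + (ln - trim),
                            reference.mt_name,
                            ref0,
                            "-",
                        )
                    )
                rel_off += ln - trim
            out += len(insert)
            cursor = pos
        tail = seq[cursor:]
        pieces.append(tail)
        blocks.append(Block(out, out + len(tail), name, cursor, "+"))
        donor[name] = DonorContig(name, "".join(pieces), blocks)
    return donor


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimulatedRecord:
    """A placed read, ready to serialise as one SAM line."""

    read_id: str
    contig: str
    pos: int  # 0-based
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    is_reverse: bool
    is_read1: bool
    mate_contig: str = "*"
    mate_pos: int = -1
    mate_reverse: bool = False


def _place_read(
    donor: DonorContig,
    s: int,
    e: int,
    design_decoys: list[tuple[str, int, int]],
) -> Optional[tuple[str, int, list[tuple[str, int]], bool, int]]:
    """Emulate alignment of donor[s:e) against the reference.

    Returns (contig, ref_pos, cigar, flip, mapq) where ``flip`` means the
    donor-forward sequence aligns to the reference minus strand; the aligned
    portion is the overlap with the donor block of largest overlap, the rest
    soft-clipped (the junction-spanning read signature).
    """
    best = None
    for b in donor.blocks:
        if b.ref_contig is None:
            continue
        ovl = min(e, b.end) - max(s, b.start)
        if ovl > 0 and (best is None or ovl > best[0]):
            best = (ovl, b)
    if best is None:
        return None
    ovl, b = best
    a0, b0 = max(s, b.start), min(e, b.end)
    left_clip, right_clip = a0 - s, e - b0
    if b.strand == "+":
        ref_pos = b.ref_start + (a0 - b.start)
        cigar = [("S", left_clip), ("M", ovl), ("S", right_clip)]
        flip = False
    else:
        ref_pos = b.ref_start + (b.end - b0)
        cigar = [("S", right_clip), ("M", ovl), ("S", left_clip)]
        flip = True
    cigar = [(op, n) for op, n in cigar if n > 0]
    mapq = 60
    for contig, ds, de in design_decoys:
        if contig == b.ref_contig and ref_pos < de and ref_pos + ovl > ds:
            mapq = 0
            break
    return b.ref_contig, ref_pos, cigar, flip, mapq


def simulate_sample_reads(
    donor: dict[str, DonorContig],
    design: CohortDesign,
    sample: str,
    rng: np.random.Generator,
) -> list[SimulatedRecord]:
    """Uniform paired-end reads over every donor contig, placed on the reference."""
    if design.mean_depth < 0:
        raise ConfigurationError("depth must be >= 0")
    rl = design.read_length
    records: list[SimulatedRecord] = []
    for name in sorted(donor):
        dc = donor[name]
        L = len(dc.sequence)
        n_pairs = int(round(design.mean_depth * L / (2 * rl)))
        if n_pairs == 0:
            continue
        frags = rng.normal(design.insert_mean, design.insert_sd, size=n_pairs)
        frags = np.maximum(frags.round().astype(int), rl)
        frags = np.minimum(frags, L)
        starts = (rng.random(n_pairs) * (L - frags + 1)).astype(int)
        for i in range(n_pairs):
            fs, fl = int(starts[i]), int(frags[i])
            r1 = (fs, min(fs + rl, fs + fl))
            r2 = (max(fs + fl - rl, fs), fs + fl)
            p1 = _place_read(dc, r1[0], r1[1], design.decoy_regions)
            p2 = _place_read(dc, r2[0], r2[1], design.decoy_regions)
            if p1 is None or p2 is None:
                continue
            rid = f"{sample}:{name}:{i}"
            seq1 = dc.sequence[r1[0] : r1[1]]
            seq2 = revcomp(dc.sequence[r2[0] : r2[1]])
            if design.error_rate > 0:
                seq1 = _add_errors(seq1, rng, design.error_rate)
                seq2 = _add_errors(seq2, rng, design.error_rate)
            recs = []
            for (contig, pos, cigar, flip, mapq), seq, donor_fwd, is_r1 in (
                (p1, seq1, True, True),
                (p2, seq2, False, False),
            ):
                # SAM stores the sequence in reference-forward orientation
                read_is_rev = (not donor_fwd) != flip
                sam_seq = seq if not read_is_rev else revcomp(seq)
                recs.append(
                    SimulatedRecord(
                        read_id=rid,
                        contig=contig,
                        pos=pos,
                        mapq=mapq,
                        cigar=cigar,
                        seq=sam_seq,
                        is_reverse=read_is_rev,
                        is_read1=is_r1,
                    )
                )
            recs[0].mate_contig, recs[0].mate_pos = recs[1].contig, recs[1].pos
            recs[0].mate_reverse = recs[1].is_reverse
            recs[1].mate_contig, recs[1].mate_pos = recs[0].contig, recs[0].pos
            recs[1].mate_reverse = recs[0].is_reverse
            records.extend(recs)
    return records


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(0, 4)]
    return "".join(out)


def as_aligned_reads(records: list[SimulatedRecord], sample_id: str) -> list:
    """View simulated records as parsed alignments without a SAM round-trip.

    Equivalent to writing SAM and re-reading it (asserted in tests); used to
    keep large simulated cohorts in memory.
    """
    from .formats_io import AlignedRead

    out = []
    for rec in records:
        out.append(
            AlignedRead(
                read_id=rec.read_id,
                sample_id=sample_id,
                contig=rec.contig,
                start=rec.pos,
                cigar=list(rec.cigar),
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapq,
                mate_contig=rec.mate_contig if rec.mate_contig != "*" else None,
                mate_start=rec.mate_pos,
                is_supplementary=False,
                sequence=rec.seq,
                is_read1=rec.is_read1,
            )
        )
    return out


def write_sam(
    records: list[SimulatedRecord], reference: ReferenceGenome, path: str
) -> None:
    """Serialise simulated records as plain SAM (deterministic byte output)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in reference.contigs.items()
            ],
        }
    )
    tid = {name: i for i, name in enumerate(reference.contigs)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            flag = 0x1 | (0x40 if rec.is_read1 else 0x80)
            if rec.contig == rec.mate_contig:
                flag |= 0x2
            if rec.is_reverse:
                flag |= 0x10
            if rec.mate_reverse:
                flag |= 0x20
            a.flag = flag
            a.reference_id = tid[rec.contig]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            a.next_reference_id = tid.get(rec.mate_contig, -1)
            a.next_reference_start = rec.mate_pos
            out.write(a)


def simulate_cohort(
    reference: ReferenceGenome,
    design: CohortDesign,
    numts: Sequence[SimulatedNumt],
    out_dir: Optional[str] = None,
    ancestral_mt: Optional[str] = None,
) -> dict:
    """Plant NUMTs, simulate reads for every sample, optionally write files.

    Returns {"truth": ..., "reads": {sample: [SimulatedRecord]}, "donors": ...};
    when ``out_dir`` is given also writes reference FASTA, one SAM per sample,
    truth.json and manifest.tsv. A pure function of (reference, design, numts).
    """
    donors, truth = plant_numts(reference, design, numts, ancestral_mt=ancestral_mt)
    reads: dict[str, list[SimulatedRecord]] = {}
    for idx, sample in enumerate(design.sample_ids()):
        rng = np.random.default_rng((design.seed * 9_973 + idx * 7 + 1) % (2**31))
        reads[sample] = simulate_sample_reads(donors[sample], design, sample, rng)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(reference, os.path.join(out_dir, "reference.fa"))
        for sample in design.sample_ids():
            write_sam(reads[sample], reference, os.path.join(out_dir, f"{sample}.sam"))
        write_truth_set(truth, os.path.join(out_dir, "truth.json"))
        _write_manifest(design, os.path.join(out_dir, "manifest.tsv"))
    return {"truth": truth, "reads": reads, "donors": donors}


def write_truth_set(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth_set(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _write_manifest(design: CohortDesign, path: str) -> None:
    role: dict[str, list[str]] = {s: [] for s in design.sample_ids()}
    group: dict[str, str] = {s: "" for s in design.sample_ids()}
    for i, (child, father, mother) in enumerate(design.trios):
        for s, r in ((child, "child"), (father, "father"), (mother, "mother")):
            role[s].append(r)
            group[s] = f"trio{i}"
    for i, (tumour, normal) in enumerate(design.tumour_pairs):
        role[tumour].append("tumour")
        role[normal].append("normal")
        group[tumour] = group[normal] = f"pair{i}"
    with open(path, "w") as fh:
        fh.write("sample\trole\tgroup\n")
        for s in design.sample_ids():
            fh.write(f"{s}\t{','.join(role[s]) or 'cohort'}\t{group[s]}\n")
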