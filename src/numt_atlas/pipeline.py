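"""End-to-end conveniences tying detection, refinement, cohort unification
and evolution together for one cohort of per-sample alignments."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from . import breakpoints as bp
from . import cohort as co
from . import detection as det
from . import evolution as evo
from .formats_io import AlignedRead, ReferenceGenome
from .synthetic_data import revcomp


def process_sample(
    reads: Sequence[AlignedRead],
    reference: ReferenceGenome,
    min_support: int = 5,
) -> dict:
    """Discordant pairs, clusters and candidates for one sample."""
    pairs = det.extract_discordant_pairs(reads, reference)
    clusters = det.cluster_pairs(pairs)
    candidates = det.call_candidates(clusters, min_support, reference=reference)
    return {"pairs": pairs, "clusters": clusters, "candidates": candidates}


def refine_all(
    reads: Sequence[AlignedRead],
    candidates: Sequence[det.NumtCandidate],
    reference: ReferenceGenome,
) -> list[dict]:
    return [
        bp.refine_candidate(reads, cand, reference, f"cand{i}")
        for i, cand in enumerate(candidates)
    ]


def unify_samples(
    per_sample: dict[str, dict],
    reference: ReferenceGenome,
    n_samples: Optional[int] = None,
    family_of: Optional[dict[str, str]] = None,
    known_track=None,
) -> list[co.CohortNumt]:
    """Cohort NUMT loci from per-sample ``process_sample`` outputs."""
    candidates = [c for res in per_sample.values() for c in res["candidates"]]
    numts = co.unify_cohort_numts(candidates, reference.mt_length)
    co.classify_frequency_and_known(
        numts,
        n_samples if n_samples is not None else len(per_sample),
        known_track=known_track,
        family_of=family_of,
    )
    return numts


def numt_read_sequences(
    reads: Sequence[AlignedRead],
    candidate: det.NumtCandidate,
    pairs: Sequence[det.DiscordantPair],
    reference: ReferenceGenome,
    realign_cache: Optional[dict] = None,
    max_reads: int = 60,
) -> list[str]:
    """Read sequences attributable to one NUMT in one sample, mt-oriented.

    The mt-side mates of the candidate's discordant pairs (their SAM
    sequences are already reference-forward) plus realigned clipped
    segments of junction-spanning reads, flipped to mt-forward when the
    clipped segment aligned to the minus strand.
    """
    wanted = {p.read_id for p in candidate.pairs}
    seqs: list[str] = []
    for read in reads:
        if read.contig == reference.mt_name and read.read_id in wanted:
            # aligned portion only: soft-clipped tails belong to the nuclear
            # flank or to another segment of a concatenated insert
            left, right = read.clips()
            seq = read.sequence[left : len(read.sequence) - right or None]
            if len(seq) >= 25:
                seqs.append(seq)
    clipped = bp.collect_split_reads(
        reads, candidate, reference.mt_name, reference.mt_length
    )
    mt_targets = [(reference.mt_name, 0, reference.mt_length)]
    for read in clipped:
        # only the mt placement of the clipped piece matters for assembly;
        # cacheable because the target set is candidate-independent (key must
        # separate the two mates of a pair, which share the read id)
        key = (read.read_id, read.is_read1)
        if realign_cache is not None and key in realign_cache:
            sp = realign_cache[key]
        else:
            sp = bp.realign_split_read(read, reference, targets=mt_targets)
            if realign_cache is not None:
                realign_cache[key] = sp
        if sp is None or sp.segment_b[0] != reference.mt_name:
            continue
        side = sp.clip_side
        seq = read.sequence
        piece = seq[sp.query_breakpoint:] if side == "right" else seq[: sp.query_breakpoint]
        if sp.unaligned_gap:
            piece = (
                piece[sp.unaligned_gap:] if side == "right"
                else piece[: len(piece) - sp.unaligned_gap]
            )
        if sp.segment_b[2] == "-":
            piece = revcomp(piece)
        if len(piece) >= 25:
            seqs.append(piece)
    if len(seqs) > max_reads:
        # deterministic coverage cap keeps assembly cost bounded
        seqs = sorted(seqs)[:max_reads]
    return seqs


def consensuses_for_cohort(
    reads_by_sample: dict[str, Sequence[AlignedRead]],
    per_sample: dict[str, dict],
    cohort_numts: Sequence[co.CohortNumt],
    reference: ReferenceGenome,
) -> list[evo.NumtConsensus]:
    """Per (cohort NUMT, carrier) consensus assemblies."""
    member_of: dict[int, str] = {}
    for numt in cohort_numts:
        for cand in numt.members:
            member_of[id(cand)] = numt.cohort_numt_id
    out = []
    for sample, res in per_sample.items():
        reads = reads_by_sample[sample]
        realign_cache: dict = {}
        for cand in res["candidates"]:
            numt_id = member_of.get(id(cand))
            if numt_id is None:
                continue
            seqs = numt_read_sequences(
                reads, cand, res["pairs"], reference, realign_cache=realign_cache
            )
            if len(seqs) < 2:
                continue
            cons = evo.build_consensus(numt_id, sample, seqs, reference)
            if cons is not None:
                out.append(cons)
    return out


def refined_mt_breakpoints(
    refinements: Iterable[tuple[str, dict]]
) -> dict[str, tuple[int, int]]:
    """Map cohort NUMT id -> (mt_left, mt_right) positions where defined."""
    out: dict[str, tuple[int, int]] = {}
    for numt_id, refinement in refinements:
        sides = {b.side: b.position for b in refinement["breakpoints"]}
        if "mt_left" in sides and "mt_right" in sides:
            out[numt_id] = (sides["mt_left"], sides["mt_right"])
    return out
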