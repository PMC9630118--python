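"""mtDNA–mtDNA split-read junctions evidencing concatenated (mega-)NUMTs.

Reads soft-clipped on the mt contig whose clipped segment realigns elsewhere
on mtDNA mark internal junctions of concatenated inserts. Junctions are
collapsed across samples (±5 bp realignment jitter) and passed through a
filter cascade: (1) at least 3 split reads in at least one individual;
(2) at least 2 split reads per retained carrier; (3) neither position inside
the configurable exclusion windows around the mt origin (the D-loop termini,
where true mtDNA and NUMT junctions cannot be separated); (4) circular
distance between the two positions at least 50 bp (closer pairs may be
mtDNA deletions).

Trio transmission: a junction present in a child and the father but not the
mother is father-transmitted, the converse mother-transmitted, anything else
(both parents, neither, child-only) indeterminate. Presence in a parent is
at least one supporting split read — maximal sensitivity for excluding
de novo status.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .formats_io import AlignedRead, ReferenceGenome, circular_distance
from .breakpoints import realign_split_read, MIN_CLIP_BP

#: default exclusion windows around the mt origin, 1-based inclusive
DEFAULT_TERMINUS_WINDOWS = ((1, 100), (16470, 16569))
MIN_JUNCTION_SEPARATION_BP = 50
COLLAPSE_TOLERANCE_BP = 5


class ConsistencyError(ValueError):
    pass


@dataclass
class MtMtJunction:
    pos1: int  # 1-based, pos1 < pos2 after normalization
    pos2: int
    sample_counts: dict[str, int] = field(default_factory=dict)
    carriers: list[str] = field(default_factory=list)

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)


def extract_mt_mt_splits(
    reads: Iterable[AlignedRead],
    reference: ReferenceGenome,
    min_clip: int = MIN_CLIP_BP,
    min_separation: int = MIN_JUNCTION_SEPARATION_BP,
) -> list[tuple[int, int]]:
    """Per-sample raw (pos1, pos2) junction observations from split reads.

    The clipped segment competes against every contig (both strands); only
    reads whose best placement is back on mtDNA, at least ``min_separation``
    bp (circular) from the primary segment, yield a junction observation.
    """
    mt = reference.mt_name
    L = reference.mt_length
    targets = [(name, 0, len(seq)) for name, seq in reference.contigs.items()]
    out: list[tuple[int, int]] = []
    for read in reads:
        if read.contig != mt or read.mapq == 0:
            continue
        if max(read.clips()) < min_clip:
            continue
        sp = realign_split_read(read, reference, targets=targets, min_clip=min_clip)
        if sp is None or sp.segment_b[0] != mt:
            continue
        p_primary = sp.primary_junction_pos
        p_clip = sp.clipped_junction_pos
        if circular_distance(p_primary, p_clip, L) < min_separation:
            continue  # local jitter, not a junction
        out.append((min(p_primary, p_clip), max(p_primary, p_clip)))
    return out


def _collapse_junctions(
    observations: dict[str, list[tuple[int, int]]], tolerance: int
) -> list[tuple[tuple[int, int], dict[str, int]]]:
    """Group observations across samples, tolerating ±tolerance jitter.

    Single-linkage on (pos1, pos2) with Chebyshev distance <= tolerance;
    each group is reported at its modal position (ties to the smallest).
    """
    flat: list[tuple[int, int, str]] = []
    for sample, obs in observations.items():
        flat.extend((p1, p2, sample) for p1, p2 in obs)
    flat.sort()
    groups: list[list[tuple[int, int, str]]] = []
    for item in flat:
        placed = False
        for g in groups:
            if any(
                abs(item[0] - o[0]) <= tolerance and abs(item[1] - o[1]) <= tolerance
                for o in g
            ):
                g.append(item)
                placed = True
                break
        if not placed:
            groups.append([item])
    result = []
    for g in groups:
        counts = Counter((p1, p2) for p1, p2, _ in g)
        top = max(counts.values())
        pos = min(p for p, c in counts.items() if c == top)
        per_sample: Counter = Counter(sample for _, _, sample in g)
        result.append((pos, dict(per_sample)))
    return result


def filter_junctions(
    observations: dict[str, list[tuple[int, int]]],
    mt_length: int,
    terminus_windows: tuple[tuple[int, int], ...] = DEFAULT_TERMINUS_WINDOWS,
    min_separation: int = MIN_JUNCTION_SEPARATION_BP,
    min_reads_one_sample: int = 3,
    min_reads_per_carrier: int = 2,
    tolerance: int = COLLAPSE_TOLERANCE_BP,
) -> list[MtMtJunction]:
    """Collapse raw per-sample junction observations and apply the cascade."""
    L = mt_length
    junctions: list[MtMtJunction] = []
    for (p1, p2), per_sample in _collapse_junctions(observations, tolerance):
        # (1) >= min_reads_one_sample split reads in at least one individual
        if max(per_sample.values()) < min_reads_one_sample:
            continue
        # (2) carriers = samples with >= min_reads_per_carrier reads
        carriers = sorted(
            s for s, c in per_sample.items() if c >= min_reads_per_carrier
        )
        if not carriers:
            continue
        # (3) terminus exclusion windows
        if any(lo <= p <= hi for p in (p1, p2) for lo, hi in terminus_windows):
            continue
        # (4) positions too close may be mtDNA deletions
        if circular_distance(p1, p2, L) < min_separation:
            continue
        junctions.append(
            MtMtJunction(pos1=p1, pos2=p2, sample_counts=per_sample, carriers=carriers)
        )
    junctions.sort(key=lambda j: (j.pos1, j.pos2))
    return junctions


def detect_mt_mt_junctions(
    reads_by_sample: dict[str, Iterable[AlignedRead]],
    reference: ReferenceGenome,
    terminus_windows: tuple[tuple[int, int], ...] = DEFAULT_TERMINUS_WINDOWS,
    min_separation: int = MIN_JUNCTION_SEPARATION_BP,
    min_reads_one_sample: int = 3,
    min_reads_per_carrier: int = 2,
    tolerance: int = COLLAPSE_TOLERANCE_BP,
) -> list[MtMtJunction]:
    """Cohort-level mtDNA–mtDNA junction calling with the filter cascade."""
    observations = {
        sample: extract_mt_mt_splits(reads, reference, min_separation=min_separation)
        for sample, reads in reads_by_sample.items()
    }
    return filter_junctions(
        observations,
        reference.mt_length,
        terminus_windows=terminus_windows,
        min_separation=min_separation,
        min_reads_one_sample=min_reads_one_sample,
        min_reads_per_carrier=min_reads_per_carrier,
        tolerance=tolerance,
    )


def classify_transmission(
    junctions: list[MtMtJunction],
    trios: list[tuple[str, str, str]],
    cohort_samples: Optional[set[str]] = None,
) -> list[dict]:
    """Per (junction, trio) transmission table.

    Rows exist for trios whose child carries the junction. Presence in a
    parent is >= 1 supporting split read.
    """
    if cohort_samples is not None:
        for trio in trios:
            missing = set(trio) - cohort_samples
            if missing:
                raise ConsistencyError(f"pedigree samples not in cohort: {sorted(missing)}")
    rows = []
    for j in junctions:
        for child, father, mother in trios:
            if child not in j.carriers:
                continue
            in_f = j.sample_counts.get(father, 0) >= 1
            in_m = j.sample_counts.get(mother, 0) >= 1
            if in_f and not in_m:
                status = "father-transmitted"
            elif in_m and not in_f:
                status = "mother-transmitted"
            elif in_f and in_m:
                status = "indeterminate"
            else:
                status = "indeterminate"  # candidate de novo, flagged below
            rows.append(
                {
                    "pos1": j.pos1,
                    "pos2": j.pos2,
                    "child": child,
                    "father": father,
                    "mother": mother,
                    "status": status,
                    "candidate_de_novo": not in_f and not in_m,
                }
            )
    return rows


def cross_reference_rare_junctions(
    junctions: list[MtMtJunction],
    numt_carriers: dict[str, set[str]],
    n_samples: int,
    max_frequency: float = 0.01,
) -> list[dict]:
    """For rare junctions (F < max_frequency), do carriers share a NUMT call?

    ``numt_carriers`` maps cohort NUMT id -> carrier sample set.
    """
    rows = []
    for j in junctions:
        freq = j.carrier_count / n_samples
        if freq >= max_frequency or j.carrier_count < 2:
            continue
        shared = sorted(
            nid
            for nid, carriers in numt_carriers.items()
            if set(j.carriers) <= carriers
        )
        rows.append(
            {
                "pos1": j.pos1,
                "pos2": j.pos2,
                "frequency": freq,
                "carriers": j.carriers,
                "shared_numts": shared,
                "share_a_numt": bool(shared),
            }
        )
    return rows
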