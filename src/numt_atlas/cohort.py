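"""Cohort-level NUMT loci: unification, frequency classes, known-NUMT match.

Per-sample candidates are grouped across samples by the same rule used
within samples: single linkage, members within 1,000 bp on the nuclear
genome AND 1,000 bp (circular) on mtDNA. Frequency classes follow the
standard population-frequency thresholds — common (F >= 1%), rare
(0.1% <= F < 1%), ultra-rare (F < 0.1%) — with "private" meaning all
carriers belong to a single family. A locus is "known" when a
previously-reported NUMT interval overlaps the call's nuclear locus
extended by 500 bp on each side, regardless of the mt fragment involved.

F is computed over individuals (one genome each); callers with duplicate
genomes per individual should collapse them to the union of calls first.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .detection import NumtCandidate, _arc_linear_parts, _circular_gap
from .formats_io import IntervalTrack

MERGE_DISTANCE_BP = 1000
KNOWN_FLANK_BP = 500
COMMON_F = 0.01
RARE_F = 0.001


class ConsistencyError(ValueError):
    pass


@dataclass
class CohortNumt:
    cohort_numt_id: str
    nuclear_contig: str
    start: int  # representative nuclear locus, 0-based half-open
    end: int
    mt_span: tuple[int, int]  # 0-based; start > end means origin-crossing
    carriers: set[str] = field(default_factory=set)
    families: set[str] = field(default_factory=set)
    frequency: float = 0.0
    size_bp: int = 0
    freq_class: str = ""
    private: bool = False
    known: bool = False
    members: list[NumtCandidate] = field(default_factory=list, repr=False)
    nuclear_breakpoint: Optional[int] = None  # refined, 1-based

    @property
    def support_total(self) -> int:
        return sum(c.support for c in self.members)


def _median_low(values: Sequence[int]) -> int:
    """Median with ties resolved toward the smaller coordinate."""
    return int(statistics.median_low(sorted(values)))


def _arc_size(arc: tuple[int, int], length: int) -> int:
    return sum(e - s for s, e in _arc_linear_parts(arc, length))


def unify_cohort_numts(
    candidates: Sequence[NumtCandidate],
    mt_length: int,
    refined_positions: Optional[dict[int, int]] = None,
    merge_distance: int = MERGE_DISTANCE_BP,
) -> list[CohortNumt]:
    """Cross-sample single-linkage grouping into cohort NUMT loci.

    ``refined_positions`` optionally maps candidate index -> refined 1-based
    nuclear breakpoint; representative coordinates are medians over members
    (refined breakpoints preferred over cluster footprints), ties toward the
    smaller coordinate. Every candidate is assigned to exactly one locus.
    """
    if not candidates:
        return []
    refined_positions = refined_positions or {}
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (candidates[i].nuclear_contig,
                                            candidates[i].nuclear_span))
    for a in range(n):
        i = order[a]
        ci = candidates[i]
        for b in range(a + 1, n):
            j = order[b]
            cj = candidates[j]
            if ci.nuclear_contig != cj.nuclear_contig:
                break
            if cj.nuclear_span[0] - ci.nuclear_span[1] > merge_distance:
                break
            if _circular_gap(ci.mt_span, cj.mt_span, mt_length) <= merge_distance:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    numts = []
    for members_idx in sorted(groups.values(), key=lambda g: (
            candidates[g[0]].nuclear_contig, candidates[g[0]].nuclear_span)):
        members = [candidates[i] for i in members_idx]
        refined = [refined_positions[i] for i in members_idx if i in refined_positions]
        start = _median_low([c.nuclear_span[0] for c in members])
        end = _median_low([c.nuclear_span[1] for c in members])
        arc_starts = [c.mt_span[0] for c in members]
        arc_ends = [c.mt_span[1] for c in members]
        mt_span = (_median_low(arc_starts), _median_low(arc_ends))
        numts.append(
            CohortNumt(
                cohort_numt_id="",
                nuclear_contig=members[0].nuclear_contig,
                start=start,
                end=end,
                mt_span=mt_span,
                carriers={c.sample_id for c in members},
                size_bp=_arc_size(mt_span, mt_length),
                members=members,
                nuclear_breakpoint=_median_low(refined) if refined else None,
            )
        )
    numts.sort(key=lambda x: (x.nuclear_contig, x.start, x.end))
    for k, numt in enumerate(numts):
        numt.cohort_numt_id = f"NUMT{k:04d}"
    return numts


def classify_frequency_and_known(
    numts: list[CohortNumt],
    n_samples: int,
    known_track: Optional[IntervalTrack] = None,
    family_of: Optional[dict[str, str]] = None,
    flank: int = KNOWN_FLANK_BP,
) -> list[CohortNumt]:
    """Annotate frequency class, privateness and known status in place.

    Boundaries are inclusive on the common side: F = 1% exactly is common,
    F = 0.1% exactly is rare. Samples missing from the family manifest raise
    a consistency error; singleton samples are their own family.
    """
    for numt in numts:
        numt.frequency = len(numt.carriers) / n_samples
        if numt.frequency >= COMMON_F:
            numt.freq_class = "common"
        elif numt.frequency >= RARE_F:
            numt.freq_class = "rare"
        else:
            numt.freq_class = "ultra_rare"
        if family_of is not None:
            missing = numt.carriers - set(family_of)
            if missing:
                raise ConsistencyError(f"carriers without family: {sorted(missing)}")
            numt.families = {family_of[s] for s in numt.carriers}
        else:
            numt.families = set(numt.carriers)  # singletons are their own family
        numt.private = len(numt.families) == 1
        if known_track is not None:
            lo, hi = numt.start - flank, numt.end + flank
            numt.known = any(
                iv[0] == numt.nuclear_contig and iv[1] < hi and iv[2] > lo
                for iv in known_track.intervals
            )
    return numts


def cohort_summaries(
    numts: list[CohortNumt], samples: Sequence[str]
) -> dict:
    """Per-individual burden, size–frequency correlation, group comparison.

    Returns mean and s.d. of NUMT count per individual (zero-carriers
    included), the Pearson correlation between mt fragment size and cohort
    frequency (NA when fewer than 3 loci), and n for every statistic.
    """
    counts = {s: 0 for s in samples}
    for numt in numts:
        for s in numt.carriers:
            if s in counts:
                counts[s] += 1
    values = np.array([counts[s] for s in samples], dtype=float)
    out = {
        "n_samples": len(samples),
        "n_cohort_numts": len(numts),
        "mean_numts_per_individual": float(values.mean()) if len(values) else float("nan"),
        "sd_numts_per_individual": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    }
    if len(numts) >= 3:
        sizes = np.array([x.size_bp for x in numts], dtype=float)
        freqs = np.array([x.frequency for x in numts], dtype=float)
        if np.ptp(sizes) > 0 and np.ptp(freqs) > 0:
            r, p = stats.pearsonr(sizes, freqs)
            out["size_frequency_pearson_r"] = float(r)
            out["size_frequency_p"] = float(p)
        else:
            out["size_frequency_pearson_r"] = float("nan")
            out["size_frequency_p"] = float("nan")
    else:
        out["size_frequency_pearson_r"] = float("nan")
        out["size_frequency_p"] = float("nan")
    return out


def rank_sum_comparison(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison utility."""
    res = stats.mannwhitneyu(group_a, group_b, alternative="two-sided")
    return {
        "n_a": len(group_a),
        "n_b": len(group_b),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }
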