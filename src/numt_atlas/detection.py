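"""Per-sample NUMT candidate calling from nuclear–mt discordant read pairs.

A discordant pair has one mate on a nuclear contig and the other on the mt
contig; pairs where either mate has MAPQ 0 are discarded. Pairs are
single-linkage clustered on the nuclear anchor start within 500 bp,
separately per (nuclear contig, orientation signature), where the
orientation signature is the (nuclear strand, mt strand) of the anchors —
the standard discordant-cluster convention. Clusters below the support
threshold are dropped, and surviving clusters whose nuclear spans lie within
1,000 bp and whose mt spans lie within 1,000 bp (circular distance) are
merged into one candidate with summed support, so the two junction-side
clusters of a single insertion coalesce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .formats_io import AlignedRead, ReferenceGenome

CLUSTER_DISTANCE_BP = 500
MERGE_DISTANCE_BP = 1000


class ConfigurationError(ValueError):
    pass


@dataclass
class DiscordantPair:
    sample_id: str
    nuclear_contig: str
    nuclear_interval: tuple[int, int]  # 0-based half-open
    nuclear_strand: str
    mt_interval: tuple[int, int]
    mt_strand: str
    read_id: str

    @property
    def signature(self) -> tuple[str, str]:
        return (self.nuclear_strand, self.mt_strand)


@dataclass
class NumtCandidate:
    sample_id: str
    nuclear_contig: str
    nuclear_span: tuple[int, int]  # 0-based half-open cluster footprint
    mt_span: tuple[int, int]  # 0-based; start > end means origin-crossing arc
    support: int
    signatures: frozenset[tuple[str, str]]
    pairs: list[DiscordantPair] = field(default_factory=list, repr=False)


def extract_discordant_pairs(
    reads: Iterable[AlignedRead], reference: ReferenceGenome
) -> list[DiscordantPair]:
    """Retain read pairs with one nuclear and one mt end, both MAPQ > 0."""
    mt = reference.mt_name
    by_id: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.is_supplementary or read.contig is None:
            continue
        by_id.setdefault(read.read_id, []).append(read)
    pairs: list[DiscordantPair] = []
    seen: set[str] = set()
    for read_id, mates in by_id.items():
        if read_id in seen or len(mates) != 2:
            continue
        seen.add(read_id)
        a, b = mates
        if a.mapq == 0 or b.mapq == 0:
            continue
        contigs = {a.contig, b.contig}
        if mt not in contigs or len(contigs) != 2:
            continue
        nuc, mtr = (a, b) if b.contig == mt else (b, a)
        pairs.append(
            DiscordantPair(
                sample_id=nuc.sample_id,
                nuclear_contig=nuc.contig,
                nuclear_interval=(nuc.start, nuc.end),
                nuclear_strand=nuc.strand,
                mt_interval=(mtr.start, mtr.end),
                mt_strand=mtr.strand,
                read_id=read_id,
            )
        )
    return pairs


def cluster_pairs(
    pairs: Iterable[DiscordantPair], max_gap: int = CLUSTER_DISTANCE_BP
) -> list[list[DiscordantPair]]:
    """Single-linkage clusters of nuclear anchor starts within ``max_gap``.

    Clusters never mix nuclear contigs or orientation signatures. Chaining is
    transitive: anchors at 100, 450, 900 form one cluster at the 500 bp gap.
    """
    groups: dict[tuple, list[DiscordantPair]] = {}
    for p in pairs:
        groups.setdefault((p.nuclear_contig, p.signature), []).append(p)
    clusters: list[list[DiscordantPair]] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda p: (p.nuclear_interval[0], p.read_id))
        current = [members[0]]
        for p in members[1:]:
            if p.nuclear_interval[0] - current[-1].nuclear_interval[0] <= max_gap:
                current.append(p)
            else:
                clusters.append(current)
                current = [p]
        clusters.append(current)
    return clusters


def _circular_arc(intervals: list[tuple[int, int]], length: int) -> tuple[int, int]:
    """Minimal arc (0-based, possibly wrapping) covering linear mt intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if len(merged) == 1:
        return merged[0][0], merged[0][1]
    # the covering arc is the complement of the largest circular gap
    best_gap, best_idx = -1, 0
    for i, (s, e) in enumerate(merged):
        nxt = merged[(i + 1) % len(merged)][0] + (length if i == len(merged) - 1 else 0)
        gap = nxt - e
        if gap > best_gap:
            best_gap, best_idx = gap, i
    start = merged[(best_idx + 1) % len(merged)][0]
    end = merged[best_idx][1]
    return start, end  # start > end means the arc wraps the origin


def _arc_linear_parts(arc: tuple[int, int], length: int) -> list[tuple[int, int]]:
    s, e = arc
    if s < e:
        return [(s, e)]
    return [(s, length), (0, e)]


def _circular_gap(a: tuple[int, int], b: tuple[int, int], length: int) -> int:
    """Minimal circular gap (0 on overlap) between two arcs."""
    best = None
    for s1, e1 in _arc_linear_parts(a, length):
        for s2, e2 in _arc_linear_parts(b, length):
            if s1 < e2 and s2 < e1:
                return 0
            gap = min((s2 - e1) % length, (s1 - e2) % length)
            best = gap if best is None else min(best, gap)
    return best


def call_candidates(
    clusters: list[list[DiscordantPair]],
    min_support: int = 5,
    reference: Optional[ReferenceGenome] = None,
    mt_length: Optional[int] = None,
    merge_distance: int = MERGE_DISTANCE_BP,
) -> list[NumtCandidate]:
    """Support-filter clusters and merge same-NUMT clusters.

    Clusters with fewer than ``min_support`` pairs are removed (2 for the
    sensitive set, 5 for the stringent set). Survivors within 1,000 bp on the
    nuclear genome AND 1,000 bp on mtDNA (circular distance) are merged into
    one candidate with summed support — single linkage, so the two junction
    clusters of one insertion merge through their shared mt fragment.
    """
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")
    if mt_length is None:
        if reference is None:
            raise ConfigurationError("need reference or mt_length")
        mt_length = reference.mt_length
    kept = [c for c in clusters if len(c) >= min_support]
    if not kept:
        return []
    protos = []
    for c in kept:
        nuc_span = (
            min(p.nuclear_interval[0] for p in c),
            max(p.nuclear_interval[1] for p in c),
        )
        mt_span = _circular_arc([p.mt_interval for p in c], mt_length)
        protos.append((c, nuc_span, mt_span))

    parent = list(range(len(protos)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(protos)):
        for j in range(i + 1, len(protos)):
            ci, cj = protos[i], protos[j]
            if ci[0][0].nuclear_contig != cj[0][0].nuclear_contig:
                continue
            nuc_gap = max(
                ci[1][0] - cj[1][1], cj[1][0] - ci[1][1], 0
            )
            if nuc_gap > merge_distance:
                continue
            if _circular_gap(ci[2], cj[2], mt_length) > merge_distance:
                continue
            parent[find(i)] = find(j)

    merged: dict[int, list[int]] = {}
    for i in range(len(protos)):
        merged.setdefault(find(i), []).append(i)

    candidates = []
    for members in merged.values():
        pairs = [p for m in members for p in protos[m][0]]
        nuc_span = (
            min(protos[m][1][0] for m in members),
            max(protos[m][1][1] for m in members),
        )
        mt_span = _circular_arc(
            [iv for m in members for iv in _arc_linear_parts(protos[m][2], mt_length)],
            mt_length,
        )
        candidates.append(
            NumtCandidate(
                sample_id=pairs[0].sample_id,
                nuclear_contig=pairs[0].nuclear_contig,
                nuclear_span=nuc_span,
                mt_span=mt_span,
                support=len(pairs),
                signatures=frozenset(p.signature for p in pairs),
                pairs=sorted(pairs, key=lambda p: (p.nuclear_interval[0], p.read_id)),
            )
        )
    candidates.sort(key=lambda c: (c.nuclear_contig, c.nuclear_span))
    return candidates


def detect_sample(
    reads: Iterable[AlignedRead],
    reference: ReferenceGenome,
    min_support: int = 5,
) -> list[NumtCandidate]:
    """Convenience: discordant-pair extraction, clustering and calling."""
    pairs = extract_discordant_pairs(reads, reference)
    return call_candidates(cluster_pairs(pairs), min_support, reference=reference)
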