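"""De novo (trio) and tumour-specific NUMT calling, rates and associations.

A trio NUMT is de novo when the child shows at least five supporting
discordant pairs and neither parent shows even two discordant pairs at the
locus (the parental re-check deliberately drops the threshold from five to
two for sensitivity), and the insert sequence has no second near-perfect
placement in the nuclear reference — otherwise the "NUMT" could be a copy
of existing nuclear sequence rather than a fresh mtDNA insertion.

Tumour-specific NUMTs require at least five discordant pairs in the tumour
and zero in the matched normal; lost NUMTs at least five in the normal and
at most one in the tumour. Insertion rates are events/denominator with
exact (Clopper–Pearson) binomial 95% intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
from scipy import stats

from .detection import DiscordantPair, NumtCandidate, _circular_gap
from .formats_io import ReferenceGenome
from .synthetic_data import revcomp

LOCUS_MATCH_BP = 1000
DE_NOVO_CHILD_SUPPORT = 5
DE_NOVO_PARENT_RECHECK = 2
TUMOUR_SUPPORT = 5
LOST_TUMOUR_MAX = 1


class ConsistencyError(ValueError):
    pass


@dataclass
class RateEstimate:
    """Insertion rate with exact binomial confidence interval."""

    events: int
    denominator: int
    rho: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


@dataclass
class TwoByTwoResult:
    table: tuple[int, int, int, int]
    odds_ratio: float
    fisher_p: float
    ci_low: float
    ci_high: float
    continuity_note: bool = False


def _locus_matches(
    candidate: NumtCandidate,
    pair: DiscordantPair,
    mt_length: int,
    distance: int = LOCUS_MATCH_BP,
) -> bool:
    if pair.nuclear_contig != candidate.nuclear_contig:
        return False
    ns, ne = candidate.nuclear_span
    gap = max(pair.nuclear_interval[0] - ne, ns - pair.nuclear_interval[1], 0)
    if gap > distance:
        return False
    return _circular_gap(candidate.mt_span, pair.mt_interval, mt_length) <= distance


def locus_pair_count(
    candidate: NumtCandidate,
    pairs: Sequence[DiscordantPair],
    mt_length: int,
    distance: int = LOCUS_MATCH_BP,
) -> int:
    """Discordant pairs in a sample matching a candidate locus (both genomes)."""
    return sum(1 for p in pairs if _locus_matches(candidate, p, mt_length, distance))


def insert_is_unique(
    candidate: NumtCandidate,
    reference: ReferenceGenome,
    identity: float = 0.95,
    coverage: float = 0.90,
) -> bool:
    """True when the candidate's mt fragment has no near-perfect second
    placement in the nuclear reference (a desk-scale analogue of checking
    de novo assemblies for alternative nuclear origins)."""
    from .detection import _arc_linear_parts

    mt = reference.mt_sequence
    frag = "".join(
        mt[s:e] for s, e in _arc_linear_parts(candidate.mt_span, reference.mt_length)
    )
    if len(frag) < 30:
        return True  # too short to assess; paper notes short NUMTs are uncertain
    min_len = int(math.ceil(coverage * len(frag)))
    max_dist = int((1 - identity) * min_len)
    for name in reference.nuclear_names():
        target = reference.contigs[name]
        for query in (frag, revcomp(frag)):
            res = edlib.align(query, target, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] >= 0:
                return False
    return True


def call_de_novo(
    calls_by_sample: dict[str, list[NumtCandidate]],
    pairs_by_sample: dict[str, list[DiscordantPair]],
    trios: list[tuple[str, str, str]],
    reference: ReferenceGenome,
    min_child_support: int = DE_NOVO_CHILD_SUPPORT,
    parent_recheck: int = DE_NOVO_PARENT_RECHECK,
) -> tuple[list[dict], int]:
    """De novo NUMTs per trio; returns (calls, skipped_incomplete_trios)."""
    mt_length = reference.mt_length
    out = []
    skipped = 0
    for child, father, mother in trios:
        if any(s not in pairs_by_sample for s in (child, father, mother)):
            skipped += 1
            continue
        for cand in calls_by_sample.get(child, []):
            if cand.support < min_child_support:
                continue
            father_n = locus_pair_count(cand, pairs_by_sample[father], mt_length)
            mother_n = locus_pair_count(cand, pairs_by_sample[mother], mt_length)
            if father_n >= parent_recheck or mother_n >= parent_recheck:
                continue
            if father_n > 0 or mother_n > 0:
                # below the re-check threshold but not "none of discordant
                # read detected in the parents": fails the primary rule
                continue
            if not insert_is_unique(cand, reference):
                continue
            out.append(
                {
                    "child": child,
                    "trio": (child, father, mother),
                    "candidate": cand,
                    "father_pairs": father_n,
                    "mother_pairs": mother_n,
                }
            )
    return out, skipped


def call_tumour_specific(
    calls_by_sample: dict[str, list[NumtCandidate]],
    pairs_by_sample: dict[str, list[DiscordantPair]],
    pairs_manifest: list[tuple[str, str]],
    reference: ReferenceGenome,
    strict_cohort: Optional[dict[str, list[NumtCandidate]]] = None,
    min_support: int = TUMOUR_SUPPORT,
    lost_tumour_max: int = LOST_TUMOUR_MAX,
) -> tuple[list[dict], list[dict]]:
    """(tumour_specific, lost) NUMT lists over tumour–normal pairs.

    Tumour-specific: tumour support >= 5 and zero discordant pairs in the
    matched normal; strict mode additionally requires no matching call in
    any other (non-cancer) genome of ``strict_cohort``. Lost: normal support
    >= 5 and at most one discordant pair in the tumour.
    """
    mt_length = reference.mt_length
    tumour_specific, lost = [], []
    for tumour, normal in pairs_manifest:
        if tumour not in pairs_by_sample or normal not in pairs_by_sample:
            raise ConsistencyError(f"unmatched pair ({tumour}, {normal})")
        for cand in calls_by_sample.get(tumour, []):
            if cand.support < min_support:
                continue
            if locus_pair_count(cand, pairs_by_sample[normal], mt_length) > 0:
                continue
            if strict_cohort is not None:
                seen_elsewhere = any(
                    sample not in (tumour, normal)
                    and any(
                        _candidates_match(cand, other, mt_length)
                        for other in calls
                    )
                    for sample, calls in strict_cohort.items()
                )
                if seen_elsewhere:
                    continue
            tumour_specific.append({"tumour": tumour, "normal": normal, "candidate": cand})
        for cand in calls_by_sample.get(normal, []):
            if cand.support < min_support:
                continue
            if locus_pair_count(cand, pairs_by_sample[tumour], mt_length) <= lost_tumour_max:
                lost.append({"tumour": tumour, "normal": normal, "candidate": cand})
    return tumour_specific, lost


def _candidates_match(a: NumtCandidate, b: NumtCandidate, mt_length: int) -> bool:
    if a.nuclear_contig != b.nuclear_contig:
        return False
    gap = max(b.nuclear_span[0] - a.nuclear_span[1], a.nuclear_span[0] - b.nuclear_span[1], 0)
    return gap <= LOCUS_MATCH_BP and _circular_gap(a.mt_span, b.mt_span, mt_length) <= LOCUS_MATCH_BP


def insertion_rate(
    events: int, denominator: int, confidence: float = 0.95
) -> RateEstimate:
    """rho = events/denominator with a Clopper–Pearson (exact binomial) CI.

    Lower bound is 0 at events = 0 and the upper bound 1 at
    events = denominator (Beta-quantile closed forms at the edges).
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= events <= denominator:
        raise ValueError("events must lie in [0, denominator]")
    alpha = 1 - confidence
    if events == 0:
        low = 0.0
    else:
        low = float(stats.beta.ppf(alpha / 2, events, denominator - events + 1))
    if events == denominator:
        high = 1.0
    else:
        high = float(stats.beta.ppf(1 - alpha / 2, events + 1, denominator - events))
    return RateEstimate(
        events=events,
        denominator=denominator,
        rho=events / denominator,
        ci_low=low,
        ci_high=high,
        confidence=confidence,
    )


def two_by_two_association(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """Sample odds ratio, two-sided Fisher exact p and a normal-approximation
    95% CI on the log odds ratio.

    The two-sided p sums hypergeometric table probabilities no larger than
    the observed table's (the probability-mass rule). A zero cell triggers
    the Haldane 0.5 continuity correction for the OR and CI (flagged); the
    exact p is still defined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("margins must be positive")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    continuity = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if continuity else (a, b, c, d)
    )
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(odds)
    return TwoByTwoResult(
        table=(a, b, c, d),
        odds_ratio=odds,
        fisher_p=float(p),
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
        continuity_note=continuity,
    )
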