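"""Molecular evolution of inserted mtDNA: consensus assembly, NUMT-specific
variants, coding effects, mutational spectra and insertion-age estimates.

Per (NUMT, sample), reads attributable to the insert — the mt-side mates of
discordant pairs, plus realigned clipped segments of junction-spanning reads
— are assembled by a greedy overlap-layout: the pair of contigs with the
longest exact suffix–prefix overlap (>= 25 bp) is merged repeatedly, ties
resolved toward the lexicographically smaller merged string, and the final
base at each column is the majority over the contributing reads (an exact
tie falls back to the mt reference base after alignment).

Variant calling applies a fixed filter cascade: NUMTs shorter than 1,000 bp
only; variants more than 5 bp from both mt breakpoints; reference-allele
concordance; single-nucleotide changes only; per-sample outlier exclusion
(count > cohort mean + 3 s.d.); removal of the standard mt low-complexity
tracts. NUMT-specific status then removes alleles shared by most carriers
(they predate insertion): group A drops variants in > 50% of carriers of a
common/rare NUMT or > 75% for ultra-rare; group B further drops singletons;
group C keeps only variants seen in >= 2 members of one family.

Ages come from the ancestral-allele ratio: across sites where the human and
ancestral (chimpanzee-like) mt sequences differ, the fraction r matching
the human allele yields age = (1 - r) x 6 Myr against the 6 Myr
human–chimpanzee divergence, mutations taken to accrue uniformly on the
human mt lineage.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from .cohort import CohortNumt
from .formats_io import ReferenceGenome, circular_distance
from .synthetic_data import revcomp

MIN_ASSEMBLY_OVERLAP = 25
MAX_VARIANT_NUMT_BP = 1000
BREAKPOINT_EXCLUSION_BP = 5
AGE_MIN_BP = 50
AGE_MAX_BP = 1000
T_DIVERGENCE_MYR = 6.0

#: standard mt low-complexity tracts (1-based inclusive) excluded from
#: variant calls; toggleable
LOW_COMPLEXITY_REGIONS = (
    (66, 71), (300, 316), (513, 525), (3106, 3107), (12418, 12425), (16182, 16194)
)


@dataclass
class NumtConsensus:
    cohort_numt_id: str
    sample_id: str
    consensus: str
    mt_start: int  # 1-based start of the aligned mt window
    column_mt_pos: list[int]  # per consensus column: 1-based mt pos, 0 = inserted
    n_supporting_reads: int
    fragmented: bool = False


@dataclass
class NumtVariant:
    cohort_numt_id: str
    mt_pos: int  # 1-based
    ref: str
    alt: str
    carriers: set[str] = field(default_factory=set)
    carrier_fraction: float = 0.0
    group: str = ""  # "", "A", "B" or "C" (highest attained)
    numt_specific: bool = False

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)


@dataclass
class AgeEstimate:
    cohort_numt_id: str
    n_informative: int
    n_match_human: int
    r: float
    age_myr: float
    n_carriers: int


# ---------------------------------------------------------------------------
# consensus assembly


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k with a[-k:] == b[:k] (k >= min_overlap), else 0.

    k = len(b) signals containment of b's prefix; full containment is
    handled by the caller through offsets.
    """
    seed = b[:min_overlap]
    i = a.find(seed)
    while i != -1:
        k = len(a) - i
        if k >= len(b):
            if a[i : i + len(b)] == b:
                return len(b)
        elif a[i:] == b[:k]:
            return k
        i = a.find(seed, i + 1)
    return 0


def layout_consensus(layout: list[tuple[int, str]]) -> str:
    """Column-majority base call over an (offset, read) layout.

    Uncovered columns become N; an exact vote tie is marked "?" for later
    resolution against the reference base at the aligned position.
    """
    end = max(off + len(r) for off, r in layout)
    votes: list[Counter] = [Counter() for _ in range(end)]
    for off, r in layout:
        for i, base in enumerate(r):
            votes[off + i][base] += 1
    out = []
    for col in votes:
        if not col:
            out.append("N")
            continue
        top = max(col.values())
        winners = sorted(b for b, c in col.items() if c == top)
        out.append(winners[0] if len(winners) == 1 else "?")
    return "".join(out)


def assemble_numt_consensus(
    reads: Sequence[str],
    reference_fragment: Optional[str] = None,
    min_overlap: int = MIN_ASSEMBLY_OVERLAP,
) -> tuple[str, bool, int]:
    """Greedy overlap-layout-consensus of mt-oriented read sequences.

    Returns (consensus, fragmented, n_reads_in_contig). Ties at the merge
    step go to the lexicographically smaller merged string; column-majority
    voting resolves disagreements, an exact tie keeping the base of
    ``reference_fragment`` aligned at that column when provided.
    """
    if len(reads) < 2:
        raise ValueError("need at least 2 reads to assemble")
    # layout: contig id -> list of (offset, read); merge strings are plain
    # suffix-prefix concatenations, the column vote is applied once at the end
    contigs: dict[int, list[tuple[int, str]]] = {
        i: [(0, r)] for i, r in enumerate(sorted(set(reads)))
    }
    strings: dict[int, str] = {i: c[0][1] for i, c in contigs.items()}
    overlaps: dict[tuple[int, int], int] = {}
    for i in contigs:
        for j in contigs:
            if i != j:
                overlaps[(i, j)] = _best_overlap(strings[i], strings[j], min_overlap)
    next_id = len(contigs)
    while len(contigs) > 1:
        best = None  # (overlap, merged_string, i, j)
        for (i, j), k in overlaps.items():
            if k == 0:
                continue
            merged = strings[i] + strings[j][k:]
            if best is None or k > best[0] or (k == best[0] and merged < best[1]):
                best = (k, merged, i, j)
        if best is None:
            break
        k, merged, i, j = best
        offset = len(strings[i]) - k
        merged_layout = contigs[i] + [(off + offset, r) for off, r in contigs[j]]
        for stale in (i, j):
            del contigs[stale], strings[stale]
        overlaps = {
            key: v for key, v in overlaps.items() if i not in key and j not in key
        }
        contigs[next_id] = merged_layout
        strings[next_id] = merged
        for other in contigs:
            if other != next_id:
                overlaps[(next_id, other)] = _best_overlap(
                    merged, strings[other], min_overlap
                )
                overlaps[(other, next_id)] = _best_overlap(
                    strings[other], merged, min_overlap
                )
        next_id += 1

    fragmented = len(contigs) > 1
    best_id = max(contigs, key=lambda m: (len(strings[m]), -m))
    layout = contigs[best_id]
    consensus = layout_consensus(layout)
    if "?" in consensus:
        resolved = []
        ref_by_col = _tie_reference_bases(consensus, reference_fragment)
        for idx, base in enumerate(consensus):
            resolved.append(ref_by_col.get(idx, "N") if base == "?" else base)
        consensus = "".join(resolved)
    return consensus, fragmented, len(layout)


def _tie_reference_bases(consensus: str, fragment: Optional[str]) -> dict[int, str]:
    if fragment is None:
        return {}
    res = edlib.align(consensus.replace("?", "N"), fragment, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return {}
    t = res["locations"][0][0]
    q = 0
    mapping: dict[int, str] = {}
    for count, op in _parse_cigar(res["cigar"]):
        if op == "=" or op == "M" or op == "X":
            for _ in range(count):
                mapping[q] = fragment[t]
                q += 1
                t += 1
        elif op == "I":
            q += count
        elif op == "D":
            t += count
    return mapping


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def align_consensus_to_mt(
    consensus: str, reference: ReferenceGenome
) -> Optional[tuple[int, list[int], str]]:
    """Locate the consensus on the mt genome (both strands).

    Returns (1-based mt start, per-column mt position list with 0 for
    inserted columns, strand) or None when no acceptable placement exists
    (alignment must cover >= 80% of the consensus at >= 85% identity).
    """
    mt = reference.mt_sequence
    best = None
    for strand, query in (("+", consensus), ("-", revcomp(consensus))):
        res = edlib.align(query, mt, mode="HW", task="path")
        d = res["editDistance"]
        if d < 0:
            continue
        if best is None or d < best[0]:
            best = (d, strand, query, res)
    if best is None:
        return None
    d, strand, query, res = best
    if d > 0.15 * len(query):
        return None
    t = res["locations"][0][0]
    column_pos = [0] * len(query)
    q = 0
    tt = t
    for count, op in _parse_cigar(res["cigar"]):
        if op in "=MX":
            for _ in range(count):
                column_pos[q] = tt + 1
                q += 1
                tt += 1
        elif op == "I":
            q += count
        elif op == "D":
            tt += count
    if strand == "-":
        column_pos = column_pos[::-1]
    covered = sum(1 for p in column_pos if p > 0)
    if covered < 0.8 * len(consensus):
        return None
    return t + 1, column_pos, strand


def build_consensus(
    cohort_numt_id: str,
    sample_id: str,
    reads: Sequence[str],
    reference: ReferenceGenome,
) -> Optional[NumtConsensus]:
    """Assemble and align one per-sample NUMT consensus (reads mt-oriented)."""
    if len(reads) < 2:
        return None
    consensus, fragmented, n_reads = assemble_numt_consensus(
        reads, reference_fragment=reference.mt_sequence
    )
    placed = align_consensus_to_mt(consensus, reference)
    if placed is None:
        return None
    mt_start, column_pos, strand = placed
    if strand == "-":
        consensus = revcomp(consensus)
    return NumtConsensus(
        cohort_numt_id=cohort_numt_id,
        sample_id=sample_id,
        consensus=consensus,
        mt_start=mt_start,
        column_mt_pos=column_pos,
        n_supporting_reads=n_reads,
        fragmented=fragmented,
    )


# ---------------------------------------------------------------------------
# variant calling


def call_numt_variants(
    consensuses: Iterable[NumtConsensus],
    numts: dict[str, CohortNumt],
    mt_breakpoints: dict[str, tuple[int, int]],
    reference: ReferenceGenome,
    exclude_low_complexity: bool = True,
    outlier_sd: float = 3.0,
) -> list[NumtVariant]:
    """Per-NUMT aggregated single-nucleotide variants after the filter
    cascade (see module docstring for the ordered steps)."""
    mt = reference.mt_sequence
    L = reference.mt_length
    per_sample: dict[tuple[str, str], list[tuple[str, int, str, str]]] = defaultdict(list)
    assayed: dict[str, set[str]] = defaultdict(set)
    for cons in consensuses:
        numt = numts.get(cons.cohort_numt_id)
        if numt is None:
            continue
        # (1) only NUMTs shorter than 1,000 bp
        if numt.size_bp >= MAX_VARIANT_NUMT_BP:
            continue
        assayed[cons.cohort_numt_id].add(cons.sample_id)
        bps = mt_breakpoints.get(cons.cohort_numt_id)
        for col, mt_pos in enumerate(cons.column_mt_pos):
            if mt_pos == 0:
                continue  # insertion relative to mt: not a SNV
            alt = cons.consensus[col]
            ref = mt[mt_pos - 1]
            if alt == ref or alt not in "ACGT":
                continue
            # (2) exclude variants within 5 bp of either mt breakpoint
            if bps is not None and any(
                circular_distance(mt_pos, bp, L) <= BREAKPOINT_EXCLUSION_BP
                for bp in bps
            ):
                continue
            # (3) reference-allele concordance holds by construction here:
            # ref is read from the mt reference at the aligned position
            # (6) low-complexity tracts
            if exclude_low_complexity and any(
                lo <= mt_pos <= hi for lo, hi in LOW_COMPLEXITY_REGIONS
            ):
                continue
            per_sample[(cons.sample_id, cons.cohort_numt_id)].append(
                (cons.cohort_numt_id, mt_pos, ref, alt)
            )

    # (5) per-sample outlier exclusion on total variant count, over every
    # assayed individual (zero-variant samples included in the background)
    counts_by_sample: Counter = Counter()
    for (sample, _), items in per_sample.items():
        counts_by_sample[sample] += len(items)
    all_samples = {s for members in assayed.values() for s in members}
    values = np.array(
        [counts_by_sample.get(s, 0) for s in sorted(all_samples)], dtype=float
    )
    if len(values) > 1:
        cutoff = values.mean() + outlier_sd * values.std(ddof=1)
    else:
        cutoff = float("inf")
    outliers = {s for s in all_samples if counts_by_sample.get(s, 0) > cutoff}

    aggregated: dict[tuple[str, int, str, str], set[str]] = defaultdict(set)
    for (sample, numt_id), items in per_sample.items():
        if sample in outliers:
            continue
        for numt_id_, mt_pos, ref, alt in items:
            aggregated[(numt_id_, mt_pos, ref, alt)].add(sample)

    variants = []
    for (numt_id, mt_pos, ref, alt), carriers in sorted(aggregated.items()):
        n_assayed = max(len(assayed[numt_id]), 1)
        variants.append(
            NumtVariant(
                cohort_numt_id=numt_id,
                mt_pos=mt_pos,
                ref=ref,
                alt=alt,
                carriers=carriers,
                carrier_fraction=len(carriers) / n_assayed,
            )
        )
    return variants


def classify_variant_groups(
    variants: list[NumtVariant],
    numts: dict[str, CohortNumt],
    family_of: Optional[dict[str, str]] = None,
) -> dict[str, list[NumtVariant]]:
    """NUMT-specific variant groups A ⊇ B ⊇ C (annotates in place).

    A: removes alleles carried by > 50% of carriers of a common/rare NUMT
    (> 75% for ultra-rare) — those likely predate insertion. B: removes
    variants seen in a single individual. C: requires >= 2 individuals from
    one family.
    """
    groups: dict[str, list[NumtVariant]] = {"A": [], "B": [], "C": []}
    for v in variants:
        numt = numts.get(v.cohort_numt_id)
        if numt is None:
            continue
        threshold = 0.75 if numt.freq_class == "ultra_rare" else 0.50
        if v.carrier_fraction > threshold:
            continue
        v.numt_specific = True
        v.group = "A"
        groups["A"].append(v)
        if v.carrier_count < 2:
            continue
        v.group = "B"
        groups["B"].append(v)
        if family_of is None:
            continue
        fams = Counter(family_of.get(s) for s in v.carriers if family_of.get(s))
        if any(c >= 2 for c in fams.values()):
            v.group = "C"
            groups["C"].append(v)
    return groups


# ---------------------------------------------------------------------------
# coding effects and spectra

PYRIMIDINES = ("C", "T")
SPECTRUM_CLASSES = [
    f"{l}[{ref}>{alt}]{r}"
    for ref in PYRIMIDINES
    for alt in "ACGT"
    if alt != ref
    for l in "ACGT"
    for r in "ACGT"
]


def coding_effect_and_spectrum(
    variants: Sequence[NumtVariant],
    reference: ReferenceGenome,
    regions=None,
    signature_matrix=None,
) -> dict:
    """Synonymous/non-synonymous annotation and the 96-class spectrum.

    Protein-coding regions use the vertebrate mitochondrial genetic code,
    strand-aware; variants outside coding regions get effect NA but still
    count in the pyrimidine-centred trinucleotide spectrum. Optionally
    returns cosine similarity of the 96-vector against each column of a
    user-supplied signature matrix (96 x k, rows in SPECTRUM_CLASSES order).
    """
    from .enrichment import load_mt_regions

    if regions is None:
        regions = load_mt_regions()
    mt = reference.mt_sequence
    L = reference.mt_length
    genes = regions[regions["kind"] == "protein"]

    effects = []
    spectrum: Counter = Counter({c: 0 for c in SPECTRUM_CLASSES})
    for v in variants:
        effect = "NA"
        for _, gene in genes.iterrows():
            s, e, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
            if not (s <= v.mt_pos <= e):
                continue
            if strand == "+":
                off = v.mt_pos - s
                codon_start = s + (off // 3) * 3
                codon = mt[codon_start - 1 : codon_start + 2]
                idx = off % 3
                alt_codon = codon[:idx] + v.alt + codon[idx + 1 :]
            else:
                off = e - v.mt_pos
                codon_end = e - (off // 3) * 3
                codon = revcomp(mt[codon_end - 3 : codon_end])
                idx = off % 3
                alt_codon = codon[:idx] + revcomp(v.alt) + codon[idx + 1 :]
            if len(codon) != 3:
                break
            aa_ref = str(Seq(codon).translate(table=2))
            aa_alt = str(Seq(alt_codon).translate(table=2))
            effect = "synonymous" if aa_ref == aa_alt else "non-synonymous"
            break
        effects.append({"mt_pos": v.mt_pos, "ref": v.ref, "alt": v.alt,
                        "gene_effect": effect})
        i = v.mt_pos - 1
        left, ref, right, alt = mt[(i - 1) % L], v.ref, mt[(i + 1) % L], v.alt
        if ref not in PYRIMIDINES:
            left, ref, right, alt = (
                revcomp(right), revcomp(ref), revcomp(left), revcomp(alt)
            )
        spectrum[f"{left}[{ref}>{alt}]{right}"] += 1

    out = {
        "effects": effects,
        "spectrum": {c: spectrum[c] for c in SPECTRUM_CLASSES},
        "n_synonymous": sum(1 for e in effects if e["gene_effect"] == "synonymous"),
        "n_non_synonymous": sum(
            1 for e in effects if e["gene_effect"] == "non-synonymous"
        ),
    }
    if signature_matrix is not None:
        vec = np.array([spectrum[c] for c in SPECTRUM_CLASSES], dtype=float)
        sims = {}
        for col in signature_matrix.columns:
            sig = signature_matrix[col].to_numpy(dtype=float)
            denom = np.linalg.norm(vec) * np.linalg.norm(sig)
            sims[col] = float(vec @ sig / denom) if denom > 0 else float("nan")
        out["signature_cosine"] = sims
    return out


# ---------------------------------------------------------------------------
# age estimation


def estimate_numt_age(
    consensuses: Iterable[NumtConsensus],
    numts: dict[str, CohortNumt],
    ancestral_mt: str,
    reference: ReferenceGenome,
    concatenated_ids: Optional[set[str]] = None,
    t_divergence_myr: float = T_DIVERGENCE_MYR,
) -> list[AgeEstimate]:
    """Ancestral-allele-ratio ages for eligible NUMTs.

    Filters: fragment length in [50, 1,000] bp; at least one informative
    (human != ancestral) site; site classifications must agree in > 50% of
    carriers and >= 2 carriers; concatenated NUMTs excluded. r is the
    fraction of informative sites carrying the human allele;
    age = (1 - r) x t_divergence.
    """
    concatenated_ids = concatenated_ids or set()
    mt = reference.mt_sequence
    by_numt: dict[str, list[NumtConsensus]] = defaultdict(list)
    for cons in consensuses:
        by_numt[cons.cohort_numt_id].append(cons)

    estimates = []
    for numt_id, group in sorted(by_numt.items()):
        numt = numts.get(numt_id)
        if numt is None or numt_id in concatenated_ids:
            continue
        if not AGE_MIN_BP <= numt.size_bp <= AGE_MAX_BP:
            continue
        carriers = {c.sample_id for c in group}
        if len(carriers) < 2:
            continue
        # per informative site, per carrier: does the consensus match the
        # human or the ancestral allele?
        site_votes: dict[int, list[str]] = defaultdict(list)
        for cons in group:
            for col, mt_pos in enumerate(cons.column_mt_pos):
                if mt_pos == 0:
                    continue
                human, anc = mt[mt_pos - 1], ancestral_mt[mt_pos - 1]
                if human == anc:
                    continue
                base = cons.consensus[col]
                if base == human:
                    site_votes[mt_pos].append("human")
                elif base == anc:
                    site_votes[mt_pos].append("ancestral")
                else:
                    site_votes[mt_pos].append("other")
        n_informative = 0
        n_match_human = 0
        for mt_pos, votes in site_votes.items():
            counts = Counter(votes)
            call, top = counts.most_common(1)[0]
            if len(votes) < 2 or top <= len(votes) / 2:
                continue  # needs majority agreement in >= 2 carriers
            if call == "other":
                continue
            n_informative += 1
            if call == "human":
                n_match_human += 1
        if n_informative == 0:
            continue
        r = n_match_human / n_informative
        estimates.append(
            AgeEstimate(
                cohort_numt_id=numt_id,
                n_informative=n_informative,
                n_match_human=n_match_human,
                r=r,
                age_myr=(1 - r) * t_divergence_myr,
                n_carriers=len(carriers),
            )
        )
    return estimates
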