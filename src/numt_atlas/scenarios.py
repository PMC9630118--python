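"""Benchmark scenarios measuring pipeline performance on simulated cohorts.

Each scenario builds a synthetic cohort under the study conditions the
package emulates (30x 150 bp paired-end sequencing, ~400 bp inserts),
runs the relevant pipeline stages from scratch and returns summary metrics.
Problem sizes (contig lengths, cohort sizes) are desk-scale so a scenario
runs in seconds to a few minutes on one core.
"""

from __future__ import annotations

import numpy as np

from . import breakpoints as bp
from . import concatenation as concat
from . import detection as det
from . import enrichment as enr
from . import evolution as evo
from . import trio_tumour as tt
from .cohort import unify_cohort_numts
from .formats_io import IntervalTrack
from .pipeline import consensuses_for_cohort, process_sample
from .synthetic_data import (
    CohortDesign,
    SimulatedNumt,
    as_aligned_reads,
    build_toy_references,
    make_ancestral_mt,
    plant_numts,
    simulate_sample_reads,
)


def _matches_truth(cand, truth_pos, truth_mt, mt_length, distance=1000):
    if abs(cand.nuclear_span[0] - truth_pos) > distance and abs(
        cand.nuclear_span[1] - truth_pos
    ) > distance:
        return False
    return det._circular_gap(cand.mt_span, truth_mt, mt_length) <= distance


def detection_benchmark(seed: int = 0) -> dict:
    """Recall/precision of candidate calling and blunt-junction exactness.

    20 samples at 30x; 10 planted blunt NUMTs of 100–2,000 bp, each carried
    by a random subset of samples. Recall and precision are evaluated per
    (NUMT, carrier) instance at the sensitive (2-pair) support threshold;
    junction refinement is checked for one carrier per NUMT.
    """
    rng = np.random.default_rng(seed)
    sizes = [100, 150, 250, 400, 600, 800, 1000, 1300, 1600, 2000]
    reference = build_toy_references({"chr1": 60000}, seed=seed)
    numts = []
    for i, size in enumerate(sizes):
        mt_start = 400 + i * 1450
        numts.append(
            SimulatedNumt(
                f"N{i}", "chr1", 3000 + i * 5500,
                [(mt_start, mt_start + size - 1, "+")],
            )
        )
    n_samples = 20
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    carriers = {
        n.numt_id: sorted(
            rng.choice(sample_ids, size=int(rng.integers(5, 16)), replace=False)
        )
        for n in numts
    }
    design = CohortDesign(
        n_samples=n_samples, carriers=carriers, mean_depth=30.0, seed=seed
    )
    donors, truth = plant_numts(reference, design, numts)
    truth_by_id = {t["numt_id"]: t for t in truth["numts"]}

    n_instances = found = n_calls = matched_calls = 0
    exact_sides = total_sides = 0
    refined_numts: set[str] = set()
    for idx, sample in enumerate(design.sample_ids()):
        rng_s = np.random.default_rng((design.seed * 9_973 + idx * 7 + 1) % (2**31))
        records = simulate_sample_reads(donors[sample], design, sample, rng_s)
        reads = as_aligned_reads(records, sample)
        res = process_sample(reads, reference, min_support=2)
        carried = [
            truth_by_id[nid] for nid, cs in carriers.items() if sample in cs
        ]
        for t in carried:
            n_instances += 1
            seg = t["segments"][0]
            mt_span = (seg[0] - 1, seg[1])
            if any(
                _matches_truth(c, t["nuclear_pos"], mt_span, reference.mt_length)
                for c in res["candidates"]
            ):
                found += 1
        for cand in res["candidates"]:
            n_calls += 1
            hit = None
            for t in carried:
                seg = t["segments"][0]
                if _matches_truth(
                    cand, t["nuclear_pos"], (seg[0] - 1, seg[1]), reference.mt_length
                ):
                    hit = t
                    break
            if hit is not None:
                matched_calls += 1
                if hit["numt_id"] not in refined_numts and cand.support >= 5:
                    refined_numts.add(hit["numt_id"])
                    refinement = bp.refine_candidate(
                        reads, cand, reference, hit["numt_id"]
                    )
                    sides = {b.side: b.position for b in refinement["breakpoints"]}
                    seg = hit["segments"][0]
                    expect = {
                        "nuclear": hit["nuclear_pos"],
                        "mt_left": seg[0],
                        "mt_right": seg[1],
                    }
                    for side, pos in expect.items():
                        if side in sides:
                            total_sides += 1
                            exact_sides += int(sides[side] == pos)
    return {
        "recall": found / n_instances,
        "precision": matched_calls / n_calls if n_calls else float("nan"),
        "n_instances": n_instances,
        "n_calls": n_calls,
        "breakpoint_exact_fraction": exact_sides / total_sides if total_sides else float("nan"),
        "n_breakpoint_sides": total_sides,
    }


def trio_benchmark(seed: int = 0, n_trios: int = 50) -> dict:
    """De novo calling over simulated trios.

    Five planted child-only events (true de novo) and five inherited events
    (child + father carriers) across distinct trios; every other trio is
    event-free. Returns the recovered/false de novo counts and the
    cohort-level insertion-rate estimate.
    """
    reference = build_toy_references({"chr1": 20000}, seed=seed + 101)
    children = [f"S{i:04d}" for i in range(n_trios)]
    fathers = [f"S{i:04d}" for i in range(n_trios, 2 * n_trios)]
    mothers = [f"S{i:04d}" for i in range(2 * n_trios, 3 * n_trios)]
    trios = list(zip(children, fathers, mothers))
    rng = np.random.default_rng(seed)
    numts, carriers = [], {}
    for k in range(5):
        size = int(rng.integers(200, 500))
        mt_start = 300 + k * 1500
        numts.append(
            SimulatedNumt(
                f"denovo{k}", "chr1", 2000 + k * 1700,
                [(mt_start, mt_start + size - 1, "+")],
            )
        )
        carriers[f"denovo{k}"] = [children[k]]
    for k in range(5):
        size = int(rng.integers(200, 500))
        mt_start = 8300 + k * 1500
        numts.append(
            SimulatedNumt(
                f"inherited{k}", "chr1", 2000 + (5 + k) * 1700,
                [(mt_start, mt_start + size - 1, "+")],
            )
        )
        carriers[f"inherited{k}"] = [children[5 + k], fathers[5 + k]]
    design = CohortDesign(
        n_samples=3 * n_trios, carriers=carriers, trios=trios,
        mean_depth=30.0, seed=seed,
    )
    donors, truth = plant_numts(reference, design, numts)

    calls_by_sample, pairs_by_sample = {}, {}
    for idx, sample in enumerate(design.sample_ids()):
        rng_s = np.random.default_rng((design.seed * 9_973 + idx * 7 + 1) % (2**31))
        records = simulate_sample_reads(donors[sample], design, sample, rng_s)
        reads = as_aligned_reads(records, sample)
        res = process_sample(reads, reference, min_support=2)
        calls_by_sample[sample] = res["candidates"]
        pairs_by_sample[sample] = res["pairs"]

    calls, _ = tt.call_de_novo(
        calls_by_sample, pairs_by_sample, trios, reference
    )
    truth_by_id = {t["numt_id"]: t for t in truth["numts"]}
    recovered = set()
    false_calls = 0
    for call in calls:
        hit = None
        for k in range(5):
            t = truth_by_id[f"denovo{k}"]
            seg = t["segments"][0]
            if call["child"] == children[k] and _matches_truth(
                call["candidate"], t["nuclear_pos"], (seg[0] - 1, seg[1]),
                reference.mt_length,
            ):
                hit = k
                break
        if hit is None:
            false_calls += 1
        else:
            recovered.add(hit)
    rate = tt.insertion_rate(len({c["child"] for c in calls}), n_trios)
    return {
        "n_true_events": 5,
        "n_recovered": len(recovered),
        "n_false_de_novo": false_calls,
        "rate": rate.rho,
        "rate_ci": (rate.ci_low, rate.ci_high),
    }


def concatenation_benchmark(seed: int = 0) -> dict:
    """Recovery of a two-segment NUMT's internal mtDNA–mtDNA junction.

    One concatenated NUMT (internal junction 12867/14977) in two samples
    plus a sub-50 bp internal-junction decoy; reports junction offset from
    truth and whether the decoy survived the filter cascade.
    """
    reference = build_toy_references({"chr1": 50000}, seed=seed + 7)
    numts = [
        SimulatedNumt(
            "concat", "chr1", 8000, [(12367, 12867, "+"), (14977, 15477, "+")]
        ),
        SimulatedNumt(
            "decoy", "chr1", 30000, [(5001, 5100, "+"), (5131, 5400, "+")]
        ),
    ]
    design = CohortDesign(
        n_samples=3,
        carriers={"concat": ["S0000", "S0001"], "decoy": ["S0000"]},
        mean_depth=30.0,
        seed=seed,
    )
    donors, _ = plant_numts(reference, design, numts)
    reads_by_sample = {}
    for idx, sample in enumerate(design.sample_ids()):
        rng_s = np.random.default_rng((design.seed * 9_973 + idx * 7 + 1) % (2**31))
        records = simulate_sample_reads(donors[sample], design, sample, rng_s)
        reads_by_sample[sample] = as_aligned_reads(records, sample)
    junctions = concat.detect_mt_mt_junctions(reads_by_sample, reference)
    offsets = [
        max(abs(j.pos1 - 12867), abs(j.pos2 - 14977))
        for j in junctions
        if abs(j.pos1 - 12867) <= 5 and abs(j.pos2 - 14977) <= 5
    ]
    decoy_survived = any(abs(j.pos1 - 5100) <= 5 for j in junctions)
    return {
        "junction_found": bool(offsets),
        "junction_offset": min(offsets) if offsets else float("nan"),
        "decoy_removed": not decoy_survived,
        "n_junctions": len(junctions),
    }


def permutation_calibration(
    seed: int = 0, n_tests: int = 400, n_permutations: int = 1000
) -> dict:
    """Type-I error of the permutation test under the uniform null.

    Each test draws 30 NUMT positions uniformly and a random 20-interval
    track on a 100 kb genome; reports the fraction of tests with p < 0.05.
    """
    reference = build_toy_references({"chr1": 100000}, seed=seed + 13)
    rng = np.random.default_rng(seed)
    n_sig = 0
    for t in range(n_tests):
        positions = [("chr1", int(p)) for p in rng.integers(1, 100001, size=30)]
        starts = rng.choice(100000 - 500, size=20, replace=False)
        track = IntervalTrack(
            f"t{t}", [("chr1", int(s), int(s) + 500) for s in starts]
        )
        res = enr.permutation_enrichment(
            positions, track, reference,
            n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31)),
        )
        if res.empirical_p < 0.05:
            n_sig += 1
    return {"fraction_significant": n_sig / n_tests, "n_tests": n_tests}


def age_benchmark(seed: int = 0, n_numts: int = 50, age_fraction: float = 0.25) -> dict:
    """Recovery of the planted insertion age from ancestral-allele ratios.

    ``n_numts`` NUMTs of 350–500 bp, each in four carriers, planted with the
    same age fraction; the expected age is ``age_fraction * 6`` Myr. Returns
    the mean estimated age over NUMTs with >= 20 informative sites.
    """
    rng = np.random.default_rng(seed)
    reference = build_toy_references({"chr1": 350000}, seed=seed + 3)
    ancestral = make_ancestral_mt(reference, divergence=0.08, seed=seed + 4)
    sample_ids = [f"S{i:04d}" for i in range(4)]
    numts, carriers = [], {}
    for i in range(n_numts):
        size = int(rng.integers(350, 501))
        mt_start = int(rng.integers(1, 16569 - size))
        numts.append(
            SimulatedNumt(
                f"A{i}", "chr1", 4000 + i * 6800,
                [(mt_start, mt_start + size - 1, "+")],
                age_fraction=age_fraction,
            )
        )
        carriers[f"A{i}"] = list(sample_ids)
    design = CohortDesign(
        n_samples=4, carriers=carriers, mean_depth=30.0,
        insert_mean=500.0, insert_sd=80.0, seed=seed,
    )
    donors, truth = plant_numts(
        reference, design, numts, ancestral_mt=ancestral
    )
    reads_by_sample, per_sample = {}, {}
    for idx, sample in enumerate(design.sample_ids()):
        rng_s = np.random.default_rng((design.seed * 9_973 + idx * 7 + 1) % (2**31))
        records = simulate_sample_reads(donors[sample], design, sample, rng_s)
        reads = as_aligned_reads(records, sample)
        reads_by_sample[sample] = reads
        per_sample[sample] = process_sample(reads, reference, min_support=5)
    candidates = [c for r in per_sample.values() for c in r["candidates"]]
    cohort_numts = unify_cohort_numts(candidates, reference.mt_length)
    numt_map = {n.cohort_numt_id: n for n in cohort_numts}
    consensuses = consensuses_for_cohort(
        reads_by_sample, per_sample, cohort_numts, reference
    )
    ages = evo.estimate_numt_age(consensuses, numt_map, ancestral, reference)
    informative = [a for a in ages if a.n_informative >= 20]
    mean_age = (
        float(np.mean([a.age_myr for a in informative]))
        if informative
        else float("nan")
    )
    return {
        "expected_age_myr": age_fraction * evo.T_DIVERGENCE_MYR,
        "mean_age_myr": mean_age,
        "n_numts_estimated": len(informative),
        "n_numts_planted": n_numts,
    }


def variant_specificity_benchmark(seed: int = 0) -> dict:
    """Zero planted variants, error-free reads: the caller must stay silent."""
    reference = build_toy_references({"chr1": 30000}, seed=seed + 31)
    numts = [
        SimulatedNumt("V0", "chr1", 6000, [(2001, 2300, "+")]),
        SimulatedNumt("V1", "chr1", 20000, [(7001, 7400, "+")]),
    ]
    samples = [f"S{i:04d}" for i in range(3)]
    design = CohortDesign(
        n_samples=3,
        carriers={"V0": samples, "V1": samples},
        mean_depth=30.0,
        seed=seed,
    )
    donors, _ = plant_numts(reference, design, numts)
    reads_by_sample, per_sample = {}, {}
    for idx, sample in enumerate(design.sample_ids()):
        rng_s = np.random.default_rng((design.seed * 9_973 + idx * 7 + 1) % (2**31))
        records = simulate_sample_reads(donors[sample], design, sample, rng_s)
        reads = as_aligned_reads(records, sample)
        reads_by_sample[sample] = reads
        per_sample[sample] = process_sample(reads, reference, min_support=5)
    candidates = [c for r in per_sample.values() for c in r["candidates"]]
    cohort_numts = unify_cohort_numts(candidates, reference.mt_length)
    numt_map = {n.cohort_numt_id: n for n in cohort_numts}
    consensuses = consensuses_for_cohort(
        reads_by_sample, per_sample, cohort_numts, reference
    )
    variants = evo.call_numt_variants(consensuses, numt_map, {}, reference)
    return {
        "n_variants": len(variants),
        "n_consensuses": len(consensuses),
        "n_cohort_numts": len(cohort_numts),
    }
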