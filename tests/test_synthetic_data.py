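import numpy as np
import pytest

from numt_atlas import formats_io as fio
from numt_atlas.synthetic_data import (
    CohortDesign,
    ConfigurationError,
    DesignError,
    SimulatedNumt,
    as_aligned_reads,
    build_toy_references,
    make_ancestral_mt,
    plant_numts,
    simulate_cohort,
    simulate_sample_reads,
    write_sam,
)


class TestReferences:
    def test_deterministic_per_seed(self):
        a = build_toy_references({"chr1": 2000}, seed=1)
        b = build_toy_references({"chr1": 2000}, seed=1)
        assert a.contigs == b.contigs

    def test_packaged_mt_length(self, toy_reference):
        assert toy_reference.mt_length == 16569

    def test_zero_nuclear_contigs_rejected(self):
        with pytest.raises(ConfigurationError):
            build_toy_references({}, seed=1)

    def test_short_mt_rejected_in_packaged_mode(self):
        with pytest.raises(ConfigurationError):
            build_toy_references({"chr1": 2000}, mt_length=500, seed=1)

    def test_ancestral_divergence(self, toy_reference):
        anc = make_ancestral_mt(toy_reference, divergence=0.08, seed=3)
        diff = sum(1 for a, b in zip(anc, toy_reference.mt_sequence) if a != b)
        assert diff == round(0.08 * 16569)


class TestPlanting:
    def _design(self, **kw):
        base = dict(n_samples=1, carriers={"N": ["S0000"]}, seed=1)
        base.update(kw)
        return CohortDesign(**base)

    def test_blunt_insert_length_conservation(self, toy_reference):
        numt = SimulatedNumt("N", "chr1", 10000, [(5001, 5300, "+")])
        donors, _ = plant_numts(toy_reference, self._design(), [numt])
        donor = donors["S0000"]["chr1"]
        assert len(donor.sequence) == 50000 + 300

    def test_microhomology_splice_arithmetic(self, toy_reference):
        """Shared bases are counted once: donor gains insert length - mh."""
        numt = SimulatedNumt(
            "N", "chr1", 10000, [(5001, 5300, "+")], microhomology_len=3
        )
        donors, truth = plant_numts(toy_reference, self._design(), [numt])
        donor = donors["S0000"]["chr1"]
        assert len(donor.sequence) == 50000 + 300 - 3
        pos = truth["numts"][0]["nuclear_pos"]
        nuc = toy_reference.contigs["chr1"]
        mt = toy_reference.mt_sequence
        # the realized splice point carries the homology tract
        assert nuc[pos - 3 : pos] == mt[5000:5003]
        # donor continues with the insert minus the shared prefix
        assert donor.sequence[pos : pos + 10] == mt[5003:5013]

    def test_insertion_bases_added(self, toy_reference):
        numt = SimulatedNumt(
            "N", "chr1", 10000, [(5001, 5300, "+")], inserted_bases="TTA"
        )
        donors, _ = plant_numts(toy_reference, self._design(), [numt])
        assert len(donors["S0000"]["chr1"].sequence) == 50000 + 300 + 3

    def test_concatenated_segments_single_insert(self, toy_reference):
        numt = SimulatedNumt(
            "N", "chr1", 10000, [(12367, 12867, "+"), (14977, 15477, "+")]
        )
        donors, _ = plant_numts(toy_reference, self._design(), [numt])
        donor = donors["S0000"]["chr1"]
        assert len(donor.sequence) == 50000 + 501 + 501
        mt = toy_reference.mt_sequence
        # the internal junction abuts segment 1 end and segment 2 start
        junction = donor.sequence[10000 + 501 - 5 : 10000 + 501 + 5]
        assert junction == mt[12862:12867] + mt[14976:14981]

    def test_overlapping_numts_rejected(self, toy_reference):
        numts = [
            SimulatedNumt("A", "chr1", 10000, [(5001, 5300, "+")]),
            SimulatedNumt("B", "chr1", 10000, [(8001, 8300, "+")]),
        ]
        design = CohortDesign(
            n_samples=1, carriers={"A": ["S0000"], "B": ["S0000"]}, seed=1
        )
        with pytest.raises(DesignError):
            plant_numts(toy_reference, design, numts)

    def test_microhomology_and_insertion_exclusive(self):
        with pytest.raises(DesignError):
            SimulatedNumt(
                "N", "chr1", 1000, [(1, 300, "+")],
                microhomology_len=2, inserted_bases="AA",
            )


class TestReadSimulation:
    def test_zero_depth_empty_output(self, toy_reference):
        numt = SimulatedNumt("N", "chr1", 10000, [(5001, 5300, "+")])
        design = CohortDesign(
            n_samples=1, carriers={"N": ["S0000"]}, mean_depth=0.0, seed=1
        )
        res = simulate_cohort(toy_reference, design, [numt])
        assert res["reads"]["S0000"] == []

    def test_same_seed_byte_identical_sam(self, tmp_path, junction_cohort):
        ref = junction_cohort["reference"]
        design = junction_cohort["design"]
        res2 = simulate_cohort(ref, design, junction_cohort["numts"])
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(junction_cohort["records"]["S0000"], ref, str(p1))
        write_sam(res2["reads"]["S0000"], ref, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_as_aligned_reads_matches_sam_round_trip(self, tmp_path, junction_cohort):
        ref = junction_cohort["reference"]
        path = tmp_path / "s.sam"
        write_sam(junction_cohort["records"]["S0000"], ref, str(path))
        parsed = list(fio.read_alignments(str(path), ref, "S0000"))
        direct = junction_cohort["reads"]["S0000"]
        assert len(parsed) == len(direct)
        for a, b in zip(parsed, direct):
            assert (a.read_id, a.contig, a.start, a.cigar, a.strand, a.mapq,
                    a.sequence) == (
                b.read_id, b.contig, b.start, b.cigar, b.strand, b.mapq, b.sequence
            )

    def test_discordant_pair_count_matches_closed_form(self, toy_reference):
        """Expected nuclear-mt pairs: depth * (insert_mean - read_len) / read_len."""
        numt = SimulatedNumt("N", "chr1", 20000, [(5001, 5500, "+")])
        counts = []
        for seed in range(5):
            design = CohortDesign(
                n_samples=1, carriers={"N": ["S0000"]}, seed=seed
            )
            res = simulate_cohort(toy_reference, design, [numt])
            by_id = {}
            for rec in res["reads"]["S0000"]:
                by_id.setdefault(rec.read_id, set()).add(rec.contig)
            counts.append(
                sum(1 for c in by_id.values() if c == {"chr1", "chrM"})
            )
        d = CohortDesign(n_samples=1, seed=0)
        expected = d.mean_depth * (d.insert_mean - d.read_length) / d.read_length
        sem = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * sem

    def test_junction_evidence_at_depth(self, junction_cohort):
        """Every planted junction yields soft-clipped reads and discordant
        pairs at 30x."""
        reads = junction_cohort["reads"]["S0000"]
        truth = {t["numt_id"]: t for t in junction_cohort["truth"]["numts"]}
        for t in truth.values():
            pos = t["nuclear_pos"]
            clipped = [
                r for r in reads
                if r.contig == "chr1" and max(r.clips()) > 0
                and r.start - 200 <= pos <= r.end + 200
            ]
            assert len(clipped) >= 1
        by_id = {}
        for r in reads:
            by_id.setdefault(r.read_id, set()).add(r.contig)
        assert sum(1 for c in by_id.values() if c == {"chr1", "chrM"}) >= 3

    def test_decoy_regions_get_mapq_zero(self, toy_reference):
        numt = SimulatedNumt("N", "chr1", 10000, [(5001, 5300, "+")])
        design = CohortDesign(
            n_samples=1, carriers={"N": ["S0000"]},
            decoy_regions=[("chr1", 30000, 31000)], seed=1,
        )
        res = simulate_cohort(toy_reference, design, [numt])
        in_decoy = [
            r for r in res["reads"]["S0000"]
            if r.contig == "chr1" and r.pos < 31000 and r.pos + 150 > 30000
        ]
        assert in_decoy and all(r.mapq == 0 for r in in_decoy)

    def test_truth_frequencies_match_carriers(self, toy_reference):
        numt = SimulatedNumt("N", "chr1", 10000, [(5001, 5300, "+")])
        design = CohortDesign(
            n_samples=10, carriers={"N": ["S0001", "S0004"]}, mean_depth=0.0, seed=1
        )
        res = simulate_cohort(toy_reference, design, [numt])
        record = res["truth"]["numts"][0]
        assert record["frequency"] == 0.2
        assert [c["sample"] for c in record["carriers"]] == ["S0001", "S0004"]

    def test_de_novo_flag_only_in_child_record(self, toy_reference):
        numt = SimulatedNumt("N", "chr1", 10000, [(5001, 5300, "+")])
        design = CohortDesign(
            n_samples=3,
            carriers={"N": ["S0000"]},
            trios=[("S0000", "S0001", "S0002")],
            mean_depth=0.0,
            seed=1,
        )
        res = simulate_cohort(toy_reference, design, [numt])
        carriers = res["truth"]["numts"][0]["carriers"]
        assert carriers == [
            {"sample": "S0000", "de_novo": True, "tumour_specific": False}
        ]
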