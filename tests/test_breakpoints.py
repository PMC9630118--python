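import pytest

from numt_atlas import breakpoints as bp
from numt_atlas import detection as det
from numt_atlas.formats_io import AlignedRead, ReferenceGenome
from numt_atlas.synthetic_data import revcomp


@pytest.fixture(scope="module")
def refined(junction_cohort):
    """Refine all three planted NUMTs of the session cohort once."""
    ref = junction_cohort["reference"]
    reads = junction_cohort["reads"]["S0000"]
    truth = {t["numt_id"]: t for t in junction_cohort["truth"]["numts"]}
    out = {}
    for cand in det.detect_sample(reads, ref, 5):
        # match candidate to truth by proximity of the nuclear span
        for tid, t in truth.items():
            if abs(cand.nuclear_span[0] - t["nuclear_pos"]) < 1500:
                out[tid] = (cand, bp.refine_candidate(reads, cand, ref, tid))
    return {"truth": truth, "refined": out}


class TestBreakpointAccuracy:
    def test_blunt_junction_exact(self, refined):
        t = refined["truth"]["blunt"]
        _, r = refined["refined"]["blunt"]
        sides = {b.side: b for b in r["breakpoints"]}
        assert sides["nuclear"].position == t["nuclear_pos"]
        assert sides["mt_left"].position == t["segments"][0][0]
        assert sides["mt_right"].position == t["segments"][0][1]
        assert not r["complex"]

    def test_microhomology_within_ambiguity(self, refined):
        t = refined["truth"]["mh3"]
        _, r = refined["refined"]["mh3"]
        sides = {b.side: b for b in r["breakpoints"]}
        mh = t["microhomology_len"]
        assert abs(sides["nuclear"].position - t["nuclear_pos"]) <= mh
        assert abs(sides["mt_left"].position - t["segments"][0][0]) <= mh

    def test_reverse_insert_breakpoints(self, refined):
        t = refined["truth"]["ins2"]
        _, r = refined["refined"]["ins2"]
        sides = {b.side: b for b in r["breakpoints"]}
        # reverse-oriented insert: first insert base is the segment end
        assert sides["mt_left"].position == t["segments"][0][1]
        assert sides["mt_right"].position == t["segments"][0][0]
        assert sides["mt_left"].strand == "-"

    def test_junction_classes_recovered(self, refined):
        classes = {
            tid: {j.junction_side: j for j in r["junctions"]}
            for tid, (_, r) in refined["refined"].items()
        }
        assert classes["blunt"]["left"].junction_class == "blunt"
        left = classes["mh3"]["left"]
        assert left.junction_class == "microhomology"
        assert left.microhomology_len == 3
        ins = classes["ins2"]["left"]
        assert ins.junction_class == "insertion"
        assert ins.inserted_seq == "TT"

    def test_classes_partition(self, refined):
        for _, r in refined["refined"].values():
            for j in r["junctions"]:
                is_mh = j.junction_class == "microhomology"
                is_ins = j.junction_class == "insertion"
                is_blunt = j.junction_class == "blunt"
                assert is_mh + is_ins + is_blunt == 1
                assert is_mh == (j.microhomology_len >= 1)
                assert is_ins == (len(j.inserted_seq) >= 1)


def _clipped_read(contig, start, matched, clip, side, seq, mapq=60):
    cigar = (
        [("M", matched), ("S", clip)] if side == "right" else [("S", clip), ("M", matched)]
    )
    return AlignedRead(
        read_id=f"r{start}",
        sample_id="s",
        contig=contig,
        start=start,
        cigar=cigar,
        strand="+",
        mapq=mapq,
        mate_contig=None,
        mate_start=-1,
        is_supplementary=False,
        sequence=seq,
        is_read1=True,
    )


class TestCollectSplitReads:
    def _candidate(self):
        return det.NumtCandidate(
            sample_id="s",
            nuclear_contig="chr1",
            nuclear_span=(10000, 10400),
            mt_span=(5000, 5400),
            support=5,
            signatures=frozenset(),
        )

    def test_clip_near_candidate_collected(self, toy_reference):
        read = _clipped_read("chr1", 10350, 110, 40, "right", "A" * 150)
        got = bp.collect_split_reads([read], self._candidate(), "chrM", 16569)
        assert got == [read]

    def test_distant_clip_excluded(self, toy_reference):
        read = _clipped_read("chr1", 15500, 110, 40, "right", "A" * 150)
        assert bp.collect_split_reads([read], self._candidate(), "chrM", 16569) == []

    def test_small_clip_excluded(self, toy_reference):
        read = _clipped_read("chr1", 10350, 142, 8, "right", "A" * 150)
        assert bp.collect_split_reads([read], self._candidate(), "chrM", 16569) == []


class TestRealign:
    def test_all_n_clip_returns_null(self, toy_reference):
        seq = toy_reference.contigs["chr1"][10000:10110] + "N" * 40
        read = _clipped_read("chr1", 10000, 110, 40, "right", seq)
        assert bp.realign_split_read(read, toy_reference) is None

    def test_clean_mt_clip_located_exactly(self, toy_reference):
        mt = toy_reference.mt_sequence
        seq = toy_reference.contigs["chr1"][10000:10110] + mt[5000:5040]
        read = _clipped_read("chr1", 10000, 110, 40, "right", seq)
        sp = bp.realign_split_read(read, toy_reference)
        assert sp is not None
        assert sp.segment_b == ("chrM", (5000, 5040), "+")
        assert sp.clipped_junction_pos == 5001
        assert sp.unaligned_gap == 0


class TestDefineBreakpoints:
    def test_modal_tie_breaks_to_smallest(self):
        cand = det.NumtCandidate(
            sample_id="s", nuclear_contig="chr1", nuclear_span=(1000, 1400),
            mt_span=(100, 400), support=5, signatures=frozenset(),
        )
        splits = []
        for i, mt_pos in enumerate([1000, 1000, 1001]):
            splits.append(
                bp.SplitReadAlignment(
                    read_id=f"r{i}", sample_id="s",
                    segment_a=("chr1", (900, 1000 + (mt_pos - 1000)), "+"),
                    segment_b=("chrM", (mt_pos - 901, mt_pos - 801), "+"),
                    query_breakpoint=100, overlap_len=0, unaligned_gap=0,
                    clip_side="right",
                )
            )
        bps, _, _ = bp.define_breakpoints(splits, cand, "x", "chrM")
        sides = {b.side: b for b in bps}
        assert sides["nuclear"].position == 1000
        assert sides["nuclear"].split_support == 3

    def test_two_split_reads_insufficient(self):
        cand = det.NumtCandidate(
            sample_id="s", nuclear_contig="chr1", nuclear_span=(1000, 1400),
            mt_span=(100, 400), support=5, signatures=frozenset(),
        )
        splits = [
            bp.SplitReadAlignment(
                read_id=f"r{i}", sample_id="s",
                segment_a=("chr1", (900, 1000), "+"),
                segment_b=("chrM", (99, 199), "+"),
                query_breakpoint=100, overlap_len=0, unaligned_gap=0,
                clip_side="right",
            )
            for i in range(2)
        ]
        bps, _, _ = bp.define_breakpoints(splits, cand, "x", "chrM")
        assert bps == []


class TestClassifyJunctionStringOracle:
    def _reference(self, nuclear, mt):
        return ReferenceGenome(contigs={"chr1": nuclear, "chrM": mt}, mt_name="chrM")

    def test_shared_cca_microhomology(self):
        # nuclear ...ACGTCCA | mt CCAG...: "CCA" present on both flanks
        nuclear = "T" * 93 + "ACGTCCA" + "G" * 100
        mt = "CCAGTTTT" + "A" * 92
        ref = self._reference(nuclear, mt)
        nuc_bp = bp.Breakpoint("x", "nuclear", "chr1", 100, 5)
        mt_bp = bp.Breakpoint("x", "mt_left", "chrM", 4, 5, "+")
        j = bp.classify_junction(nuc_bp, mt_bp, "left", ref)
        assert j.junction_class == "microhomology"
        assert j.microhomology_len == 3

    def test_clean_abutment_blunt(self):
        nuclear = "A" * 100 + "G" * 100
        mt = "C" * 50 + "T" * 50
        ref = self._reference(nuclear, mt)
        j = bp.classify_junction(
            bp.Breakpoint("x", "nuclear", "chr1", 100, 5),
            bp.Breakpoint("x", "mt_left", "chrM", 51, 5, "+"),
            "left", ref,
        )
        assert j.junction_class == "blunt"

    def test_untemplated_bases_insertion(self):
        nuclear = "A" * 100 + "G" * 100
        mt = "C" * 50 + "T" * 50
        ref = self._reference(nuclear, mt)
        splits = [
            bp.SplitReadAlignment(
                read_id="r", sample_id="s",
                segment_a=("chr1", (50, 100), "+"),
                segment_b=("chrM", (50, 90), "+"),
                query_breakpoint=50, overlap_len=0, unaligned_gap=2,
                clip_side="right", inserted_seq="GT",
            )
        ] * 3
        j = bp.classify_junction(
            bp.Breakpoint("x", "nuclear", "chr1", 100, 5),
            bp.Breakpoint("x", "mt_left", "chrM", 51, 5, "+"),
            "left", ref, splits=splits,
        )
        assert j.junction_class == "insertion"
        assert j.inserted_seq == "GT"

    def test_undefined_breakpoint_rejected(self):
        ref = self._reference("A" * 100, "C" * 100)
        with pytest.raises(ValueError):
            bp.classify_junction(None, None, "left", ref)


class TestSequenceContext:
    def test_trinucleotide_tallies_sum_and_content(self, toy_reference):
        mt = toy_reference.mt_sequence
        bps = [
            bp.Breakpoint("x", "mt_left", "chrM", pos, 3, "+")
            for pos in (100, 200, 300)
        ]
        ctx = bp.breakpoint_sequence_context(bps, toy_reference)
        tri = ctx["trinucleotides"]["mt"]
        assert sum(tri.values()) == 3
        assert tri[mt[98:101]] >= 1

    def test_reverse_strand_context_reverse_complemented(self, toy_reference):
        mt = toy_reference.mt_sequence
        pos = 500
        fwd = bp.breakpoint_sequence_context(
            [bp.Breakpoint("x", "mt_left", "chrM", pos, 3, "+")], toy_reference
        )
        rev = bp.breakpoint_sequence_context(
            [bp.Breakpoint("x", "mt_left", "chrM", pos, 3, "-")], toy_reference
        )
        fwd_class = next(iter(fwd["trinucleotides"]["mt"]))
        rev_class = next(iter(rev["trinucleotides"]["mt"]))
        assert rev_class == revcomp(fwd_class)

    def test_poly_c_fold_closed_form(self, toy_reference):
        """Breakpoints planted before CCCC tracts: fold(k=4) = 1/f_C^4."""
        mt = toy_reference.mt_sequence
        positions = [
            i + 1
            for i in range(200, len(mt) - 5)
            if mt[i + 1 : i + 5] == "CCCC"
        ][:20]
        assert len(positions) >= 10
        bps = [
            bp.Breakpoint("x", "mt_right", "chrM", pos, 3, "+") for pos in positions
        ]
        ctx = bp.breakpoint_sequence_context(bps, toy_reference)
        f_c = ctx["mt_c_frequency"]
        stats4 = ctx["poly_c"][4]
        assert stats4["observed"] == len(positions)
        assert stats4["fold"] == pytest.approx(1 / f_c**4, rel=1e-9)
        assert stats4["p_value"] < 1e-6
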