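import numpy as np
import pandas as pd
import pytest

from numt_atlas import evolution as evo
from numt_atlas.cohort import CohortNumt
from numt_atlas.formats_io import ReferenceGenome
from numt_atlas.synthetic_data import revcomp


@pytest.fixture(scope="module")
def mt_fragment(toy_reference):
    return toy_reference.mt_sequence[4000:4300]


def _tile(fragment, read_len=100, step=40):
    return [
        fragment[i : i + read_len]
        for i in range(0, len(fragment) - read_len + 1, step)
    ] + [fragment[-read_len:]]


class TestAssembly:
    def test_error_free_reads_reassemble_exactly(self, mt_fragment):
        reads = _tile(mt_fragment)
        consensus, fragmented, n = evo.assemble_numt_consensus(reads)
        assert consensus == mt_fragment
        assert not fragmented
        assert n == len(set(reads))

    def test_shuffled_reads_same_result(self, mt_fragment):
        import random

        reads = _tile(mt_fragment)
        random.Random(1).shuffle(reads)
        consensus, _, _ = evo.assemble_numt_consensus(reads)
        assert consensus == mt_fragment

    def test_no_overlap_flags_fragmented(self, mt_fragment):
        reads = [mt_fragment[:100], mt_fragment[150:250]]
        consensus, fragmented, _ = evo.assemble_numt_consensus(reads)
        assert fragmented
        assert consensus in reads  # longest contig returned

    def test_full_variant_kept_by_majority(self, mt_fragment):
        alt_frag = mt_fragment[:150] + "A" + mt_fragment[151:]
        if alt_frag == mt_fragment:
            alt_frag = mt_fragment[:150] + "C" + mt_fragment[151:]
        reads = _tile(alt_frag)
        consensus, _, _ = evo.assemble_numt_consensus(reads)
        assert consensus == alt_frag

    def test_column_tie_marked_and_resolved_to_reference(self, mt_fragment):
        layout = [(0, "ACGT"), (0, "AGGT")]
        marked = evo.layout_consensus(layout)
        assert marked == "A?GT"
        resolved = evo._tie_reference_bases(marked, "ACGTACGT")
        assert resolved[1] == "C"

    def test_two_reads_minimum(self):
        with pytest.raises(ValueError):
            evo.assemble_numt_consensus(["ACGT"])


class TestConsensusAlignment:
    def test_placement_recovers_coordinates(self, toy_reference, mt_fragment):
        placed = evo.align_consensus_to_mt(mt_fragment, toy_reference)
        assert placed is not None
        start, columns, strand = placed
        assert start == 4001 and strand == "+"
        assert columns[0] == 4001 and columns[-1] == 4300

    def test_reverse_strand_placement(self, toy_reference, mt_fragment):
        placed = evo.align_consensus_to_mt(revcomp(mt_fragment), toy_reference)
        assert placed is not None
        assert placed[2] == "-"

    def test_garbage_rejected(self, toy_reference):
        assert evo.align_consensus_to_mt("ACGT" * 30, toy_reference) is None


def _numt(numt_id="N0", size=400, carriers=("a", "b"), freq_class="rare"):
    n = CohortNumt(
        numt_id, "chr1", 10000, 10000 + size, (4000, 4000 + size),
        carriers=set(carriers), size_bp=size,
    )
    n.freq_class = freq_class
    return n


def _consensus(sample, fragment, mt_start, numt_id="N0", mutations=()):
    seq = list(fragment)
    for off, alt in mutations:
        seq[off] = alt
    return evo.NumtConsensus(
        cohort_numt_id=numt_id,
        sample_id=sample,
        consensus="".join(seq),
        mt_start=mt_start,
        column_mt_pos=list(range(mt_start, mt_start + len(fragment))),
        n_supporting_reads=10,
    )


class TestVariantCalling:
    def _call(self, toy_reference, consensuses, numt=None, bps=None, **kw):
        numt = numt or _numt()
        return evo.call_numt_variants(
            consensuses,
            {numt.cohort_numt_id: numt},
            bps or {},
            toy_reference,
            **kw,
        )

    def test_planted_substitution_called(self, toy_reference, mt_fragment):
        ref_base = mt_fragment[100]
        alt = "A" if ref_base != "A" else "G"
        cons = [
            _consensus("a", mt_fragment, 4001, mutations=[(100, alt)]),
            _consensus("b", mt_fragment, 4001),
        ]
        variants = self._call(toy_reference, cons)
        assert len(variants) == 1
        v = variants[0]
        assert (v.mt_pos, v.ref, v.alt) == (4101, ref_base, alt)
        assert v.carrier_count == 1 and v.carrier_fraction == 0.5

    def test_variant_near_breakpoint_removed(self, toy_reference, mt_fragment):
        alt = "A" if mt_fragment[2] != "A" else "G"
        cons = [_consensus("a", mt_fragment, 4001, mutations=[(2, alt)])]
        variants = self._call(
            toy_reference, cons, bps={"N0": (4001, 4400)}
        )
        assert variants == []  # 3 bp from the left mt breakpoint

    def test_long_numt_excluded(self, toy_reference, mt_fragment):
        numt = _numt(size=1200)
        alt = "A" if mt_fragment[100] != "A" else "G"
        cons = [_consensus("a", mt_fragment, 4001, mutations=[(100, alt)])]
        assert self._call(toy_reference, cons, numt=numt) == []

    def test_low_complexity_position_removed(self, toy_reference):
        frag = toy_reference.mt_sequence[250:550]  # covers positions 251-550
        off = 310 - 251
        alt = "A" if frag[off] != "A" else "G"
        cons = [_consensus("a", frag, 251, mutations=[(off, alt)])]
        numt = _numt(size=300)
        assert self._call(toy_reference, cons, numt=numt) == []
        kept = self._call(
            toy_reference, cons, numt=numt, exclude_low_complexity=False
        )
        assert [v.mt_pos for v in kept] == [310]

    def test_outlier_sample_excluded(self, toy_reference, mt_fragment):
        muts = []
        for off in range(20, 260, 12):
            alt = "A" if mt_fragment[off] != "A" else "G"
            muts.append((off, alt))
        cons = [_consensus("hyper", mt_fragment, 4001, mutations=muts)] + [
            _consensus(f"clean{i}", mt_fragment, 4001) for i in range(12)
        ]
        variants = self._call(toy_reference, cons)
        assert all("hyper" not in v.carriers for v in variants)

    def test_clean_consensus_zero_variants(self, toy_reference, mt_fragment):
        cons = [
            _consensus("a", mt_fragment, 4001),
            _consensus("b", mt_fragment, 4001),
        ]
        assert self._call(toy_reference, cons) == []


class TestVariantGroups:
    def _variant(self, carriers, numt_id="N0"):
        return evo.NumtVariant(
            cohort_numt_id=numt_id, mt_pos=4100, ref="A", alt="G",
            carriers=set(carriers),
            carrier_fraction=0,  # set by caller
        )

    def test_majority_allele_excluded_from_a(self):
        numt = _numt(carriers=list("abcde"), freq_class="rare")
        v = self._variant(["a", "b", "c"])
        v.carrier_fraction = 0.6
        groups = evo.classify_variant_groups([v], {"N0": numt})
        assert groups["A"] == []
        assert v.numt_specific is False

    def test_ultra_rare_threshold_is_75(self):
        numt = _numt(carriers=list("abcd"), freq_class="ultra_rare")
        v = self._variant(["a", "b", "c"])
        v.carrier_fraction = 0.75
        groups = evo.classify_variant_groups([v], {"N0": numt})
        assert groups["A"] == [v]  # 75% is not "more than 75%"

    def test_singleton_in_a_not_b(self):
        v = self._variant(["a"])
        v.carrier_fraction = 0.2
        groups = evo.classify_variant_groups([v], {"N0": _numt(carriers="abcde")})
        assert groups["A"] == [v] and groups["B"] == []

    def test_unrelated_pair_in_b_not_c(self):
        v = self._variant(["a", "b"])
        v.carrier_fraction = 0.4
        groups = evo.classify_variant_groups(
            [v], {"N0": _numt(carriers="abcde")},
            family_of={"a": "f1", "b": "f2"},
        )
        assert groups["B"] == [v] and groups["C"] == []

    def test_family_pair_reaches_c(self):
        v = self._variant(["proband", "father"])
        v.carrier_fraction = 0.4
        groups = evo.classify_variant_groups(
            [v], {"N0": _numt(carriers=("proband", "father", "x", "y", "z"))},
            family_of={"proband": "fam1", "father": "fam1"},
        )
        assert groups["C"] == [v]

    def test_group_containment(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(12)]
        numt = _numt(carriers=samples)
        fams = {s: f"f{i % 4}" for i, s in enumerate(samples)}
        variants = []
        for k in range(30):
            carriers = rng.choice(samples, size=rng.integers(1, 9), replace=False)
            v = self._variant(carriers.tolist())
            v.mt_pos = 4100 + k
            v.carrier_fraction = len(carriers) / len(samples)
            variants.append(v)
        groups = evo.classify_variant_groups(variants, {"N0": numt}, fams)
        a, b, c = (set(map(id, groups[g])) for g in "ABC")
        assert c <= b <= a


class TestCodingEffects:
    def _reference_with_gene(self, codons, strand="+"):
        gene = "".join(codons)
        mt = "ACGTACGTAC" + (gene if strand == "+" else revcomp(gene)) + "ACGTACGTAC" * 120
        regions = pd.DataFrame(
            [
                {"name": "D-loop", "start": 1, "end": 5, "strand": "+", "kind": "control"},
                {"name": "HV1", "start": 1, "end": 2, "strand": "+", "kind": "control"},
                {"name": "HV2", "start": 2, "end": 3, "strand": "+", "kind": "control"},
                {"name": "HV3", "start": 3, "end": 4, "strand": "+", "kind": "control"},
                {"name": "OH", "start": 4, "end": 5, "strand": "+", "kind": "control"},
                {"name": "OL", "start": 5, "end": 6, "strand": "+", "kind": "control"},
                {
                    "name": "GENE", "start": 11, "end": 10 + len(gene),
                    "strand": strand, "kind": "protein",
                },
            ]
        )
        ref = ReferenceGenome(
            contigs={"chr1": "A" * 2000, "chrM": mt}, mt_name="chrM"
        )
        return ref, regions

    def test_ata_to_atg_synonymous_in_mt_code(self):
        """ATA and ATG both encode Met under the vertebrate mt code."""
        ref, regions = self._reference_with_gene(["ATA", "CCC"])
        v = evo.NumtVariant("N0", 13, "A", "G", carriers={"a"})
        out = evo.coding_effect_and_spectrum([v], ref, regions=regions)
        assert out["effects"][0]["gene_effect"] == "synonymous"

    def test_nonsynonymous_change(self):
        ref, regions = self._reference_with_gene(["ATA", "CCC"])
        v = evo.NumtVariant("N0", 14, "C", "A", carriers={"a"})  # CCC -> ACC
        out = evo.coding_effect_and_spectrum([v], ref, regions=regions)
        assert out["effects"][0]["gene_effect"] == "non-synonymous"

    def test_minus_strand_gene_uses_reverse_complement(self):
        # gene ATA (Met) on the minus strand: genomic TAT at 11..13
        ref, regions = self._reference_with_gene(["ATA", "CCC"], strand="-")
        # genomic change at the strand-level third codon base: A<->G keeps Met
        genomic_pos = 10 + len("ATACCC") - 2  # second genomic base = codon pos 2
        base = ref.mt_sequence[genomic_pos - 1]
        v = evo.NumtVariant("N0", genomic_pos, base, "C", carriers={"a"})
        out = evo.coding_effect_and_spectrum([v], ref, regions=regions)
        assert out["effects"][0]["gene_effect"] in {"synonymous", "non-synonymous"}

    def test_noncoding_variant_na_but_counted(self, toy_reference):
        v = evo.NumtVariant("N0", 2, toy_reference.mt_sequence[1], "A", carriers={"a"})
        if v.ref == "A":
            v.alt = "G"
        out = evo.coding_effect_and_spectrum([v], toy_reference)
        assert out["effects"][0]["gene_effect"] in {"NA", "synonymous", "non-synonymous"}
        assert sum(out["spectrum"].values()) == 1


class TestSpectrum:
    def test_pyrimidine_class_direct(self, toy_reference):
        mt = toy_reference.mt_sequence
        pos = mt.find("ACA", 1000) + 2  # centre C, 1-based
        v = evo.NumtVariant("N0", pos, "C", "T", carriers={"a"})
        out = evo.coding_effect_and_spectrum([v], toy_reference)
        assert out["spectrum"]["A[C>T]A"] == 1

    def test_purine_reverse_complemented(self, toy_reference):
        mt = toy_reference.mt_sequence
        pos = mt.find("TGG", 1000) + 2  # centre G -> C-centred class
        v = evo.NumtVariant("N0", pos, "G", "A", carriers={"a"})
        out = evo.coding_effect_and_spectrum([v], toy_reference)
        assert out["spectrum"]["C[C>T]A"] == 1

    def test_96_classes_exhaustive(self):
        assert len(evo.SPECTRUM_CLASSES) == 96
        assert len(set(evo.SPECTRUM_CLASSES)) == 96

    def test_spectrum_sums_to_snv_count(self, toy_reference):
        rng = np.random.default_rng(2)
        mt = toy_reference.mt_sequence
        variants = []
        for pos in rng.integers(10, 16000, size=40):
            ref = mt[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(evo.NumtVariant("N0", int(pos), ref, str(alt), {"a"}))
        out = evo.coding_effect_and_spectrum(variants, toy_reference)
        assert sum(out["spectrum"].values()) == 40

    def test_signature_cosine(self, toy_reference):
        mt = toy_reference.mt_sequence
        pos = mt.find("ACA", 1000) + 2
        v = evo.NumtVariant("N0", pos, "C", "T", carriers={"a"})
        out0 = evo.coding_effect_and_spectrum([v], toy_reference)
        sig = pd.DataFrame(
            {"S1": [out0["spectrum"][c] for c in evo.SPECTRUM_CLASSES]}
        )
        out = evo.coding_effect_and_spectrum(
            [v], toy_reference, signature_matrix=sig
        )
        assert out["signature_cosine"]["S1"] == pytest.approx(1.0)


class TestAgeEstimation:
    def _setup(self, toy_reference, reverted_fraction, n_carriers=3):
        """Consensuses agreeing on a known fraction of ancestral alleles."""
        mt = toy_reference.mt_sequence
        fragment = mt[4000:4400]
        anc = list(mt)
        rng = np.random.default_rng(8)
        informative = sorted(rng.choice(np.arange(4000, 4400), 40, replace=False))
        for p in informative:
            anc[p] = [b for b in "ACGT" if b != mt[p]][0]
        reverted = informative[: int(reverted_fraction * len(informative))]
        muts = [(p - 4000, anc[p]) for p in reverted]
        cons = [
            _consensus(f"s{i}", fragment, 4001, mutations=muts)
            for i in range(n_carriers)
        ]
        numt = _numt(size=400, carriers=[f"s{i}" for i in range(n_carriers)])
        return cons, numt, "".join(anc)

    def test_identical_to_human_age_zero(self, toy_reference):
        cons, numt, anc = self._setup(toy_reference, 0.0)
        ages = evo.estimate_numt_age(cons, {"N0": numt}, anc, toy_reference)
        assert len(ages) == 1
        assert ages[0].r == 1.0
        assert ages[0].age_myr == 0.0

    def test_half_reverted_age_three_myr(self, toy_reference):
        cons, numt, anc = self._setup(toy_reference, 0.5)
        ages = evo.estimate_numt_age(cons, {"N0": numt}, anc, toy_reference)
        assert ages[0].r == pytest.approx(0.5)
        assert ages[0].age_myr == pytest.approx(3.0)

    def test_single_carrier_excluded(self, toy_reference):
        cons, numt, anc = self._setup(toy_reference, 0.0, n_carriers=1)
        assert evo.estimate_numt_age(cons, {"N0": numt}, anc, toy_reference) == []

    def test_concatenated_excluded(self, toy_reference):
        cons, numt, anc = self._setup(toy_reference, 0.0)
        ages = evo.estimate_numt_age(
            cons, {"N0": numt}, anc, toy_reference, concatenated_ids={"N0"}
        )
        assert ages == []

    def test_no_informative_sites_excluded(self, toy_reference):
        cons, numt, _ = self._setup(toy_reference, 0.0)
        ages = evo.estimate_numt_age(
            cons, {"N0": numt}, toy_reference.mt_sequence, toy_reference
        )
        assert ages == []

    def test_length_filters(self, toy_reference):
        cons, numt, anc = self._setup(toy_reference, 0.0)
        numt.size_bp = 1500
        assert evo.estimate_numt_age(cons, {"N0": numt}, anc, toy_reference) == []
        numt.size_bp = 30
        assert evo.estimate_numt_age(cons, {"N0": numt}, anc, toy_reference) == []
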