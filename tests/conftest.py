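import pytest

from numt_atlas.synthetic_data import (
    CohortDesign,
    SimulatedNumt,
    as_aligned_reads,
    build_toy_references,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_reference():
    return build_toy_references({"chr1": 50000}, seed=1)


@pytest.fixture(scope="session")
def junction_cohort(toy_reference):
    """Two-sample cohort: one carrier of three NUMTs, one blank sample.

    The three planted NUMTs exercise the three junction mechanisms: blunt,
    3 bp microhomology and a 2 bp untemplated insertion (reverse-oriented
    mt fragment).
    """
    numts = [
        SimulatedNumt("blunt", "chr1", 10000, [(5001, 5500, "+")]),
        SimulatedNumt("mh3", "chr1", 25000, [(8001, 8400, "+")], microhomology_len=3),
        SimulatedNumt("ins2", "chr1", 40000, [(12001, 12300, "-")], inserted_bases="TT"),
    ]
    design = CohortDesign(
        n_samples=2,
        carriers={n.numt_id: ["S0000"] for n in numts},
        seed=11,
    )
    res = simulate_cohort(toy_reference, design, numts)
    reads = {s: as_aligned_reads(r, s) for s, r in res["reads"].items()}
    return {
        "reference": toy_reference,
        "numts": numts,
        "design": design,
        "truth": res["truth"],
        "records": res["reads"],
        "reads": reads,
    }
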