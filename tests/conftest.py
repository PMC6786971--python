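import pytest

import consbin as cb
from consbin.core import ScoringParams


@pytest.fixture(scope="session")
def refs():
    return cb.default_reference_sets()


@pytest.fixture()
def worked_example():
    """The tiny two-binner instance whose selection outcome is known by hand.

    Binner X bins c1+c2+c3; binner Y splits them as {c1,c2} and {c3,c4}.
    SCG families fam1..fam3 sit on c1, c2, c3; c4 carries a second copy of
    fam3.  Against a 3-family reference set with b=c=t=0.5, X1 scores 1.0
    and wins; Y1 empties, Y2 shrinks to {c4}, rescores 1/3 and is extracted
    but rejected.  Final set: [X1] alone.
    """
    lengths = {"c1": 10, "c2": 10, "c3": 10, "c4": 10}
    bin_sets = [
        cb.BinSet("X", {"X1": {"c1", "c2", "c3"}}),
        cb.BinSet("Y", {"Y1": {"c1", "c2"}, "Y2": {"c3", "c4"}}),
    ]
    ann = cb.SCGAnnotation()
    for cid, fam in [("c1", "fam1"), ("c2", "fam2"), ("c3", "fam3"), ("c4", "fam3")]:
        ann.add(cid, fam, "bacteria", gene_id=f"g_{cid}")
    test_refs = {
        "bacteria": cb.ReferenceSCGSet("bacteria", frozenset({"fam1", "fam2", "fam3"})),
        "archaea": cb.ReferenceSCGSet("archaea", frozenset({"afam1", "afam2"})),
    }
    return lengths, bin_sets, ann, test_refs, ScoringParams(0.5, 0.5, 0.5)


@pytest.fixture(scope="session")
def small_benchmark():
    """A 10-genome community with 3 corrupted binners, reused across tests."""
    cfg = cb.SimConfig(seed=42, n_genomes=10, n_archaea=1,
                       genome_length_bounds=(200_000, 1_000_000),
                       contig_length_bounds=(5_000, 100_000))
    return cb.generate_benchmark(cfg, n_binners=3)
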