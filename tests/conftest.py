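import numpy as np
import pytest

from benguela.io_formats import GenotypeMatrix, PopulationMap, SequenceAlignment


@pytest.fixture
def toy_popmap():
    inds = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
    return PopulationMap(inds, {"A": "north", "B": "south"})


@pytest.fixture
def toy_alignment(toy_popmap):
    # two tight clusters separated by two fixed differences (sites 0 and 5)
    seqs = {
        "a0": "AAAACCGGTT",
        "a1": "AAAACCGGTT",
        "a2": "AAATCCGGTT",
        "b0": "GAAACCGGTA",
        "b1": "GAAACCGGTA",
        "b2": "GAAACCGATA",
    }
    return SequenceAlignment.from_records(list(seqs), list(seqs.values()))


@pytest.fixture
def toy_genotypes():
    """Two populations, three loci; population X fixed-ish for low alleles,
    Y shifted upward at locus L3."""
    ids = tuple(f"x{i}" for i in range(6)) + tuple(f"y{i}" for i in range(6))
    calls = np.array(
        [
            # L1        L2          L3
            [[100, 102], [150, 150], [200, 202]],
            [[100, 100], [150, 152], [200, 200]],
            [[102, 102], [150, 150], [202, 202]],
            [[100, 102], [152, 152], [200, 202]],
            [[100, 100], [150, 152], [200, 200]],
            [[100, 102], [150, 150], [200, 202]],
            [[100, 102], [150, 152], [210, 212]],
            [[102, 102], [152, 152], [210, 210]],
            [[100, 100], [150, 150], [212, 212]],
            [[100, 102], [150, 152], [210, 212]],
            [[102, 102], [152, 152], [210, 210]],
            [[100, 102], [150, 150], [210, 212]],
        ]
    )
    gm = GenotypeMatrix(ids, ("L1", "L2", "L3"), calls)
    popmap = PopulationMap(
        {i: ("X" if i.startswith("x") else "Y") for i in ids},
        {"X": "north", "Y": "south"},
    )
    return gm, popmap
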