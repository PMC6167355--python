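import numpy as np
import pytest

from xstrkit import LinkageGroupDef, Sample, GenotypeTable
from xstrkit.simulate import SyntheticSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Four loci in two linkage groups, modest sample sizes."""
    return SyntheticSpec(
        n_females=40, n_males=30,
        loci={
            "L1": {"10": 0.5, "11": 0.3, "12": 0.2},
            "L2": {"8": 0.6, "9": 0.4},
            "L3": {"20": 0.4, "21": 0.3, "22": 0.2, "23": 0.1},
            "L4": {"15": 0.7, "16": 0.3},
        },
        linkage_groups=(LinkageGroupDef("G1", ("L1", "L2")),
                        LinkageGroupDef("G2", ("L3", "L4"))),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_table(small_spec) -> GenotypeTable:
    table, _ = simulate_genotypes(small_spec)
    return table


@pytest.fixture(scope="session")
def gelao_table():
    from xstrkit import gelao_like_fixture
    return gelao_like_fixture(1)


def make_table(loci, rows):
    """Build a GenotypeTable from (sample_id, sex, {locus: call-tuple}) rows."""
    return GenotypeTable(loci=list(loci),
                         samples=[Sample(sid, sex, calls) for sid, sex, calls in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
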