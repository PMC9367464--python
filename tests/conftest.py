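import numpy as np
import pytest

from sequestra.pedigree import Pedigree, PedigreeRecord
from sequestra.simulate import make_paper_margin_ledger


@pytest.fixture(scope="session")
def margin_ledger() -> Pedigree:
    """Deterministic pedigree reproducing the published table margins."""
    return make_paper_margin_ledger()


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Founder sire + founder dam + one kitten."""
    return Pedigree(
        [
            PedigreeRecord(id="s1", sex="male"),
            PedigreeRecord(id="d1", sex="female"),
            PedigreeRecord(id="k1", sire="s1", dam="d1", sex="female",
                           birth_year=2010, status="affected"),
        ]
    )


@pytest.fixture
def fullsib_mating_pedigree() -> Pedigree:
    """Two founders, two full sibs, and an offspring of the sib mating."""
    return Pedigree(
        [
            PedigreeRecord(id="gs", sex="male"),
            PedigreeRecord(id="gd", sex="female"),
            PedigreeRecord(id="b", sire="gs", dam="gd", sex="male"),
            PedigreeRecord(id="s", sire="gs", dam="gd", sex="female"),
            PedigreeRecord(id="x", sire="b", dam="s"),
        ]
    )


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random valid pedigree of n animals (ancestors appear before offspring)."""
    records = []
    for i in range(n):
        sire = dam = None
        males = [j for j in range(i) if j % 2 == 0]
        females = [j for j in range(i) if j % 2 == 1]
        if males and rng.random() < 0.7:
            sire = f"a{rng.choice(males)}"
        if females and rng.random() < 0.7:
            dam = f"a{rng.choice(females)}"
        records.append(
            PedigreeRecord(
                id=f"a{i}",
                sire=sire,
                dam=dam,
                sex="male" if i % 2 == 0 else "female",
            )
        )
    return Pedigree(records)
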