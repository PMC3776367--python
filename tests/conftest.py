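import numpy as np
import pytest

from adverank.containers import InteractionTable, LabelMatrix, ProteinChemicalTable
from adverank.synthetic import FixtureSpec, generate_fixture


def random_instance(rng, n_drugs=None, n_proteins=None, n_effects=None):
    """Small random problem instance in both package and naive-dict form.

    Interaction scores are integer-valued so sums are exact in floating
    point and oracle comparisons can use strict equality.
    """
    n_drugs = n_drugs or int(rng.integers(3, 13))
    n_proteins = n_proteins or int(rng.integers(1, 7))
    n_effects = n_effects or int(rng.integers(2, 9))
    drugs = [f"d{i}" for i in range(n_drugs)]
    proteins = [f"p{i}" for i in range(n_proteins)]
    effects = [f"e{i}" for i in range(n_effects)]

    cc_dict = {}
    cc = InteractionTable()
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            if rng.uniform() < 0.4:
                s = float(rng.integers(1, 1000))
                cc_dict[(drugs[i], drugs[j])] = s
                cc_dict[(drugs[j], drugs[i])] = s
                cc.add(drugs[i], drugs[j], s)

    pc_dict = {}
    pc = ProteinChemicalTable()
    for d in drugs:
        for p in proteins:
            if rng.uniform() < 0.4:
                s = float(rng.integers(1, 1000))
                pc_dict[(p, d)] = s
                pc.add(p, d, s)

    label_map = {}
    for d in drugs:
        labs = {e for e in effects if rng.uniform() < 0.4}
        if not labs:
            labs = {effects[int(rng.integers(n_effects))]}
        label_map[d] = labs
    labels = LabelMatrix(drugs, effects, label_map)

    return {
        "drugs": drugs,
        "proteins": proteins,
        "effects": effects,
        "cc": cc,
        "pc": pc,
        "labels": labels,
        "cc_dict": cc_dict,
        "pc_dict": pc_dict,
        "label_map": label_map,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted-community fixture at a fixed seed."""
    return generate_fixture(FixtureSpec(seed=7))


@pytest.fixture
def small_fixture():
    return generate_fixture(
        FixtureSpec(
            n_drugs=16,
            n_proteins=8,
            n_side_effects=6,
            n_communities=2,
            seed=11,
        )
    )
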