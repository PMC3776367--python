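"""Generate a synthetic interaction/label dataset and build a benchmark.

Drugs are grouped into communities that share side effects; the benchmark
step keeps the most-populated side-effect categories, drops drugs with no
interaction coverage, counts structural vs virtual drugs (one virtual drug
per category a compound belongs to) and draws a 10% random test split.
"""

from adverank import build_benchmark, count_virtual_drugs
from adverank.synthetic import FixtureSpec, generate_fixture, write_fixture

fixture = generate_fixture(FixtureSpec(seed=7))
paths = write_fixture(fixture, "scratch/fixture")
print("fixture files:", *(p.name for p in paths.values()))

dataset = build_benchmark(
    list(fixture.labels.pairs()),
    fixture.cc,
    fixture.pc,
    top_k=fixture.labels.n_effects,
    test_fraction=0.1,
    split_seed=0,
)
n_str, n_vir = count_virtual_drugs(dataset.labels)
print(f"structure-different drugs N(str) = {n_str}")
print(f"virtual drugs N(vir) = sum_i N(C_i) = {n_vir}")
print(f"train/test split: {len(dataset.train_drugs)}/{len(dataset.test_drugs)}")
# N(vir) > N(str) because most drugs carry several side-effect labels;
# the split sizes follow the 10% rule with exact halves rounded down.
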