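"""Rank side effects for query drugs with the two-step predictor.

Step 1 scores each side effect by summing the query's chemical-chemical
interaction confidences into the categories of its interactive training
drugs.  When a drug has no interactive training drug at all (a "chemical
orphan"), step 2 falls back to the hybrid score built from shared chemical
neighbors and shared protein partners.
"""

from adverank import predict_two_step
from adverank.synthetic import FixtureSpec, generate_fixture

fixture = generate_fixture(FixtureSpec(seed=7))
train = fixture.labels

connected = next(d for d in train.drugs if d not in fixture.orphans)
orphan = sorted(fixture.orphans)[0]

for drug in (connected, orphan):
    pred = predict_two_step(drug, train, fixture.cc, fixture.pc)
    truth = sorted(train.effects_of(drug))
    print(f"\nquery {drug} (method used: {pred.method}; true effects: {truth})")
    for rank, effect, score in pred.items[:5]:
        hit = "*" if effect in truth else " "
        print(f"  {rank}. {effect}  score={score:9.2f} {hit}")
# Scores are relative evidence, not probabilities: higher means more
# interaction-weighted training drugs carry that side effect. Starred
# rows are true side effects of the query.
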