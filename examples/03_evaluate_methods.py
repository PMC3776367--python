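"""Compare the interaction-based method with the similarity baseline.

Both methods are evaluated by leave-one-out jackknife: each drug's labels
are withheld, its side effects re-predicted from the remaining drugs, and
AC(j) = P(j)/N records the fraction of drugs whose j-th ranked candidate
is a true side effect.
"""

from adverank import jackknife_evaluate, no_skill_ac1
from adverank.synthetic import FixtureSpec, generate_fixture

fixture = generate_fixture(FixtureSpec(seed=7))
train = fixture.labels

interaction, _ = jackknife_evaluate(train, "interaction", cc=fixture.cc, pc=fixture.pc)
similarity, _ = jackknife_evaluate(train, "similarity", provider=fixture.provider)

print(f"jackknife over N = {interaction.n_drugs} drugs")
print("order  interaction  similarity  difference")
for j in range(1, 6):
    a, b = interaction.ac(j), similarity.ac(j)
    print(f"{j:>5}  {a:>10.2%}  {b:>9.2%}  {a - b:>+9.2%}")
print(f"\nno-skill AC(1) baseline: {no_skill_ac1(train):.2%}")
# A random ranking would hit at order 1 only as often as the mean label
# density; the interaction method should clear that by a wide margin and
# typically outrank the similarity baseline at low orders.
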