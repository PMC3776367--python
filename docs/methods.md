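# Methods

## Model

The predictor treats side-effect assignment as multi-label ranking by
guilt by association. Its premise: compounds that interact — by sharing
reactions, structures/activities, or literature associations — tend to
share biological functions, and side effects are part of those functions.
Evidence for "query drug `d` has side effect `C_j`" is therefore
accumulated from training drugs labeled with `C_j`, weighted by how
strongly `d` interacts with them.

Three score vectors over the side-effect catalog `C_1..C_m` are defined
for a query drug against a training set `S'` (any training drug with the
query's identifier is excluded from `S'`):

* **direct** — `Π^c(d→C_j) = Σ_{d_i∈S'} Q^c(d,d_i)·c_{i,j}`, a sum of
  chemical–chemical confidence scores into each category;
* **hybrid** — the same sum with `Q^c` replaced by the shared-neighbor
  score `Q^h` (below);
* **similarity** — `Π^s(d→C_j) = max_{d_i∈S'} Q^s(d,d_i)·c_{i,j}`, the
  best structural similarity to any drug in the category.

The two-step predictor uses the direct vector when *any* entry is
positive and otherwise falls back to the hybrid vector. "Any entry
positive" is the implemented reading of a "trivial" direct outcome: the
alternative (falling back whenever the top score is weak) would need a
threshold with no principled value. If both vectors are all-zero the
prediction is empty and every order counts as a miss downstream.

### The hybrid score

For a pair of drugs with shared chemical neighbors `I^c(d1,d2)` and
shared protein partners `I^p(d1,d2)` (both defined by strictly positive
confidence scores),

```
Q^h(d1,d2) = [ Σ_{d'} (Q^c(d1,d') + Q^c(d2,d'))
             + Σ_{p'} (Q^p(p',d1) + Q^p(p',d2)) ] / (2·|I^c ∪ I^p|)
```

i.e. the mean, over shared entities, of the average confidence each
entity carries toward the two drugs. Chemical and protein identifiers
are namespace-tagged before the union, so the denominator is always
`2(|I^c∩| + |I^p∩|)` even if a chemical and a protein share a raw ID
string. The empty-union case is defined as `Q^h = 0`: no shared evidence
degrades gracefully to "no evidence" instead of 0/0. `Q^h` is symmetric,
scale-covariant (multiplying all confidences by λ multiplies it by λ),
and bounded by the largest single confidence score in the tables.

### Ranking

Only strictly positive scores are emitted (a zero score means "no
evidence", not "ranked last"). Ties break on higher training prevalence
`N(C_i)` first — a more common side effect is the safer guess — then on
catalog index, making the ordering fully deterministic.

## Inputs and their handling

Interaction files follow the STITCH detailed-links dialects
(tab-separated, header naming a `combined_score` column, edges listed in
both directions). Decisions made where the dialect leaves room:

* **Duplicate/bidirectional edges collapse by MAX.** Real dumps can list
  a pair twice with differing scores; taking the maximum keeps the
  interaction, consistent with "positive score = interactive".
* **Scores stay on their native 0–999 scale.** Every downstream formula
  is a scale-covariant sum, average or max, so normalization would only
  change units; rankings are invariant.
* **`min_score` is an exclusive threshold defaulting to 0** (keep rows
  with score > 0). Public interaction databases are often used with a
  low-confidence cutoff (e.g. 150); that is exposed as a parameter, not
  imposed.
* **Self-loops are dropped at load** — a drug must never feed evidence
  about itself back into its own prediction.
* **Header detection:** a first row whose score fields are all numeric is
  data (canonical column order assumed); otherwise it is a header.

Benchmark construction keeps the `top_k` (default 100) side effects with
the most drugs, then excludes drugs with neither a chemical nor a protein
neighbor, then drops any category emptied by that exclusion — in that
order. The test split draws `ceil(fraction·n − 0.5)` drugs (half-down
rounding, so 10% of 835 is 83, not 84) uniformly without replacement
under a required, recorded seed.

## Evaluation

`AC(j) = P(j)/N` where `P(j)` counts evaluated drugs whose j-th ranked
candidate is a true side effect and `N` is the number of
structure-different drugs evaluated. `N` is fixed across orders: a drug
whose prediction list is shorter than `j` (or empty) misses at order `j`
rather than shrinking the denominator.

The jackknife removes only the left-out drug's **labels** (implemented as
identifier exclusion from `S'`), not its network edges or similarity
scores: the interaction network is external knowledge, while the label
matrix is the model being evaluated. For the similarity method this also
means a drug's self-similarity of 1.0 never reaches its own jackknife
prediction — otherwise leave-one-out would be degenerate whenever a
structural duplicate exists.

## Structural similarity backends

The baseline needs a symmetric `Q^s(d1,d2) ∈ [0,1]` with `Q^s(d,d) = 1`
for a valid structure. The default backend computes RDKit path-based
(Daylight-style) fingerprints from SMILES — 2048 bits, paths of length
1–7, the library defaults, recorded on every fingerprint so mismatched
parameters cannot be compared — and the Tanimoto coefficient
|A∩B| / |A∪B|, with two empty fingerprints defined as identical (1.0)
and exactly one empty as 0.0. A drug whose SMILES cannot be parsed scores
0 against everything (logged) rather than aborting a run. A precomputed
table backend (validated for symmetry within 1e-9 and range) allows
bit-exact reuse of similarity scores produced by other toolkits, which
publish no single canonical fingerprint.

## Synthetic data generator

`FixtureSpec`/`generate_fixture` emulate the guilt-by-association premise
in miniature: drugs are partitioned into communities; each community owns
a block of side effects and a block of proteins; chemical edges are drawn
with probability `p_edge_within` (default 0.8) inside and
`p_edge_between` (0.05) across communities; drugs link to their
community's proteins with probability 0.8; each drug carries each
characteristic effect with `p_label_within` (0.9) plus background labels
tuned so the mean label count is about `labels_per_drug` (3). Confidence
scores are uniform on 150–999, the medium-to-high confidence band of
public interaction databases. Defaults: 40 drugs, 12 proteins, 10 side
effects, 4 communities. A fifth of the drugs (`frac_chemical_orphans`)
get no chemical edges at all, so roughly 80% of drugs exercise the direct
path and the rest the hybrid fallback. Each random component (edges,
protein links, labels, scores, similarity) draws from its own child
stream of the seed, so changing one parameter perturbs only that
component; output is byte-identical across runs at the same seed.

What the generator does **not** emulate: real chemical structures (the
similarity table is numeric — high within communities, low across), the
heavy-tailed degree distribution and score distribution of real
interaction databases, correlated side-effect co-occurrence beyond
community blocks, and label noise from pharmacovigilance reporting.
Passing tests on fixtures therefore demonstrate the algorithms'
correctness and the expected qualitative behavior (interaction method ≫
no-skill, usually ≥ similarity baseline at low orders), not real-world
accuracy levels.

## Problem sizes and numerical choices

Tests and the acceptance script run on the default 40-drug fixture and on
random instances of ≤ 12 drugs, 6 proteins and 8 effects — sizes chosen so
brute-force reference implementations (explicit set materialization and
triple loops) can verify every score exactly. Random-instance scores are
integer-valued, making floating-point sums order-independent and oracle
comparisons exact. File round-trips write floats with `repr` and parse
with correctly rounded converters, so write→read reproduces tables
bit-for-bit.

## Known limitations

* Accuracy on synthetic fixtures does not transfer to real STITCH/SIDER
  data; evaluating there requires the original dumps and a recorded split.
* One level of indirection only: the hybrid score never chains through
  two or more intermediaries.
* Scores are relative rankings, not calibrated probabilities.
* Compound identifiers are opaque; stereo/flat variants of the same
  molecule are distinct drugs unless the input merges them.
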