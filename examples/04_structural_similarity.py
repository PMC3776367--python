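"""Structural-similarity scoring from SMILES strings.

The baseline ranker needs a pairwise similarity Q^s in [0, 1]; here it is
built from RDKit path fingerprints compared with the Tanimoto coefficient
(shared bits / total bits).  A precomputed score table can be plugged in
instead for bit-exact reuse of scores from other toolkits.
"""

from adverank import (
    FingerprintProvider,
    fingerprint_from_smiles,
    predict_similarity,
    tanimoto,
)
from adverank.containers import LabelMatrix

smiles = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "salicylic_acid": "O=C(O)c1ccccc1O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

fp_a = fingerprint_from_smiles(smiles["aspirin"])
fp_s = fingerprint_from_smiles(smiles["salicylic_acid"])
print(f"Tanimoto(aspirin, salicylic acid) = {tanimoto(fp_a, fp_s):.3f}")

provider = FingerprintProvider(smiles)
train = LabelMatrix(
    ["salicylic_acid", "ibuprofen", "caffeine"],
    ["GI_upset", "Tinnitus", "Insomnia"],
    {
        "salicylic_acid": {"GI_upset", "Tinnitus"},
        "ibuprofen": {"GI_upset"},
        "caffeine": {"Insomnia"},
    },
)
pred = predict_similarity("aspirin", train, provider)
print("similarity-based ranking for aspirin:")
for rank, effect, score in pred.items:
    print(f"  {rank}. {effect}  Q^s={score:.3f}")
# Each side effect scores the maximum similarity between the query and
# any training drug in that category, so aspirin inherits the labels of
# its close analog salicylic acid first.
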