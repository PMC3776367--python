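import numpy as np
import pytest

from adverank.containers import (
    InteractionTable,
    LabelMatrix,
    ProteinChemicalTable,
    ScoreVector,
)
from adverank.ranking import (
    predict_two_step,
    rank,
    score_direct,
    score_hybrid,
    score_similarity,
)
from adverank.similarity import PrecomputedProvider

from .conftest import random_instance
from .oracles import (
    naive_score_direct,
    naive_score_hybrid,
    naive_score_similarity,
)


def matrix(label_map, effects):
    return LabelMatrix(list(label_map), effects, label_map)


class TestScoreDirect:
    def test_no_interactive_training_drugs_gives_zero_vector(self):
        train = matrix({"d1": {"C1"}}, ["C1", "C2"])
        cc = InteractionTable()
        sv = score_direct("q", train, cc)
        assert sv.is_trivial()

    def test_hand_computed_sums(self):
        train = matrix({"d1": {"C1"}, "d2": {"C1", "C2"}}, ["C1", "C2", "C3"])
        cc = InteractionTable()
        cc.add("q", "d1", 0.4)
        cc.add("q", "d2", 0.6)
        sv = score_direct("q", train, cc)
        assert sv.scores == pytest.approx({"C1": 1.0, "C2": 0.6, "C3": 0.0})

    def test_query_identifier_excluded_from_training(self):
        train = matrix({"q": {"C1"}, "d1": {"C2"}}, ["C1", "C2"])
        cc = InteractionTable()
        cc.add("q", "d1", 5.0)
        sv = score_direct("q", train, cc)
        # q's own row must not contribute even though cc could link q to itself
        assert sv.scores["C1"] == 0.0
        assert sv.scores["C2"] == 5.0

    def test_matches_triple_loop_brute_force(self, rng):
        for _ in range(30):
            inst = random_instance(rng)
            train = inst["labels"]
            for q in inst["drugs"]:
                sv = score_direct(q, train, inst["cc"])
                expected = naive_score_direct(
                    q, inst["label_map"], inst["effects"], inst["cc_dict"]
                )
                assert sv.scores == expected

    def test_additive_over_training_partition(self, rng):
        inst = random_instance(rng, n_drugs=10)
        drugs = inst["drugs"]
        q = drugs[0]
        rest = drugs[1:]
        half = len(rest) // 2
        part_a, part_b = rest[:half], rest[half:]
        effects = inst["effects"]
        whole = score_direct(
            q, matrix({d: inst["label_map"][d] for d in rest}, effects), inst["cc"]
        )
        a = score_direct(
            q, matrix({d: inst["label_map"][d] for d in part_a}, effects), inst["cc"]
        )
        b = score_direct(
            q, matrix({d: inst["label_map"][d] for d in part_b}, effects), inst["cc"]
        )
        for e in effects:
            assert whole.scores[e] == a.scores[e] + b.scores[e]


class TestScoreHybrid:
    def test_all_zero_hybrid_scores_give_zero_vector(self):
        train = matrix({"d1": {"C1"}}, ["C1"])
        sv = score_hybrid("q", train, InteractionTable(), ProteinChemicalTable())
        assert sv.is_trivial()

    def test_single_training_drug_hand_example(self):
        # hybrid score q<->d1 is 0.75 (shared chemical + shared protein)
        cc = InteractionTable()
        cc.add("q", "x", 0.9)
        cc.add("d1", "x", 0.7)
        pc = ProteinChemicalTable()
        pc.add("p1", "q", 0.8)
        pc.add("p1", "d1", 0.6)
        train = matrix({"d1": {"C1", "C3"}}, ["C1", "C2", "C3"])
        sv = score_hybrid("q", train, cc, pc)
        assert sv.scores == pytest.approx({"C1": 0.75, "C2": 0.0, "C3": 0.75})

    def test_matches_brute_force(self, rng):
        for _ in range(15):
            inst = random_instance(rng, n_drugs=8, n_proteins=4)
            train = inst["labels"]
            for q in inst["drugs"][:4]:
                sv = score_hybrid(q, train, inst["cc"], inst["pc"])
                expected = naive_score_hybrid(
                    q, inst["label_map"], inst["effects"], inst["cc_dict"], inst["pc_dict"]
                )
                assert sv.scores == expected


class TestScoreSimilarity:
    def test_max_rule(self):
        train = matrix({"d1": {"C1"}, "d2": {"C1"}}, ["C1"])
        provider = PrecomputedProvider({("q", "d1"): 0.8, ("q", "d2"): 0.5})
        sv = score_similarity("q", train, provider)
        assert sv.scores["C1"] == 0.8

    def test_unlabeled_effect_scores_zero(self):
        train = matrix({"d1": {"C1"}}, ["C1", "C5"])
        provider = PrecomputedProvider({("q", "d1"): 0.9})
        sv = score_similarity("q", train, provider)
        assert sv.scores["C5"] == 0.0

    def test_identical_duplicate_structure_reaches_one(self):
        train = matrix({"dup": {"C1", "C2"}}, ["C1", "C2", "C3"])
        provider = PrecomputedProvider({("q", "dup"): 1.0})
        sv = score_similarity("q", train, provider)
        assert sv.scores["C1"] == sv.scores["C2"] == 1.0

    def test_provider_failure_degrades_to_zero(self, caplog):
        class Flaky:
            def similarity(self, a, b):
                raise RuntimeError("backend down")

        train = matrix({"d1": {"C1"}}, ["C1"])
        with caplog.at_level("WARNING"):
            sv = score_similarity("q", train, Flaky())
        assert sv.scores["C1"] == 0.0
        assert any("failed" in r.message for r in caplog.records)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            inst = random_instance(rng)
            sims = {}
            drugs = inst["drugs"]
            for i in range(len(drugs)):
                for j in range(i + 1, len(drugs)):
                    sims[(drugs[i], drugs[j])] = float(rng.uniform(0, 1))
            provider = PrecomputedProvider(sims)
            for q in drugs:
                sv = score_similarity(q, inst["labels"], provider)
                expected = naive_score_similarity(
                    q, inst["label_map"], inst["effects"], sims
                )
                assert sv.scores == expected


class TestRank:
    def test_descending_positive_chain(self):
        train = matrix({"d": {"C2", "C4", "C90"}}, ["C2", "C4", "C90", "C99"])
        sv = ScoreVector("q", {"C2": 5.0, "C4": 3.0, "C90": 1.0, "C99": 0.0}, "direct")
        pred = rank(sv, train)
        assert [e for _, e, _ in pred.items] == ["C2", "C4", "C90"]

    def test_all_zero_vector_gives_empty_prediction(self):
        train = matrix({"d": {"C1"}}, ["C1"])
        sv = ScoreVector("q", {"C1": 0.0}, "direct")
        assert rank(sv, train).items == []

    def test_tie_broken_by_training_prevalence_then_index(self):
        label_map = {f"d{i}": {"C1"} for i in range(5)}
        for i in range(3):
            label_map[f"d{i}"].add("C2")
        label_map["d0"].add("C3")
        train = matrix(label_map, ["C1", "C2", "C3"])
        # N(C1)=5 > N(C2)=3 > N(C3)=1
        sv = ScoreVector("q", {"C1": 2.0, "C2": 2.0, "C3": 2.0}, "direct")
        pred = rank(sv, train)
        assert [e for _, e, _ in pred.items] == ["C1", "C2", "C3"]

    def test_deterministic(self, rng):
        inst = random_instance(rng)
        sv = ScoreVector(
            "q",
            {e: float(rng.integers(0, 4)) for e in inst["effects"]},
            "hybrid",
        )
        assert rank(sv, inst["labels"]) == rank(sv, inst["labels"])


class TestPredictTwoStep:
    def setup_method(self):
        self.train = matrix({"d1": {"C1"}, "d2": {"C2"}}, ["C1", "C2"])

    def test_direct_takes_precedence_over_hybrid(self):
        cc = InteractionTable()
        cc.add("q", "d1", 1.0)
        # hybrid evidence toward C2 exists but must be ignored
        cc.add("q", "x", 9.0)
        cc.add("d2", "x", 9.0)
        pc = ProteinChemicalTable()
        pred = predict_two_step("q", self.train, cc, pc)
        assert pred.method == "direct"
        assert pred.items[0][1] == "C1"

    def test_hybrid_fallback_when_direct_is_trivial(self):
        cc = InteractionTable()
        cc.add("q", "x", 2.0)   # x is not a training drug
        cc.add("d2", "x", 4.0)
        pc = ProteinChemicalTable()
        pred = predict_two_step("q", self.train, cc, pc)
        assert pred.method == "hybrid"
        assert pred.items[0][1] == "C2"

    def test_no_evidence_gives_empty_hybrid_tagged_prediction(self):
        pred = predict_two_step("q", self.train, InteractionTable(), ProteinChemicalTable())
        assert pred.items == []
        assert pred.method == "hybrid"

    def test_training_order_never_changes_scores(self, rng):
        inst = random_instance(rng)
        effects = inst["effects"]
        perm = [inst["drugs"][i] for i in rng.permutation(len(inst["drugs"]))]
        shuffled = matrix({d: inst["label_map"][d] for d in perm}, effects)
        for q in inst["drugs"][:3]:
            a = predict_two_step(q, inst["labels"], inst["cc"], inst["pc"])
            b = predict_two_step(q, shuffled, inst["cc"], inst["pc"])
            assert a.items == b.items

    def test_true_effects_rank_above_random_on_planted_fixture(self, default_fixture):
        """Mean rank of true side effects beats a random catalog permutation."""
        fx = default_fixture
        m = fx.labels.n_effects
        true_ranks, rand_ranks = [], []
        rng = np.random.default_rng(99)
        for d in fx.labels.drugs:
            pred = predict_two_step(d, fx.labels, fx.cc, fx.pc)
            pos = {e: r for r, e, _ in pred.items}
            for e in fx.labels.effects_of(d):
                true_ranks.append(pos.get(e, m + 1))
            for _ in range(50):  # Monte-Carlo random ranking baseline
                perm = rng.permutation(m)
                for i, e in enumerate(fx.labels.effects):
                    if e in fx.labels.effects_of(d):
                        rand_ranks.append(perm[i] + 1)
        mean_true = np.mean(true_ranks)
        rand = np.array(rand_ranks, dtype=float)
        # 95% lower confidence bound on the random mean rank
        lower = rand.mean() - 1.96 * rand.std(ddof=1) / np.sqrt(len(rand))
        assert mean_true < lower
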