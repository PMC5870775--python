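"""Sign propagation, scoring, significance and ranking."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from netcausal import (
    Hypothesis,
    Signature,
    SignedEdge,
    build_ccg,
    enrichment_significance,
    map_signature,
    oracle_predict,
    predict_regulation,
    rank_hypotheses,
    ranking_table,
    score_hypothesis,
    score_significance,
)

from conftest import mapped, random_observations, random_small_ccg


def exhaustive_p_value(pred_values: list[int], obs_values: list[int]) -> float:
    """Null p-value by enumerating every assignment of observations to genes."""
    observed = sum(p * o for p, o in zip(pred_values, obs_values))
    hits = total = 0
    for perm in itertools.permutations(obs_values):
        total += 1
        if sum(p * o for p, o in zip(pred_values, perm)) >= observed:
            hits += 1
    return hits / total


class TestPredictRegulation:
    def test_signed_chain_at_depth_two(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 2)
        assert dict(pred.predictions) == {"A": +1, "B": +1, "C": -1}

    def test_contradictory_edges_force_ambiguity(self):
        ccg = build_ccg([SignedEdge("A", +1, "B"), SignedEdge("A", -1, "B")])
        pred = predict_regulation(ccg, Hypothesis("A", +1), 1)
        assert dict(pred.predictions) == {"A": +1, "B": 0}

    def test_depth_limit_excludes_distant_nodes(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 1)
        assert dict(pred.predictions) == {"A": +1, "B": +1}

    def test_negative_hypothesis_flips_all_predictions(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", -1), 2)
        assert dict(pred.predictions) == {"A": -1, "B": -1, "C": +1}

    def test_unknown_node_raises(self, chain_ccg):
        with pytest.raises(KeyError, match="Nope"):
            predict_regulation(chain_ccg, Hypothesis("Nope", +1), 1)

    def test_negative_feedback_makes_start_ambiguous(self):
        # A -> B -| A: the opposite copy of A is reachable in 2 steps
        ccg = build_ccg([SignedEdge("A", +1, "B"), SignedEdge("B", -1, "A")])
        pred = predict_regulation(ccg, Hypothesis("A", +1), 2)
        assert pred.predictions["A"] == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_walk_enumeration_oracle(self, seed):
        ccg = random_small_ccg(seed)
        rng = random.Random(seed)
        delta = rng.randint(1, 4)
        for node in sorted(ccg.entities):
            for sign in (+1, -1):
                hyp = Hypothesis(node, sign)
                assert dict(predict_regulation(ccg, hyp, delta).predictions) == dict(
                    oracle_predict(ccg, hyp, delta).predictions
                )

    @pytest.mark.parametrize("seed", range(15))
    def test_monotone_in_delta(self, seed):
        """Growing the horizon only adds entities or degrades signs to ambiguity."""
        ccg = random_small_ccg(seed)
        if not ccg.entities:
            return
        node = sorted(ccg.entities)[0]
        previous = None
        for delta in (1, 2, 3, 4):
            current = predict_regulation(ccg, Hypothesis(node, +1), delta).predictions
            if previous is not None:
                assert set(previous) <= set(current)
                for entity, value in previous.items():
                    assert current[entity] in ({value, 0} if value != 0 else {0})
            previous = current


class TestScoreHypothesis:
    def test_perfect_agreement(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 2)
        msig = mapped(chain_ccg, {"B": +1, "C": -1})
        assert tuple(score_hypothesis(pred, msig)) == (2, 2, 0, 0)

    def test_single_contradiction(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 1)
        msig = mapped(chain_ccg, {"B": -1})
        assert tuple(score_hypothesis(pred, msig)) == (-1, 0, 1, 0)

    def test_ambiguous_gene_contributes_nothing(self):
        ccg = build_ccg([SignedEdge("A", +1, "B"), SignedEdge("A", -1, "B")])
        pred = predict_regulation(ccg, Hypothesis("A", +1), 1)
        msig = mapped(ccg, {"B": +1})
        score, correct, incorrect, ambiguous = score_hypothesis(pred, msig)
        assert (score, ambiguous) == (0, 1)

    def test_zero_observations_and_unpredicted_genes_ignored(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 1)
        msig = mapped(chain_ccg, {"B": 0, "C": +1})  # C not predicted at delta 1
        assert tuple(score_hypothesis(pred, msig)) == (0, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_antisymmetry_under_hypothesis_sign_flip(self, seed):
        ccg = random_small_ccg(seed)
        msig = random_observations(ccg, seed + 1, n_genes=8)
        for node in sorted(ccg.entities):
            up = score_hypothesis(predict_regulation(ccg, Hypothesis(node, +1), 3), msig)
            down = score_hypothesis(predict_regulation(ccg, Hypothesis(node, -1), 3), msig)
            assert down.score == -up.score
            assert (down.correct, down.incorrect) == (up.incorrect, up.correct)
            assert down.ambiguous == up.ambiguous


class TestScoreSignificance:
    def test_single_gene_degenerate_null(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 1)
        msig = mapped(chain_ccg, {"B": +1})
        assert score_significance(pred, msig, method="exact") == 1.0

    def test_two_gene_half(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 2)
        msig = mapped(chain_ccg, {"B": +1, "C": -1})
        assert score_significance(pred, msig, method="exact") == 0.5

    def test_no_predictions_gives_one(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("C", +1), 1)  # C has no targets
        msig = mapped(chain_ccg, {"A": +1, "B": -1})
        assert score_significance(pred, msig, method="exact") == 1.0

    def test_empty_signature_gives_one(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 1)
        msig = mapped(chain_ccg, {})
        assert score_significance(pred, msig, method="exact") == 1.0

    def test_montecarlo_requires_seed(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 2)
        msig = mapped(chain_ccg, {"B": +1, "C": -1})
        with pytest.raises(ValueError, match="seed"):
            score_significance(pred, msig, method="montecarlo")

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_equals_exhaustive_permutation(self, seed):
        ccg = random_small_ccg(seed)
        msig = random_observations(ccg, seed + 100, n_genes=7)
        if not msig.mapped:
            return
        node = sorted(ccg.entities)[seed % len(ccg.entities)]
        pred = predict_regulation(ccg, Hypothesis(node, +1), 2)
        genes = sorted(msig.mapped)
        pred_values = [pred.predictions.get(g) or 0 for g in genes]
        obs_values = [msig.mapped[g] for g in genes]
        exact = score_significance(pred, msig, method="exact")
        assert exact == pytest.approx(exhaustive_p_value(pred_values, obs_values), abs=1e-12)

    def test_montecarlo_converges_to_exact(self):
        ccg = random_small_ccg(7)
        msig = random_observations(ccg, 8, n_genes=8)
        node = sorted(ccg.entities)[0]
        pred = predict_regulation(ccg, Hypothesis(node, +1), 3)
        n_perm = 10_000
        exact = score_significance(pred, msig, method="exact")
        mc = score_significance(pred, msig, method="montecarlo", n_perm=n_perm, seed=42)
        band = 3 * math.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
        assert abs(mc - exact) <= band


class TestEnrichmentSignificance:
    def test_zero_predicted_degenerate(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("C", +1), 1)
        msig = mapped(chain_ccg, {"A": +1, "B": -1})
        assert enrichment_significance(pred, msig) == 1.0

    def test_saturated_margins(self, diamond_ccg):
        pred = predict_regulation(diamond_ccg, Hypothesis("A", +1), 2)
        msig = mapped(diamond_ccg, {"A": +1, "B": +1, "C": +1, "D": +1})
        assert enrichment_significance(pred, msig) == pytest.approx(1.0)

    def test_two_of_two_in_universe_of_four(self, diamond_ccg):
        # universe 4, 2 predicted, 2 observed-nonzero, overlap 2 -> C(2,2)/C(4,2)
        pred = predict_regulation(diamond_ccg, Hypothesis("B", +1), 1)  # predicts B, D
        msig = mapped(diamond_ccg, {"A": 0, "B": +1, "C": 0, "D": +1})
        assert enrichment_significance(pred, msig) == pytest.approx(1 / 6)

    def test_universe_smaller_than_signature_rejected(self, chain_ccg):
        pred = predict_regulation(chain_ccg, Hypothesis("A", +1), 1)
        msig = mapped(chain_ccg, {"A": +1, "B": -1})
        with pytest.raises(ValueError):
            enrichment_significance(pred, msig, universe_size=1)


class TestRankHypotheses:
    def test_chain_top_row_is_true_regulator(self):
        ccg = build_ccg([SignedEdge("A", +1, "B")])
        msig = mapped(ccg, {"B": +1})
        results = rank_hypotheses(ccg, msig, 1)
        assert [str(r.hypothesis) for r in results] == ["A+", "B+", "A-", "B-"]
        assert results[0].score == 1
        assert [r.rank for r in results] == [1, 2, 3, 4]

    def test_row_count_is_twice_entities(self, diamond_ccg):
        msig = mapped(diamond_ccg, {"D": +1})
        assert len(rank_hypotheses(diamond_ccg, msig, 2)) == 2 * diamond_ccg.n_entities

    def test_empty_signature_scores_zero_ordered_by_name(self, diamond_ccg):
        results = rank_hypotheses(diamond_ccg, mapped(diamond_ccg, {}), 2)
        assert all(r.score == 0 and r.p_value == 1.0 for r in results)
        names = [r.hypothesis.node for r in results]
        assert names == sorted(names)

    def test_nodes_filter_restricts_rows(self, diamond_ccg):
        msig = mapped(diamond_ccg, {"D": +1})
        results = rank_hypotheses(diamond_ccg, msig, 2, nodes=["A", "B"])
        assert {r.hypothesis.node for r in results} == {"A", "B"}
        with pytest.raises(KeyError):
            rank_hypotheses(diamond_ccg, msig, 2, nodes=["Zed"])

    @pytest.mark.parametrize("seed", range(10))
    def test_score_antisymmetry_across_full_table(self, seed):
        ccg = random_small_ccg(seed)
        msig = random_observations(ccg, seed + 3, n_genes=6)
        results = rank_hypotheses(ccg, msig, 2, significance="none")
        by_hyp = {(r.hypothesis.node, r.hypothesis.sign): r for r in results}
        for node in ccg.entities:
            assert by_hyp[(node, -1)].score == -by_hyp[(node, +1)].score
            assert by_hyp[(node, -1)].ambiguous == by_hyp[(node, +1)].ambiguous

    def test_montecarlo_ranking_is_order_independent(self):
        """Per-hypothesis seeds are derived from identity, not evaluation order."""
        ccg = random_small_ccg(3)
        msig = random_observations(ccg, 4, n_genes=6)
        full = rank_hypotheses(ccg, msig, 2, significance="montecarlo", n_perm=200, seed=9)
        some_node = sorted(ccg.entities)[-1]
        alone = rank_hypotheses(
            ccg, msig, 2, significance="montecarlo", n_perm=200, seed=9, nodes=[some_node]
        )
        full_p = {
            (r.hypothesis.node, r.hypothesis.sign): r.p_value
            for r in full
            if r.hypothesis.node == some_node
        }
        for r in alone:
            assert r.p_value == full_p[(r.hypothesis.node, r.hypothesis.sign)]

    def test_ranking_table_columns(self, chain_ccg):
        msig = mapped(chain_ccg, {"B": +1})
        frame = ranking_table(rank_hypotheses(chain_ccg, msig, 1))
        assert list(frame.columns) == [
            "NodeName",
            "Regulation",
            "Score",
            "Correct",
            "Incorrect",
            "Ambiguous",
            "PValue",
            "EnrichmentPValue",
            "Rank",
        ]
        assert list(frame["Rank"]) == list(range(1, len(frame) + 1))
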