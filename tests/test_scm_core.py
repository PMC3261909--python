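from dataclasses import replace

import numpy as np
import pytest

from textscm.corpus_io import TrainingPartition
from textscm.errors import EmptyPositiveSetError
from textscm.experiments import random_partition
from textscm.feature_mining import Feature, mine_common_sets, support_counts
from textscm.scm_core import (RuleModel, ScoreParams, predict, predict_many,
                              score, train_mscm)

from conftest import rec


def slow_greedy(partition, candidates, params, q):
    """Exhaustive per-step argmax reference for the greedy cover."""
    active_p = {r.record_id for r in partition.P}
    active_u = {r.record_id for r in partition.U}
    chosen, out = set(), []
    while active_p and len(out) < params.M:
        best = None
        for f in candidates:
            if f.canonical_key in chosen:
                continue
            c = support_counts(f, partition, (active_p, None, active_u))
            s = score(c, params.p, q)
            key = (-s, len(f.stems), -c[0], f.canonical_key)
            if best is None or key < best[0]:
                best = (key, f, c, s)
        if best is None or best[3] <= params.min_score:
            break
        _, f, c, s = best
        chosen.add(f.canonical_key)
        out.append((f.canonical_key, s))
        active_p -= {r.record_id for r in partition.P
                     if f.stems <= r.tokens}
        active_u -= {r.record_id for r in partition.U
                     if f.stems <= r.tokens}
    return out


@pytest.mark.parametrize("counts,p,q,expected", [
    ((5, 2, 0), 1.0, 0.0, 3.0),
    ((4, 4, 0), 0.5, 0.0, 2.0),
    ((6, 1, 4), 1.0, 0.5, 3.0),
])
def test_penalized_score(counts, p, q, expected):
    assert score(counts, p, q) == expected


class TestTrainMscm:
    def test_single_rule_covers_positives(self, tiny_partition):
        cands = [Feature(frozenset({"angiogram"}))]
        model = train_mscm(tiny_partition, cands, ScoreParams(), 0.0)
        assert [r.canonical_key for r in model.rules] == ["angiogram"]
        assert model.trace[0]["score"] == 3.0

    def test_m_limit_stops_early(self):
        P = (rec("p0", "aa x", "positive"), rec("p1", "aa y", "positive"),
             rec("p2", "bb x", "positive"), rec("p3", "bb y", "positive"))
        part = TrainingPartition(P=P, U=(), N=())
        cands = [Feature(frozenset({"aa"})), Feature(frozenset({"bb"}))]
        model = train_mscm(part, cands, ScoreParams(M=1), 0.0)
        assert len(model.rules) == 1

    def test_nonpositive_scores_give_empty_model(self):
        P = (rec("p0", "aa", "positive"), rec("p1", "aa", "positive"))
        N = tuple(rec(f"n{i}", "aa", "negative") for i in range(5))
        part = TrainingPartition(P=P, U=(), N=N)
        model = train_mscm(part, [Feature(frozenset({"aa"}))],
                           ScoreParams(), 0.0)
        assert model.rules == ()

    def test_empty_positive_set_refused(self):
        part = TrainingPartition(P=(), U=(), N=(rec("n0", "x", "negative"),))
        with pytest.raises(EmptyPositiveSetError):
            train_mscm(part, [Feature(frozenset({"x"}))], ScoreParams(), 0.0)

    def test_empty_candidates_warn(self, tiny_partition):
        with pytest.warns(UserWarning, match="no candidate"):
            model = train_mscm(tiny_partition, [], ScoreParams(), 0.0)
        assert model.rules == ()

    def test_greedy_step_argmax_oracle(self):
        """Every selected feature attains the exhaustive per-step argmax."""
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(40):
            part = random_partition(rng, n_pos=7, n_neg=8, n_unl=7,
                                    vocab_size=11)
            cands = mine_common_sets([r.tokens for r in part.P], None,
                                     pair_intersection_limit=40)
            if not cands or len(cands) > 200:
                continue
            q = float(rng.choice([0.0, 0.2, 0.5, 1.0]))
            params = ScoreParams(p=float(rng.choice([0.5, 1.0])))
            got = train_mscm(part, cands, params, q)
            want = slow_greedy(part, cands, params, q)
            assert [(r.canonical_key, t["score"])
                    for r, t in zip(got.rules, got.trace)] == want
            checked += 1
        assert checked >= 30

    def test_covered_positives_strictly_decrease(self, rng):
        part = random_partition(rng, n_pos=10, n_neg=6, n_unl=6)
        cands = mine_common_sets([r.tokens for r in part.P], 3,
                                 pair_intersection_limit=40)
        if not cands:
            pytest.skip("no shared stems in this draw")
        model = train_mscm(part, cands, ScoreParams(), 0.2)
        assert all(t["n_pos"] >= 1 for t in model.trace)

    def test_gold_labels_never_consulted(self, tiny_partition):
        flipped = TrainingPartition(
            P=tuple(replace(r, gold=True) for r in tiny_partition.P),
            U=tuple(replace(r, gold=False) for r in tiny_partition.U),
            N=tuple(replace(r, gold=True) for r in tiny_partition.N),
        )
        cands = [Feature(frozenset({"angiogram"}))]
        a = train_mscm(tiny_partition, cands, ScoreParams(), 0.0)
        b = train_mscm(flipped, cands, ScoreParams(), 0.0)
        assert a.to_json() == b.to_json()

    def test_determinism_byte_identical(self, rng):
        part = random_partition(rng, n_pos=8, n_neg=8, n_unl=8)
        cands = mine_common_sets([r.tokens for r in part.P], 3,
                                 pair_intersection_limit=40)
        m1 = train_mscm(part, cands, ScoreParams(), 0.3)
        m2 = train_mscm(part, cands, ScoreParams(), 0.3)
        assert m1.to_json() == m2.to_json()


class TestPredict:
    def test_any_rule_fires(self):
        model = RuleModel(rules=(Feature(frozenset({"vessel"})),
                                 Feature(frozenset({"stent"}))),
                          params=ScoreParams())
        assert predict(model, rec("r", "stent insert"))

    def test_conjunctive_rule_must_be_contained(self):
        model = RuleModel(rules=(Feature(frozenset({"ovari", "cancer"})),),
                          params=ScoreParams())
        assert not predict(model, rec("r", "ovari cyst"))

    def test_empty_model_predicts_negative(self):
        model = RuleModel(rules=(), params=ScoreParams())
        assert predict_many(model, [rec("r", "anything")]) == {"r": False}


def test_model_json_round_trip(tiny_partition):
    cands = [Feature(frozenset({"angiogram"}))]
    model = train_mscm(tiny_partition, cands, ScoreParams(), 0.25)
    again = RuleModel.from_json(model.to_json())
    assert again.to_json() == model.to_json()
    assert again.params == model.params
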