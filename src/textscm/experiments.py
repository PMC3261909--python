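"""Validation experiments and naive reference implementations.

These routines exist to *check* the learner rather than to run it: a
brute-force power-set miner, exhaustive greedy replay, random small
fixtures, and the study-shaped synthetic experiments (rule recovery on
noise-free corpora; the semi-supervised recall gain under 60% code-label
purity). The test suite and the acceptance script both drive them.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import chain, combinations
from typing import Sequence

import numpy as np

from .corpus_io import (ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_UNLABELLED,
                        TextRecord, TrainingPartition)
from .evaluation import evaluate_labels
from .feature_mining import Feature, mine_common_sets
from .s3cm import train_s3cm
from .scm_core import ScoreParams, predict_many, train_mscm
from .synthetic_corpus import CorpusConfig, PlantedRule, generate, table1_fixture


# ---------------------------------------------------------------------------
# naive references
# ---------------------------------------------------------------------------

def brute_force_common_sets(texts: Sequence[frozenset[str]],
                            s_cap: int | None = None) -> list[Feature]:
    """Power-set reference for the pairwise miner.

    Enumerates every non-empty subset of the union vocabulary and keeps
    those contained in at least two texts. Exponential in vocabulary size;
    usable only on tiny instances.
    """
    vocab = sorted(set(chain.from_iterable(texts)))
    top = len(vocab) if s_cap is None else min(s_cap, len(vocab))
    out = []
    for k in range(1, top + 1):
        for combo in combinations(vocab, k):
            cand = frozenset(combo)
            support = sum(1 for t in texts if cand <= t)
            if support >= 2:
                out.append(Feature(cand))
    out.sort(key=lambda f: (len(f.stems), f.canonical_key))
    return out


# ---------------------------------------------------------------------------
# random small fixtures
# ---------------------------------------------------------------------------

def random_token_sets(rng: np.random.Generator, n_texts: int,
                      vocab_size: int, mean_tokens: float = 4.0
                      ) -> list[frozenset[str]]:
    vocab = [f"w{i}" for i in range(vocab_size)]
    out = []
    for _ in range(n_texts):
        k = min(vocab_size, max(1, int(rng.poisson(mean_tokens))))
        idx = rng.choice(vocab_size, size=k, replace=False)
        out.append(frozenset(vocab[i] for i in idx))
    return out


def random_partition(rng: np.random.Generator, *, n_pos: int = 6,
                     n_neg: int = 8, n_unl: int = 6,
                     vocab_size: int = 12) -> TrainingPartition:
    """A small random partition for reduction and greedy-oracle checks."""
    def recs(prefix, role, sets):
        return tuple(
            TextRecord(record_id=f"{prefix}{i}", raw_text=" ".join(sorted(s)),
                       tokens=s, role=role)
            for i, s in enumerate(sets)
        )

    return TrainingPartition(
        P=recs("p", ROLE_POSITIVE,
               random_token_sets(rng, n_pos, vocab_size)),
        U=recs("u", ROLE_UNLABELLED,
               random_token_sets(rng, n_unl, vocab_size)),
        N=recs("n", ROLE_NEGATIVE,
               random_token_sets(rng, n_neg, vocab_size)),
    )


def separable_loocv_partition() -> TrainingPartition:
    """Hand-built perfectly separable fixture for leave-one-out.

    Every positive text contains the planted combination {"ovari",
    "cancer"}, which at least two other positives share and no negative
    contains, so each held-out positive is recovered and the error is 0.
    """
    planted = frozenset({"ovari", "cancer"})
    fillers = ["visit", "note", "letter", "review"]
    P = tuple(
        TextRecord(record_id=f"p{i}",
                   raw_text=f"{f} ovari cancer",
                   tokens=planted | {f},
                   role=ROLE_POSITIVE, gold=True)
        for i, f in enumerate(fillers)
    )
    U = tuple(
        TextRecord(record_id=f"u{i}", raw_text=t,
                   tokens=frozenset(t.split()), role=ROLE_UNLABELLED)
        for i, t in enumerate(["routine bloods", "knee pain review"])
    )
    N = tuple(
        TextRecord(record_id=f"n{i}", raw_text=t,
                   tokens=frozenset(t.split()), role=ROLE_NEGATIVE)
        for i, t in enumerate(
            ["asthma review visit", "blood pressure note", "flu jab letter"]
        )
    )
    return TrainingPartition(P=P, U=U, N=N)


# ---------------------------------------------------------------------------
# study-shaped experiments
# ---------------------------------------------------------------------------

def recovery_config(seed: int) -> CorpusConfig:
    """Noise-free corpus: pure code labels, no latent rules, every rule
    prevalent enough to be supported by at least five positive texts."""
    rules = tuple(
        PlantedRule(r.stems, 1.0, latent=False)
        for r in (CorpusConfig().planted_rules)
    )
    return CorpusConfig(
        seed=seed,
        planted_rules=rules,
        n_coded_positive=240,
        code_label_purity=1.0,
        n_unlabelled=300,
        unlabelled_positive_fraction=0.10,
        n_negative=800,
        n_case_patients=100,
        n_control_patients=100,
    )


def rule_recovery_run(seed: int, params: ScoreParams | None = None) -> bool:
    """True iff every planted rule is covered by the learned rule list:
    some learned rule is a subset of the planted combination and matches
    only gold-positive records."""
    params = params or ScoreParams()
    config = recovery_config(seed)
    records, manifest = generate(config)
    partition = TrainingPartition(
        P=tuple(r for r in records if r.role == ROLE_POSITIVE),
        U=tuple(r for r in records if r.role == ROLE_UNLABELLED),
        N=tuple(r for r in records if r.role == ROLE_NEGATIVE),
    )
    model, _, _ = train_s3cm(partition, params, seed=seed)
    gold_pos = {r.record_id for r in records if r.gold}
    clean_rules = []
    for rule in model.rules:
        matched = {r.record_id for r in records if rule.stems <= r.tokens}
        if matched and matched <= gold_pos:
            clean_rules.append(rule)
    planted = [frozenset(r.stems) for r in config.planted_rules]
    return all(
        any(rule.stems <= p for rule in clean_rules) for p in planted
    )


def rule_recovery_rate(n_seeds: int = 10, base_seed: int = 0,
                       params: ScoreParams | None = None) -> float:
    hits = sum(
        rule_recovery_run(base_seed + i, params) for i in range(n_seeds)
    )
    return hits / n_seeds


def gain_run(seed: int, params: ScoreParams | None = None
             ) -> tuple[float, float]:
    """(semi-supervised recall, supervised recall) on one noisy corpus.

    The corpus has the study's training-set shape (|P| = 199 at 60%
    purity, |U| = 1673, |N| = 3539). Recall is measured on the unlabelled
    set against gold. The supervised baseline is the same learner with no
    bootstrap iterations and no unlabelled penalty, predicting on U.
    """
    params = params or ScoreParams()
    partition, _ = table1_fixture("angiogram", seed=seed)
    gold = {r.record_id: bool(r.gold) for r in partition.U}

    _, _, labels = train_s3cm(partition, params, seed=seed)
    semi = evaluate_labels(labels, gold)

    sup_params = replace(params, T=0, q0=0.0)
    candidates = mine_common_sets(
        [r.tokens for r in partition.P], params.s_cap,
        pair_intersection_limit=params.pair_intersection_limit)
    sup_model = train_mscm(partition, candidates, sup_params, q_effective=0.0)
    sup = evaluate_labels(predict_many(sup_model, partition.U), gold)
    return float(semi.recall), float(sup.recall)


def semi_supervised_gain(n_seeds: int = 10, base_seed: int = 0,
                         params: ScoreParams | None = None) -> dict:
    """Mean gold recall of the bootstrap learner vs the supervised one."""
    semi, sup = [], []
    for i in range(n_seeds):
        a, b = gain_run(base_seed + i, params)
        semi.append(a)
        sup.append(b)
    return {
        "semi_recall_mean": float(np.mean(semi)),
        "supervised_recall_mean": float(np.mean(sup)),
        "per_seed_semi": semi,
        "per_seed_supervised": sup,
        "n_seeds": n_seeds,
    }
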