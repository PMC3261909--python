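"""Semi-supervised bootstrap training of the Set Covering Machine.

Each bootstrap iteration (1) mines common word combinations over the
current positive pool — the labelled positives plus all pseudo-positives
promoted so far — and appends any new ones to a cumulative candidate set;
(2) escalates the unlabelled penalty q with the size of the pseudo-
positive set; (3) fits a modified SCM on the updated partition; and
(4) promotes every remaining unlabelled record the fitted model classifies
positive into the pseudo-positive pool. Promotions are irrevocable. The
escalating penalty counteracts the growing risk of false promotions: as
pseudo-positives accumulate, unlabelled records become easier to cover,
so covering the ones that still look unlabelled must cost more.

The whole procedure is deterministic; a seed is accepted for interface
symmetry with the corpus generator and recorded in the state for audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .corpus_io import TrainingPartition
from .feature_mining import Feature, IncrementalMiner
from .scm_core import RuleModel, ScoreParams, _greedy_fit, build_match_table

logger = logging.getLogger(__name__)


def q_schedule(q0: float, q_growth: float, n_pseudo: int,
               n_labelled_pos: int) -> float:
    """Unlabelled-penalty weight for a given pseudo-positive pool size.

    Grows linearly with the pseudo-positive count, normalized by the
    number of labelled positives so the escalation is scale-free in corpus
    size:  q = q0 * (1 + q_growth * n_pseudo / n_labelled_pos).
    Equals q0 when no text has been promoted yet.
    """
    if n_labelled_pos < 1:
        raise ValueError("n_labelled_pos must be at least 1")
    return q0 * (1.0 + q_growth * n_pseudo / n_labelled_pos)


@dataclass(frozen=True)
class BootstrapState:
    """Audit trail of one semi-supervised training run."""

    iteration: int
    pseudo_positives: frozenset[str]
    candidate_pool: tuple[Feature, ...]
    q_current: float
    per_iteration_log: tuple[dict, ...] = field(default_factory=tuple)
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            "iteration": self.iteration,
            "pseudo_positives": sorted(self.pseudo_positives),
            "candidate_pool": [f.canonical_key for f in self.candidate_pool],
            "q_current": self.q_current,
            "per_iteration_log": list(self.per_iteration_log),
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "BootstrapState":
        obj = json.loads(payload)
        return cls(
            iteration=obj["iteration"],
            pseudo_positives=frozenset(obj["pseudo_positives"]),
            candidate_pool=tuple(Feature.from_key(k)
                                 for k in obj["candidate_pool"]),
            q_current=obj["q_current"],
            per_iteration_log=tuple(obj["per_iteration_log"]),
            seed=obj.get("seed", 0),
        )


def train_s3cm(partition: TrainingPartition, params: ScoreParams,
               seed: int = 0) -> tuple[RuleModel, BootstrapState, dict[str, bool]]:
    """Run T bootstrap iterations and label the unlabelled set.

    Returns the final iteration's model, the bootstrap state, and a label
    for every unlabelled record: positive iff it was promoted in some
    iteration or is classified positive by the final model. With ``T=0``
    this is a single supervised-style fit with q = q0 and no promotions.
    """
    part = partition.masked()
    records = part.records()
    pos_ids = frozenset(r.record_id for r in part.P)
    neg_ids = frozenset(r.record_id for r in part.N)
    unl_ids = frozenset(r.record_id for r in part.U)

    miner = IncrementalMiner(params.s_cap, params.pair_intersection_limit)
    pool: list[Feature] = list(miner.add_texts(r.tokens for r in part.P))
    match_table = build_match_table(pool, records)
    tokens_of = {r.record_id: r.tokens for r in part.U}

    pseudo: set[str] = set()
    log: list[dict] = []
    q_eff = params.q0
    model: RuleModel | None = None

    for t in range(1, params.T + 1):
        q_eff = q_schedule(params.q0, params.q_growth, len(pseudo), len(pos_ids))
        model = _greedy_fit(
            pool, match_table,
            pos_ids=pos_ids | pseudo, neg_ids=neg_ids,
            unl_ids=unl_ids - pseudo,
            params=params, q_effective=q_eff, provenance_iter=t,
        )
        remaining = unl_ids - pseudo
        promoted: set[str] = set()
        for rule in model.rules:
            promoted |= match_table[rule.canonical_key] & remaining
        pseudo |= promoted
        log.append({
            "iteration": t,
            "q_effective": q_eff,
            "pool_size": len(pool),
            "n_rules": len(model.rules),
            "n_promoted": len(promoted),
            "n_pseudo_total": len(pseudo),
        })
        logger.info("bootstrap iteration %d: q=%.3f pool=%d rules=%d "
                    "promoted=%d", t, q_eff, len(pool), len(model.rules),
                    len(promoted))
        if t < params.T and promoted:
            new_feats = miner.add_texts(tokens_of[rid] for rid in sorted(promoted))
            if new_feats:
                build_match_table(new_feats, records, match_table)
                pool.extend(new_feats)

    if model is None:  # T == 0: plain supervised-style fit, no promotions
        model = _greedy_fit(
            pool, match_table, pos_ids=pos_ids, neg_ids=neg_ids,
            unl_ids=unl_ids, params=params, q_effective=q_eff,
            provenance_iter=0,
        )

    labels: dict[str, bool] = {}
    for rid in unl_ids:
        if rid in pseudo:
            labels[rid] = True
        else:
            labels[rid] = any(
                rid in match_table[r.canonical_key] for r in model.rules
            )

    state = BootstrapState(
        iteration=params.T,
        pseudo_positives=frozenset(pseudo),
        candidate_pool=tuple(pool),
        q_current=q_eff,
        per_iteration_log=tuple(log),
        seed=seed,
    )
    return model, state, labels
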