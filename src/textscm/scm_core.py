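"""The (modified) Set Covering Machine: penalized scoring and greedy cover.

The learner greedily selects word-combination features to cover the
positive texts. A candidate h is scored

    score(h) = |P_h| - p * |N_h| - q * |U_h|

where P_h, N_h, U_h are the *active* positive, negative and unlabelled
records containing h, p weights the penalty for covering negatives and q
the penalty for covering unlabelled records (q = 0 recovers the fully
supervised objective). After a feature is accepted, the positive and
unlabelled records it covers are deactivated; negatives by default are
not, so every later candidate keeps paying its full negative penalty.
Learning stops when the positives are exhausted, the model reaches M
rules, or no candidate scores above ``min_score``.

The learned hypothesis is a disjunction of the selected features (each
feature itself a conjunction of stems): a record is classified positive
iff at least one selected word combination is contained in it.
"""

from __future__ import annotations

import heapq
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import TextRecord, TrainingPartition
from .errors import EmptyPositiveSetError
from .feature_mining import Feature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreParams:
    """Training parameters for the supervised and semi-supervised SCM.

    p          : weight of the negative-example penalty.
    q0         : base weight of the unlabelled-example penalty.
    q_growth   : linear growth coefficient of q in the pseudo-positive count.
    M          : maximum number of selected features per fit.
    T          : number of bootstrap iterations (0 = purely supervised fit).
    s_cap      : maximum feature size mined from text pairs (None = unbounded).
    min_score  : a feature is accepted only if its score strictly exceeds this.
    remove_matched_negatives : also deactivate covered negatives (off by
        default; removing them would progressively erase the penalty).
    """

    p: float = 1.0
    q0: float = 0.2
    q_growth: float = 1.0
    M: int = 50
    T: int = 4
    s_cap: int | None = 4
    min_score: float = 0.0
    remove_matched_negatives: bool = False
    pair_intersection_limit: int = 20

    def __post_init__(self) -> None:
        if self.p < 0 or self.q0 < 0 or self.q_growth < 0:
            raise ValueError("p, q0 and q_growth must be non-negative")
        if self.M < 1:
            raise ValueError("M must be at least 1")
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.s_cap is not None and self.s_cap < 1:
            raise ValueError("s_cap must be positive or None")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ScoreParams":
        return cls(**payload)


def score(counts: tuple[int, int, int], p: float, q: float) -> float:
    """Penalized cover score |P_h| - p*|N_h| - q*|U_h|."""
    n_pos, n_neg, n_unl = counts
    return n_pos - p * n_neg - q * n_unl


@dataclass(frozen=True)
class RuleModel:
    """An ordered list of selected features plus its training snapshot."""

    rules: tuple[Feature, ...]
    params: ScoreParams
    q_effective: float = 0.0
    trace: tuple[dict, ...] = field(default_factory=tuple)
    provenance: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        keys = [r.canonical_key for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("rules must be duplicate-free")

    def to_json(self) -> str:
        payload = {
            "rules": [r.canonical_key for r in self.rules],
            "params": self.params.to_dict(),
            "q_effective": self.q_effective,
            "trace": list(self.trace),
            "provenance": list(self.provenance),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "RuleModel":
        obj = json.loads(payload)
        return cls(
            rules=tuple(Feature.from_key(k) for k in obj["rules"]),
            params=ScoreParams.from_dict(obj["params"]),
            q_effective=obj.get("q_effective", 0.0),
            trace=tuple(obj.get("trace", ())),
            provenance=tuple(obj.get("provenance", ())),
        )


def predict(model: RuleModel, record: TextRecord) -> bool:
    """Positive iff any selected word combination is contained in the record."""
    return any(r.stems <= record.tokens for r in model.rules)


def predict_many(model: RuleModel, records: Iterable[TextRecord]) -> dict[str, bool]:
    return {r.record_id: predict(model, r) for r in records}


# ---------------------------------------------------------------------------
# internal fitting machinery (shared with the bootstrap loop)
# ---------------------------------------------------------------------------

_EMPTY: frozenset[str] = frozenset()


def build_match_table(candidates: Sequence[Feature],
                      records: Sequence[TextRecord],
                      table: dict[str, frozenset[str]] | None = None,
                      ) -> dict[str, frozenset[str]]:
    """record_ids matched by each candidate, via posting-list intersection.

    ``table`` lets callers accumulate matches across growing candidate
    pools without recomputation; the record collection must stay fixed.
    """
    postings: dict[str, set[str]] = {}
    needed = [f for f in candidates if table is None or f.canonical_key not in table]
    if table is None:
        table = {}
    if not needed:
        return table
    stems_needed = set().union(*(f.stems for f in needed))
    for rec in records:
        for stem in rec.tokens & stems_needed:
            postings.setdefault(stem, set()).add(rec.record_id)
    for f in needed:
        lists = sorted((postings.get(s, _EMPTY) for s in f.stems), key=len)
        acc = set(lists[0])
        for other in lists[1:]:
            acc &= other
            if not acc:
                break
        table[f.canonical_key] = frozenset(acc)
    return table


def _greedy_fit(candidates: Sequence[Feature],
                match_table: Mapping[str, frozenset[str]],
                pos_ids: frozenset[str], neg_ids: frozenset[str],
                unl_ids: frozenset[str], params: ScoreParams,
                q_effective: float, provenance_iter: int = 0) -> RuleModel:
    """Greedy cover over pre-computed match sets.

    Selection is exact at every step: per-candidate counts are maintained
    incrementally (deactivating a record touches only the candidates that
    match it), and updated candidates are re-pushed onto a heap with a
    version stamp so stale entries are skipped. Note scores are not
    monotone across steps — covering unlabelled records shrinks the
    q-penalty of the features they share, which is precisely how promoted
    texts make new features attractive. Tie-break is total: higher score,
    then fewer stems, then more covered positives, then lexicographic key.
    """
    if not pos_ids:
        raise EmptyPositiveSetError("cannot train with an empty positive set")
    candidates = list(candidates)
    if not candidates:
        warnings.warn("no candidate features; returning an empty model",
                      stacklevel=3)
        return RuleModel(rules=(), params=params, q_effective=q_effective)

    n_cand = len(candidates)
    mp_list: list[frozenset[str]] = []
    mn_list: list[frozenset[str]] = []
    mu_list: list[frozenset[str]] = []
    n_p = [0] * n_cand
    n_n = [0] * n_cand
    n_u = [0] * n_cand
    by_record: dict[str, list[tuple[int, int]]] = {}  # rid -> [(idx, slot)]
    track_negatives = params.remove_matched_negatives
    for idx, f in enumerate(candidates):
        m = match_table[f.canonical_key]
        mp = m & pos_ids
        mn = m & neg_ids
        mu = m & unl_ids
        mp_list.append(mp)
        mn_list.append(mn)
        mu_list.append(mu)
        n_p[idx], n_n[idx], n_u[idx] = len(mp), len(mn), len(mu)
        for rid in mp:
            by_record.setdefault(rid, []).append((idx, 0))
        for rid in mu:
            by_record.setdefault(rid, []).append((idx, 2))
        if track_negatives:
            for rid in mn:
                by_record.setdefault(rid, []).append((idx, 1))

    version = [0] * n_cand

    def entry(idx: int) -> tuple:
        s = n_p[idx] - params.p * n_n[idx] - q_effective * n_u[idx]
        f = candidates[idx]
        return (-s, len(f.stems), -n_p[idx], f.canonical_key, idx, version[idx])

    heap = [entry(i) for i in range(n_cand)]
    heapq.heapify(heap)

    active_p = set(pos_ids)
    active_u = set(unl_ids)
    active_n = set(neg_ids)
    rules: list[Feature] = []
    trace: list[dict] = []
    chosen: set[int] = set()

    while active_p and len(rules) < params.M and heap:
        neg_s, _, _, key, idx, ver = heapq.heappop(heap)
        if ver != version[idx] or idx in chosen:
            continue
        s = -neg_s
        if s <= params.min_score:
            break
        chosen.add(idx)
        rules.append(candidates[idx])
        trace.append({"score": s, "n_pos": n_p[idx], "n_neg": n_n[idx],
                      "n_unl": n_u[idx]})
        deactivated = [(rid, 0) for rid in mp_list[idx] & active_p]
        deactivated += [(rid, 2) for rid in mu_list[idx] & active_u]
        if track_negatives:
            deactivated += [(rid, 1) for rid in mn_list[idx] & active_n]
        dirty: set[int] = set()
        for rid, slot in deactivated:
            if slot == 0:
                active_p.discard(rid)
            elif slot == 2:
                active_u.discard(rid)
            else:
                active_n.discard(rid)
            for cidx, cslot in by_record.get(rid, ()):
                if cslot != slot or cidx in chosen:
                    continue
                if cslot == 0:
                    n_p[cidx] -= 1
                elif cslot == 2:
                    n_u[cidx] -= 1
                else:
                    n_n[cidx] -= 1
                dirty.add(cidx)
        for cidx in dirty:
            version[cidx] += 1
            heapq.heappush(heap, entry(cidx))
        logger.debug("selected %s score=%.3f", key, s)

    return RuleModel(
        rules=tuple(rules),
        params=params,
        q_effective=q_effective,
        trace=tuple(trace),
        provenance=tuple(provenance_iter for _ in rules),
    )


def train_mscm(partition: TrainingPartition, candidates: Sequence[Feature],
               params: ScoreParams, q_effective: float = 0.0) -> RuleModel:
    """Fit one modified SCM on a fixed partition and candidate pool.

    Candidates are expected to have been mined from the positive texts.
    Manual-review labels are hidden before fitting; training sees only
    tokens and set membership.
    """
    if q_effective < 0:
        raise ValueError("q_effective must be non-negative")
    part = partition.masked()
    # deduplicate candidates by canonical key, preserving first occurrence
    seen: set[str] = set()
    cands: list[Feature] = []
    for f in candidates:
        if f.canonical_key not in seen:
            seen.add(f.canonical_key)
            cands.append(f)
    table = build_match_table(cands, part.records())
    return _greedy_fit(
        cands, table,
        pos_ids=frozenset(r.record_id for r in part.P),
        neg_ids=frozenset(r.record_id for r in part.N),
        unl_ids=frozenset(r.record_id for r in part.U),
        params=params, q_effective=q_effective,
    )
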