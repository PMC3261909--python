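"""Candidate feature generation: word combinations shared by positive texts.

A feature is a non-empty, unordered set of word stems acting as a
conjunctive rule: a record matches the feature iff it contains every stem.
Candidates are the word combinations shared by at least two positive
texts, found by intersecting text pairs and enumerating the subsets of
each intersection. Explicit feature vectors over all word subsets are
never materialised; containment queries stand in for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .corpus_io import TextRecord, TrainingPartition
from .errors import IntersectionLimitError


@dataclass(frozen=True)
class Feature:
    """A word-stem combination used as a conjunctive matching rule."""

    stems: frozenset[str]

    def __post_init__(self) -> None:
        if not self.stems:
            raise ValueError("a feature needs at least one stem")

    @property
    def canonical_key(self) -> str:
        """Deterministic serialization: sorted stems joined by '+'."""
        return "+".join(sorted(self.stems))

    @classmethod
    def from_key(cls, key: str) -> "Feature":
        return cls(frozenset(key.split("+")))


def matches(feature: Feature, record: TextRecord) -> bool:
    """True iff the record's token set contains every stem of the feature."""
    return feature.stems <= record.tokens


class IncrementalMiner:
    """Pairwise common-word-set miner that accepts texts in batches.

    Each added text is intersected with every text seen so far; the
    non-empty subsets of each intersection (up to ``s_cap`` stems) become
    candidate features. Re-feeding intersections already expanded is
    skipped, so growing the positive pool across bootstrap iterations costs
    only the new-by-old pairs.
    """

    def __init__(self, s_cap: int | None = 4,
                 pair_intersection_limit: int = 20) -> None:
        if s_cap is not None and s_cap < 1:
            raise ValueError("s_cap must be a positive integer or None")
        self.s_cap = s_cap
        self.pair_intersection_limit = pair_intersection_limit
        self._texts: list[frozenset[str]] = []
        self._found: set[frozenset[str]] = set()
        self._done: set[frozenset[str]] = set()

    def _expand(self, inter: frozenset[str], new: set[frozenset[str]]) -> None:
        if not inter or inter in self._done:
            return
        self._done.add(inter)
        if self.s_cap is None and len(inter) > self.pair_intersection_limit:
            raise IntersectionLimitError(
                f"pairwise intersection of {len(inter)} stems exceeds the "
                f"limit of {self.pair_intersection_limit}; set s_cap to bound "
                "subset enumeration"
            )
        top = len(inter) if self.s_cap is None else min(self.s_cap, len(inter))
        members = sorted(inter)
        for k in range(1, top + 1):
            for combo in combinations(members, k):
                fs = frozenset(combo)
                if fs not in self._found:
                    self._found.add(fs)
                    new.add(fs)

    def add_texts(self, texts: Iterable[frozenset[str]]) -> list[Feature]:
        """Add a batch of token sets; return the newly discovered features,
        sorted by (size, canonical key)."""
        batch = [frozenset(t) for t in texts]
        new: set[frozenset[str]] = set()
        olds = list(self._texts)
        for i, t in enumerate(batch):
            if t:
                for old in olds:
                    self._expand(t & old, new)
                for j in range(i + 1, len(batch)):
                    self._expand(t & batch[j], new)
        self._texts.extend(batch)
        out = [Feature(s) for s in new]
        out.sort(key=lambda f: (len(f.stems), f.canonical_key))
        return out


def mine_common_sets(texts: Iterable[frozenset[str]],
                     s_cap: int | None = 4, *,
                     pair_intersection_limit: int = 20) -> list[Feature]:
    """All word combinations shared by at least two of the given texts.

    Returns exactly { c : c non-empty, |c| <= s_cap, c a subset of at least
    two distinct input texts }, deduplicated, sorted by (size, key). With
    ``s_cap=None`` the full power set of each pairwise intersection is
    enumerated, which is exponential in the intersection size; pairs whose
    intersection exceeds ``pair_intersection_limit`` then raise
    :class:`IntersectionLimitError` advising a cap.
    """
    miner = IncrementalMiner(s_cap, pair_intersection_limit)
    return miner.add_texts(texts)


def support_counts(feature: Feature, partition: TrainingPartition,
                   active: tuple[set[str] | None, set[str] | None, set[str] | None]
                   = (None, None, None)) -> tuple[int, int, int]:
    """(|P_h|, |N_h|, |U_h|): matching records per set, restricted to actives.

    ``active`` holds the record_id masks for (P, N, U); ``None`` means all
    records of that set are active. Used by greedy learning, where covered
    positives and unlabelled records are progressively deactivated.
    """
    active_p, active_n, active_u = active

    def count(records, mask):
        return sum(
            1 for r in records
            if (mask is None or r.record_id in mask) and matches(feature, r)
        )

    return (
        count(partition.P, active_p),
        count(partition.N, active_n),
        count(partition.U, active_u),
    )


def features_to_json(features: Sequence[Feature]) -> str:
    """Serialize a feature collection as a JSON array of canonical keys."""
    return json.dumps([f.canonical_key for f in features], indent=0)


def features_from_json(payload: str) -> list[Feature]:
    keys = json.loads(payload)
    out, seen = [], set()
    for key in keys:
        f = Feature.from_key(key)
        if f.stems not in seen:
            seen.add(f.stems)
            out.append(f)
    return out
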