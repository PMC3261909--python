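"""Seeded generator of primary-care-like text corpora with planted rules.

Emulates the structure of code-labelled clinical free text without any
real data: a "positive" training set selected by diagnostic code in which
only a fraction (the code-label purity) of texts truly contains the target
concept, a large unlabelled pool hiding further true positives, and a
negative control set. Background tokens are pronounceable nonsense stems
drawn from a long-tailed (shifted-Zipf) vocabulary, guaranteed disjoint
from the planted signal stems; true-positive texts carry one sampled
planted word combination injected whole into their background tokens.
Uninformative code-labelled texts instead carry stems from a small shared
administrative pool (think "hospital admission"), which also seasons the
background sets at a low rate so that decoy common word sets exist.

Some planted rules can be marked *latent*: they occur only among the
unlabelled true positives, never in the code-labelled positive set, so
they are recoverable only through the semi-supervised bootstrap. What the
generator deliberately does not mimic: real clinical language, negation,
misspellings, or abbreviation ambiguity.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import (ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_UNLABELLED,
                        TextRecord, TrainingPartition, partition_from_roles,
                        write_corpus)
from .errors import CorpusFormatError
from .feature_mining import Feature
from .stemming import porter_stem

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth word combination.

    For core rules ``weight`` is the sampling weight of the rule among
    true-positive texts. ``latent`` rules emulate hospital-letter jargon
    that never reaches the code-labelled set: they occur only among
    unlabelled true positives, and for them ``weight`` is the per-text
    inclusion probability (independent of the text's core content).
    """

    stems: frozenset[str]
    weight: float = 1.0
    latent: bool = False

    @property
    def canonical_key(self) -> str:
        return Feature(self.stems).canonical_key


ANGIOGRAM_RULES: tuple[PlantedRule, ...] = (
    PlantedRule(frozenset({"vessel"}), 0.15),
    PlantedRule(frozenset({"stent"}), 0.13),
    PlantedRule(frozenset({"graft"}), 0.13),
    PlantedRule(frozenset({"lad"}), 0.12),
    PlantedRule(frozenset({"coronari", "arteri"}), 0.12),
    PlantedRule(frozenset({"occlud"}), 0.12,),
    PlantedRule(frozenset({"stenosi"}), 0.12),
    PlantedRule(frozenset({"angiogram"}), 0.11),
    PlantedRule(frozenset({"cathet"}), 0.90, latent=True),
    PlantedRule(frozenset({"angioplasti"}), 0.30, latent=True),
)

OVARIAN_RULES: tuple[PlantedRule, ...] = (
    PlantedRule(frozenset({"ovari", "cancer"}), 0.22),
    PlantedRule(frozenset({"ovari", "malign"}), 0.18),
    PlantedRule(frozenset({"ovari", "carcinoma"}), 0.16),
    PlantedRule(frozenset({"ovari", "mass"}), 0.16),
    PlantedRule(frozenset({"ovari", "cyst"}), 0.14),
    PlantedRule(frozenset({"adnex", "mass"}), 0.14),
    PlantedRule(frozenset({"gynaecologi"}), 0.90, latent=True),
    PlantedRule(frozenset({"ca125"}), 0.30, latent=True),
)

_ADMIN_STEMS = ("hospit", "admiss", "letter", "scan", "clinic", "refer")


@dataclass(frozen=True)
class CorpusConfig:
    """Study-shaped corpus parameters; defaults mirror the angiogram task:
    199 code-labelled positives of ~60% purity, 1673 unlabelled case texts
    hiding 111 true positives, and 3539 control texts."""

    seed: int = 0
    vocab_size: int = 600
    background_mean_tokens: float = 11.0
    zipf_exponent: float = 1.15
    zipf_shift: float = 10.0
    planted_rules: tuple[PlantedRule, ...] = ANGIOGRAM_RULES
    co_occurrence: float = 0.35
    latent_only_fraction: float = 0.25
    n_coded_positive: int = 199
    code_label_purity: float = 120 / 199
    n_unlabelled: int = 1673
    unlabelled_positive_fraction: float = 111 / 1673
    n_negative: int = 3539
    n_case_patients: int = 178
    n_control_patients: int = 356
    admin_stems: tuple[str, ...] = _ADMIN_STEMS
    admin_rate: float = 0.08
    positive_code: str = "ANGIO"
    n_background_codes: int = 12
    date_start: datetime.date = datetime.date(2000, 1, 1)
    date_end: datetime.date = datetime.date(2007, 12, 31)

    def __post_init__(self) -> None:
        if not 0.0 <= self.code_label_purity <= 1.0:
            raise CorpusFormatError("code_label_purity must be in [0, 1]")
        if not 0.0 <= self.unlabelled_positive_fraction <= 1.0:
            raise CorpusFormatError(
                "unlabelled_positive_fraction must be in [0, 1]")
        if not self.planted_rules:
            raise CorpusFormatError("at least one planted rule is required")
        admin = set(self.admin_stems)
        for rule in self.planted_rules:
            for stem in rule.stems:
                if not stem or stem != stem.lower():
                    raise CorpusFormatError(
                        f"planted stem {stem!r} must be non-empty lower-case")
                if stem in admin:
                    raise CorpusFormatError(
                        f"planted stem {stem!r} collides with the "
                        "administrative pool")
        if not any(not r.latent for r in self.planted_rules):
            raise CorpusFormatError(
                "at least one planted rule must be non-latent")
        if not 0.0 <= self.latent_only_fraction <= 1.0:
            raise CorpusFormatError("latent_only_fraction must be in [0, 1]")
        for rule in self.planted_rules:
            if rule.latent and not 0.0 <= rule.weight <= 1.0:
                raise CorpusFormatError(
                    "latent rule weights are per-text prevalences in [0, 1]")
        if (self.latent_only_fraction > 0
                and not any(r.latent for r in self.planted_rules)):
            object.__setattr__(self, "latent_only_fraction", 0.0)


def _nonsense_vocabulary(rng: np.random.Generator, size: int,
                         forbidden: frozenset[str]) -> list[str]:
    """Pronounceable, stemmer-stable nonsense stems, disjoint from
    ``forbidden`` (the planted and administrative stems)."""
    cons = list(_CONSONANTS)
    vows = list(_VOWELS)
    seen: set[str] = set(forbidden)
    out: list[str] = []
    while len(out) < size:
        k = int(rng.integers(2, 4))
        word = "".join(
            cons[int(rng.integers(len(cons)))] + vows[int(rng.integers(len(vows)))]
            for _ in range(k)
        ) + cons[int(rng.integers(len(cons)))]
        if word in seen or porter_stem(word) != word:
            continue
        seen.add(word)
        out.append(word)
    return out


def _pick_rule(rng: np.random.Generator, rules: list[PlantedRule],
               exclude: PlantedRule | None = None) -> PlantedRule:
    pool = [r for r in rules if r is not exclude]
    w = np.array([r.weight for r in pool], dtype=float)
    return pool[int(rng.choice(len(pool), p=w / w.sum()))]


class _Generator:
    def __init__(self, config: CorpusConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        forbidden = frozenset(
            s for r in config.planted_rules for s in r.stems
        ) | frozenset(config.admin_stems)
        self.vocab = np.array(
            _nonsense_vocabulary(self.rng, config.vocab_size, forbidden)
        )
        ranks = np.arange(1, config.vocab_size + 1, dtype=float)
        w = (ranks + config.zipf_shift) ** (-config.zipf_exponent)
        self.weights = w / w.sum()
        self.core_rules = [r for r in config.planted_rules if not r.latent]
        self.latent_rules = [r for r in config.planted_rules if r.latent]
        self.rule_draws: list[str] = []
        self.bg_codes = [f"BG{i:02d}" for i in range(config.n_background_codes)]

    def background(self) -> set[str]:
        k = max(3, int(self.rng.poisson(self.cfg.background_mean_tokens)))
        idx = self.rng.choice(self.cfg.vocab_size, size=k, p=self.weights)
        return set(self.vocab[idx])

    def admin_sample(self, low: int, high: int) -> set[str]:
        n = int(self.rng.integers(low, high + 1))
        idx = self.rng.choice(len(self.cfg.admin_stems), size=n, replace=False)
        return {self.cfg.admin_stems[i] for i in idx}

    def positive_tokens(self, *, in_unlabelled: bool,
                        latent_only: bool = False) -> set[str]:
        """Tokens of one true-positive text.

        Code-labelled positives carry core rules only. Unlabelled
        positives additionally include each latent (letter-jargon) rule
        independently with its prevalence; latent-only texts carry no core
        rule at all, so they are reachable only through the bootstrap.
        """
        tokens = self.background()
        if not latent_only:
            primary = _pick_rule(self.rng, self.core_rules)
            tokens |= set(primary.stems)
            self.rule_draws.append(primary.canonical_key)
            if (len(self.core_rules) > 1
                    and self.rng.random() < self.cfg.co_occurrence):
                tokens |= set(
                    _pick_rule(self.rng, self.core_rules, exclude=primary).stems
                )
        if in_unlabelled and self.latent_rules:
            got_latent = False
            for rule in self.latent_rules:
                if self.rng.random() < rule.weight:
                    tokens |= set(rule.stems)
                    got_latent = True
            if latent_only and not got_latent:
                tokens |= set(_pick_rule(self.rng, self.latent_rules).stems)
        return tokens

    def decoy_tokens(self) -> set[str]:
        return self.background() | self.admin_sample(2, 3)

    def negative_tokens(self) -> set[str]:
        tokens = self.background()
        if self.rng.random() < self.cfg.admin_rate:
            tokens |= self.admin_sample(1, 2)
        return tokens

    def random_date(self) -> datetime.date:
        lo = self.cfg.date_start.toordinal()
        hi = self.cfg.date_end.toordinal()
        return datetime.date.fromordinal(int(self.rng.integers(lo, hi + 1)))

    def patient_ids(self, n_texts: int, n_patients: int,
                    prefix: str) -> list[str]:
        """Every patient receives at least one text; the rest are uniform."""
        idx = np.concatenate([
            np.arange(min(n_patients, n_texts)),
            self.rng.integers(0, n_patients, size=max(0, n_texts - n_patients)),
        ])
        self.rng.shuffle(idx)
        return [f"{prefix}-{int(i):04d}" for i in idx]

    def make_record(self, rid: str, tokens: set[str], *, patient: str,
                    code: str, role: str, gold: bool) -> TextRecord:
        words = sorted(tokens)
        order = self.rng.permutation(len(words))
        return TextRecord(
            record_id=rid,
            raw_text=" ".join(words[i] for i in order),
            tokens=frozenset(tokens),
            patient_id=patient,
            event_date=self.random_date(),
            code=code,
            role=role,
            gold=gold,
        )


def generate(config: CorpusConfig) -> tuple[list[TextRecord], dict]:
    """Generate a full corpus and its ground-truth manifest.

    Exactly ``round(purity * n_coded_positive)`` code-labelled texts and
    ``round(fraction * n_unlabelled)`` unlabelled texts are true positives;
    negatives never contain planted stems. Fully reproducible from the
    config seed.
    """
    gen = _Generator(config)
    rng = gen.rng
    records: list[TextRecord] = []

    n_true_p = int(round(config.code_label_purity * config.n_coded_positive))
    n_true_u = int(round(config.unlabelled_positive_fraction
                         * config.n_unlabelled))
    true_p = np.zeros(config.n_coded_positive, dtype=bool)
    true_p[rng.choice(config.n_coded_positive, size=n_true_p,
                      replace=False)] = True
    true_u = np.zeros(config.n_unlabelled, dtype=bool)
    true_u_idx = np.array([], dtype=int)
    if config.n_unlabelled and n_true_u:
        true_u_idx = rng.choice(config.n_unlabelled, size=n_true_u,
                                replace=False)
        true_u[true_u_idx] = True
    latent_only = np.zeros(config.n_unlabelled, dtype=bool)
    n_latent_only = int(round(config.latent_only_fraction * n_true_u))
    if n_latent_only:
        latent_only[rng.choice(true_u_idx, size=n_latent_only,
                               replace=False)] = True

    n_case_texts = config.n_coded_positive + config.n_unlabelled
    case_pids = gen.patient_ids(n_case_texts, config.n_case_patients, "case")
    ctrl_pids = gen.patient_ids(config.n_negative,
                                config.n_control_patients, "ctrl")

    for i in range(config.n_coded_positive):
        tokens = (gen.positive_tokens(in_unlabelled=False) if true_p[i]
                  else gen.decoy_tokens())
        records.append(gen.make_record(
            f"pos-{i:05d}", tokens, patient=case_pids[i],
            code=config.positive_code, role=ROLE_POSITIVE, gold=bool(true_p[i]),
        ))
    for i in range(config.n_unlabelled):
        tokens = (gen.positive_tokens(in_unlabelled=True,
                                      latent_only=bool(latent_only[i]))
                  if true_u[i] else gen.negative_tokens())
        code = gen.bg_codes[int(rng.integers(len(gen.bg_codes)))]
        records.append(gen.make_record(
            f"unl-{i:05d}", tokens, patient=case_pids[config.n_coded_positive + i],
            code=code, role=ROLE_UNLABELLED, gold=bool(true_u[i]),
        ))
    for i in range(config.n_negative):
        code = gen.bg_codes[int(rng.integers(len(gen.bg_codes)))]
        records.append(gen.make_record(
            f"neg-{i:05d}", gen.negative_tokens(), patient=ctrl_pids[i],
            code=code, role=ROLE_NEGATIVE, gold=False,
        ))

    manifest = {
        "seed": config.seed,
        "planted_rules": [
            {"stems": r.canonical_key, "weight": r.weight, "latent": r.latent}
            for r in config.planted_rules
        ],
        "rule_draws": gen.rule_draws,
        "true_positive_ids": sorted(
            r.record_id for r in records if r.gold
        ),
        "counts": {
            "coded_positive": config.n_coded_positive,
            "coded_positive_true": int(n_true_p),
            "unlabelled": config.n_unlabelled,
            "unlabelled_true": int(n_true_u),
            "unlabelled_latent_only": int(n_latent_only),
            "negative": config.n_negative,
        },
    }
    return records, manifest


def table1_fixture(task: str = "angiogram",
                   seed: int = 0) -> tuple[TrainingPartition, dict]:
    """Training partition with the published per-task set sizes.

    angiogram: |P| = 199 (120 true), |U| = 1673 (111 true), |N| = 3539.
    ovarian:   |P| = 236 (all true), |U| = 7570 (353 true), |N| = 1872
    (an external collection standing in for absent controls).
    """
    if task == "angiogram":
        config = CorpusConfig(seed=seed)
    elif task == "ovarian":
        config = CorpusConfig(
            seed=seed,
            planted_rules=OVARIAN_RULES,
            n_coded_positive=236,
            code_label_purity=1.0,
            n_unlabelled=7570,
            unlabelled_positive_fraction=353 / 7570,
            n_negative=1872,
            n_case_patients=340,
            n_control_patients=178,
            positive_code="OVCA",
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    records, manifest = generate(config)
    return partition_from_roles(records), manifest


def raw_case_file(path, seed: int = 0, *, n_blank: int = 100,
                  n_duplicate: int = 118) -> int:
    """Write a raw angiogram-style case-side file with planted blanks and
    within-patient duplicates, emulating an uncleaned extract.

    The defaults yield 2090 rows that clean down to the 1872 case texts of
    the angiogram-shaped corpus. Returns the number of rows written.
    """
    config = CorpusConfig(seed=seed)
    records, _ = generate(config)
    case = [r for r in records if r.role != ROLE_NEGATIVE]
    rng = np.random.default_rng(seed + 1)
    rows = list(case)
    for i in range(n_blank):
        donor = case[int(rng.integers(len(case)))]
        rows.append(replace(donor, record_id=f"blank-{i:04d}", raw_text="",
                            tokens=frozenset(), gold=None))
    for i in range(n_duplicate):
        donor = case[int(rng.integers(len(case)))]
        rows.append(replace(donor, record_id=f"dup-{i:04d}"))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    write_corpus(rows, path)
    return len(rows)
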