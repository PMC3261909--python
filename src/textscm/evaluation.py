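"""Evaluation against manual-review gold labels.

Precision is the percentage of records classified positive that are true
positives (positive predictive value); recall is the percentage of all
gold-positive records classified positive (sensitivity); the F score is
their harmonic mean. Confidence intervals are Wilson score intervals,
which behave sensibly at proportions near 0 or 1. Percentages are rounded
half-away-from-zero to a configurable number of decimals.

Also provided: the semi-supervised leave-one-out adaptation — each
labelled positive is demoted to unlabelled in turn, the model retrained,
and the error rate is the fraction of held-out positives not recovered —
and patient-level detection, where a patient counts as detected by the
classifier (or by diagnostic codes) iff at least one of their records is
positive, with earliest-detection dates per method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace as dc_replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .corpus_io import ROLE_UNLABELLED, TextRecord, TrainingPartition
from .errors import EvaluationError
from .s3cm import train_s3cm
from .scm_core import ScoreParams


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts with derived percentage metrics and 95% CIs.

    Undefined ratios (zero denominator) are None, never 0 or 100.
    """

    tp: int
    fp: int
    fn: int
    tn: int = 0
    precision: float | None = None
    recall: float | None = None
    f_score: float | None = None
    ci_precision: tuple[float, float] | None = None
    ci_recall: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score,
            "ci_precision": list(self.ci_precision) if self.ci_precision else None,
            "ci_recall": list(self.ci_recall) if self.ci_recall else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def format_block(self, label: str = "") -> str:
        """Human-readable metrics block in the style of a results table."""
        def fmt(v, ci):
            if v is None:
                return "undefined"
            if ci is None:
                return f"{v}"
            return f"{v} ({ci[0]}, {ci[1]})"

        lines = [
            f"{label}" if label else "",
            f"  TP={self.tp}  FP={self.fp}  FN={self.fn}  TN={self.tn}",
            f"  Precision, % (95% CI): {fmt(self.precision, self.ci_precision)}",
            f"  Recall, % (95% CI):    {fmt(self.recall, self.ci_recall)}",
            f"  F score, %:            "
            f"{self.f_score if self.f_score is not None else 'undefined'}",
        ]
        return "\n".join(l for l in lines if l)


def confusion(predicted: Mapping[str, bool],
              gold: Mapping[str, bool]) -> tuple[int, int, int, int]:
    """Standard 2x2 counts (tp, fp, fn, tn) over identical key sets."""
    if set(predicted) != set(gold):
        diff = sorted(set(predicted) ^ set(gold))
        raise EvaluationError(
            f"predicted and gold keys differ on {len(diff)} ids: {diff[:10]}"
        )
    tp = fp = fn = tn = 0
    for rid, pred in predicted.items():
        g = gold[rid]
        if pred and g:
            tp += 1
        elif pred and not g:
            fp += 1
        elif not pred and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def proportion_ci(successes: int, trials: int,
                  level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent."""
    if trials < 1:
        raise EvaluationError("proportion_ci needs at least one trial")
    if not 0 <= successes <= trials:
        raise EvaluationError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level,
                                method="wilson")
    # the closed form touches 0 and 100 exactly at the boundaries; undo
    # float round-off so those cases report the exact bound
    lo, hi = 100.0 * lo, 100.0 * hi
    if successes == 0:
        lo = 0.0
    if successes == trials:
        hi = min(100.0, round(hi, 9))
    return max(0.0, lo), min(100.0, hi)


def metrics(tp: int, fp: int, fn: int, tn: int = 0, *,
            decimals: int = 1, ci_level: float = 0.95) -> EvalReport:
    """Derive precision/recall/F (as rounded percentages) from counts.

    F is the harmonic mean computed from the unrounded ratios,
    2*TP / (2*TP + FP + FN), then rounded.
    """
    if min(tp, fp, fn, tn) < 0:
        raise EvaluationError("confusion counts must be non-negative")
    precision = recall = f_score = None
    ci_p = ci_r = None
    if tp + fp > 0:
        precision = _round_half_up(100.0 * tp / (tp + fp), decimals)
        lo, hi = proportion_ci(tp, tp + fp, ci_level)
        ci_p = (_round_half_up(lo, decimals), _round_half_up(hi, decimals))
    else:
        warnings.warn("precision undefined: no record classified positive",
                      stacklevel=2)
    if tp + fn > 0:
        recall = _round_half_up(100.0 * tp / (tp + fn), decimals)
        lo, hi = proportion_ci(tp, tp + fn, ci_level)
        ci_r = (_round_half_up(lo, decimals), _round_half_up(hi, decimals))
    else:
        warnings.warn("recall undefined: no gold-positive record", stacklevel=2)
    if 2 * tp + fp + fn > 0 and precision is not None and recall is not None:
        f_score = _round_half_up(200.0 * tp / (2 * tp + fp + fn), decimals)
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                      recall=recall, f_score=f_score, ci_precision=ci_p,
                      ci_recall=ci_r)


def evaluate_labels(predicted: Mapping[str, bool], gold: Mapping[str, bool],
                    *, decimals: int = 1) -> EvalReport:
    """Confusion + metrics in one step."""
    tp, fp, fn, tn = confusion(predicted, gold)
    return metrics(tp, fp, fn, tn, decimals=decimals)


def loo_cv(partition: TrainingPartition, params: ScoreParams) -> float:
    """Semi-supervised leave-one-out error over the labelled positives.

    Each positive text is demoted to unlabelled in turn; the model is
    retrained on the modified partition and the held-out text's final
    label inspected. Returns the fraction of positives not recovered.
    Deterministic, and invariant to the iteration order of P.
    """
    if len(partition.P) < 2:
        raise EvaluationError(
            "leave-one-out needs at least two labelled positives "
            "(mining requires two texts)"
        )
    errors = 0
    for held in partition.P:
        rest = tuple(r for r in partition.P if r.record_id != held.record_id)
        demoted = dc_replace(held, role=ROLE_UNLABELLED)
        fold = TrainingPartition(P=rest, U=partition.U + (demoted,),
                                 N=partition.N)
        _, _, labels = train_s3cm(fold, params)
        if not labels[held.record_id]:
            errors += 1
    return errors / len(partition.P)


@dataclass(frozen=True)
class PatientLevelReport:
    """Per-patient detection table plus aggregate metrics per method."""

    table: pd.DataFrame
    algorithm: EvalReport
    codes: EvalReport
    n_algorithm_earlier: int
    n_patients_without_dates: int

    def to_json(self) -> str:
        payload = {
            "patients": self.table.to_dict("records"),
            "algorithm": self.algorithm.to_dict(),
            "codes": self.codes.to_dict(),
            "n_algorithm_earlier": self.n_algorithm_earlier,
            "n_patients_without_dates": self.n_patients_without_dates,
        }
        return json.dumps(payload, sort_keys=True, indent=2, default=str)


def patient_level(records: Sequence[TextRecord],
                  predicted: Mapping[str, bool],
                  code_flags: Mapping[str, bool], *,
                  decimals: int = 1) -> PatientLevelReport:
    """Aggregate record-level predictions and code flags per patient.

    A patient is algorithm-detected iff at least one of their records is
    predicted positive, code-detected iff at least one record carries a
    positive code, and gold-positive iff at least one record is
    gold-positive. Earliest detection dates per method are the minimum
    event date among qualifying records; records without dates count for
    detection but not timing.
    """
    per: dict[str, dict] = {}
    undated_patients: set[str] = set()
    for rec in records:
        if rec.patient_id is None:
            raise EvaluationError(
                f"record {rec.record_id!r} has no patient_id"
            )
        row = per.setdefault(rec.patient_id, {
            "patient_id": rec.patient_id, "gold": False,
            "algorithm": False, "codes": False,
            "algorithm_date": None, "code_date": None,
        })
        pred = bool(predicted.get(rec.record_id, False))
        flag = bool(code_flags.get(rec.record_id, False))
        row["gold"] = row["gold"] or bool(rec.gold)
        row["algorithm"] = row["algorithm"] or pred
        row["codes"] = row["codes"] or flag
        if rec.event_date is None:
            if pred or flag:
                undated_patients.add(rec.patient_id)
            continue
        if pred and (row["algorithm_date"] is None
                     or rec.event_date < row["algorithm_date"]):
            row["algorithm_date"] = rec.event_date
        if flag and (row["code_date"] is None
                     or rec.event_date < row["code_date"]):
            row["code_date"] = rec.event_date

    if undated_patients:
        warnings.warn(
            f"{len(undated_patients)} patient(s) have undated qualifying "
            "records; they count for detection but not timing", stacklevel=2)

    rows = sorted(per.values(), key=lambda r: r["patient_id"])
    table = pd.DataFrame(rows)
    gold = {r["patient_id"]: r["gold"] for r in rows}
    alg = {r["patient_id"]: r["algorithm"] for r in rows}
    cod = {r["patient_id"]: r["codes"] for r in rows}
    n_earlier = sum(
        1 for r in rows
        if r["algorithm_date"] is not None and (
            r["code_date"] is None or r["algorithm_date"] < r["code_date"]
        )
    )
    return PatientLevelReport(
        table=table,
        algorithm=evaluate_labels(alg, gold, decimals=decimals),
        codes=evaluate_labels(cod, gold, decimals=decimals),
        n_algorithm_earlier=n_earlier,
        n_patients_without_dates=len(undated_patients),
    )
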