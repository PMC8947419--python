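"""Contingency evaluation of setae calls against eclosion outcomes.

Setae-positive pupae are predicted male, setae-negative pupae predicted
female. Pupae that never eclosed ("unfledged") carry no sex label and are
excluded from every accuracy denominator:

* accuracy of the setae-positive group = males among positives / positives
  that eclosed;
* accuracy of the setae-negative group = females among negatives / negatives
  that eclosed;
* overall accuracy = (males among positives + females among negatives) /
  all pupae that eclosed.

Percentages are reported to one decimal place, rounding half up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

OUTCOMES = ("female", "male", "unfledged")


@dataclass
class EvaluationTable:
    """Contingency counts of call x outcome and the derived accuracies.

    Accuracies are percentages rounded half-up to one decimal, or None when
    the corresponding denominator (eclosed pupae in the group) is zero.
    """

    n_setae_pos: int
    n_setae_neg: int
    setae_pos_outcomes: dict
    setae_neg_outcomes: dict
    acc_setae_pos: float | None
    acc_setae_neg: float | None
    acc_overall: float | None


def _round1(numer: int, denom: int) -> float | None:
    if denom == 0:
        return None
    pct = Decimal(100 * numer) / Decimal(denom)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def build_table(calls: pd.DataFrame, manifest: pd.DataFrame) -> EvaluationTable:
    """Cross-tabulate per-pupa calls against eclosion outcomes.

    Parameters
    ----------
    calls : DataFrame with columns ``pupa_id`` and boolean ``positive``.
    manifest : DataFrame with columns ``pupa_id`` and ``outcome``
        (female | male | unfledged).

    Every call must have a matching outcome and vice versa; mismatches raise
    with the offending ids listed.
    """
    c = calls[["pupa_id", "positive"]].copy()
    m = manifest[["pupa_id", "outcome"]].copy()
    bad = set(m["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes in manifest: {sorted(bad)}")
    missing_outcome = sorted(set(c["pupa_id"]) - set(m["pupa_id"]))
    missing_call = sorted(set(m["pupa_id"]) - set(c["pupa_id"]))
    if missing_outcome or missing_call:
        raise ValueError(
            f"unmatched pupa_ids: calls without outcome {missing_outcome}; "
            f"outcomes without call {missing_call}"
        )
    merged = c.merge(m, on="pupa_id")
    mask = merged["positive"].astype(bool)
    pos = merged[mask]
    neg = merged[~mask]
    pos_counts = {k: int((pos["outcome"] == k).sum()) for k in OUTCOMES}
    neg_counts = {k: int((neg["outcome"] == k).sum()) for k in OUTCOMES}
    pos_emerged = pos_counts["female"] + pos_counts["male"]
    neg_emerged = neg_counts["female"] + neg_counts["male"]
    acc_pos = _round1(pos_counts["male"], pos_emerged)
    acc_neg = _round1(neg_counts["female"], neg_emerged)
    acc_all = _round1(pos_counts["male"] + neg_counts["female"], pos_emerged + neg_emerged)
    if acc_all is None and len(merged):
        warnings.warn("all pupae unfledged: accuracies are undefined", stacklevel=2)
    return EvaluationTable(
        n_setae_pos=int(len(pos)),
        n_setae_neg=int(len(neg)),
        setae_pos_outcomes=pos_counts,
        setae_neg_outcomes=neg_counts,
        acc_setae_pos=acc_pos,
        acc_setae_neg=acc_neg,
        acc_overall=acc_all,
    )


def _fmt_acc(a: float | None) -> str:
    return "NA" if a is None else f"{a:.1f}"


def summarize(table: EvaluationTable):
    """Text and tabular report mirroring the published row structure.

    Returns ``(text, frame)``: ``frame`` has columns
    type, observed, female, male, unfledged, accuracy with one row per call
    group plus an overall row (omitted for an empty cohort).
    """
    rows = []
    total = table.n_setae_pos + table.n_setae_neg
    if total:
        rows.append(
            {
                "type": "no_setae",
                "observed": table.n_setae_neg,
                **table.setae_neg_outcomes,
                "accuracy": _fmt_acc(table.acc_setae_neg),
            }
        )
        rows.append(
            {
                "type": "setae",
                "observed": table.n_setae_pos,
                **table.setae_pos_outcomes,
                "accuracy": _fmt_acc(table.acc_setae_pos),
            }
        )
        rows.append(
            {
                "type": "overall",
                "observed": total,
                **{
                    k: table.setae_pos_outcomes[k] + table.setae_neg_outcomes[k]
                    for k in OUTCOMES
                },
                "accuracy": _fmt_acc(table.acc_overall),
            }
        )
    frame = pd.DataFrame(rows, columns=["type", "observed", "female", "male", "unfledged", "accuracy"])
    lines = ["type,observed,female,male,unfledged,accuracy"]
    for r in rows:
        lines.append(
            f"{r['type']},{r['observed']},{r['female']},{r['male']},{r['unfledged']},{r['accuracy']}"
        )
    return "\n".join(lines) + "\n", frame
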