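"""Evaluation statistics: multi-observer proportion of agreement (with Wald
95% CI) and information-retrieval precision.

Agreement counts concordant-positive observer pairs only: for an image
where ``k`` of ``x`` panel members marked a sign, ``C(k,2)`` of the
``C(x,2)`` observer pairs agree.  Pairs in which both observers omitted the
sign are *not* counted as agreements.  A (sign, image) pair enters the
table only when at least one observer annotated it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .annotation import AnnotationSession, annotation_matrix, observed_sign_sets
from .kb_core.model import KBError
from .reasoner import SubsumptionClosure, compute_closure

Z_95 = 1.96


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (spreadsheet-style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def truncated_percent(ratio: float) -> int:
    """Integer percentage by truncation (e.g. 10/15 -> 66)."""
    return int(ratio * 100)


@dataclass(frozen=True)
class AgreementRow:
    sign: str
    agreements: int
    disagreements: int
    images: int
    p_a: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def trials(self) -> int:
        return self.agreements + self.disagreements

    def percent(self) -> tuple[float, float, float]:
        """(p_a, ci_low, ci_high) as percentages rounded half-up to 2 dp.

        The CI is the exact Wald interval computed from the raw counts.
        """
        return (
            round_half_up(self.p_a * 100),
            round_half_up(self.ci_low * 100),
            round_half_up(self.ci_high * 100),
        )

    def percent_prerounded(self) -> tuple[float, float, float]:
        """Rendering with the CI recomputed from the 2-dp rounded percentage.

        Published per-sign agreement tables in this domain were evidently
        produced by feeding the already-rounded percentage back into the
        Wald formula; this rendering reproduces that convention.  Pooled
        totals use :meth:`percent` (the exact route).
        """
        p_pct = round_half_up(self.p_a * 100)
        n = self.trials
        se_pct = math.sqrt(p_pct * (100.0 - p_pct) / n)
        return (
            p_pct,
            round_half_up(max(0.0, p_pct - Z_95 * se_pct)),
            round_half_up(min(100.0, p_pct + Z_95 * se_pct)),
        )


@dataclass(frozen=True)
class PrecisionReport:
    per_unit: Mapping[tuple[str, str], float]
    observed_total: int
    relevant_observed_total: int

    @property
    def precision(self) -> float:
        """Micro-averaged precision over all units."""
        if self.observed_total == 0:
            raise KBError("no observed annotations; precision undefined")
        return self.relevant_observed_total / self.observed_total


def concordant_pairs(k: int, x: int) -> tuple[int, int]:
    """(agreeing pairs, total pairs) for ``k`` of ``x`` observers marking."""
    if x < 2:
        raise ValueError("panel size x must be >= 2")
    if not 0 <= k <= x:
        raise ValueError(f"k={k} outside [0, x={x}]")
    return k * (k - 1) // 2, x * (x - 1) // 2


def agreement_row(
    agreements: int, disagreements: int, sign: str = "", images: int = 0
) -> AgreementRow:
    """Proportion of agreement with Wald 95% CI clipped to [0, 1]."""
    n = agreements + disagreements
    if n < 1:
        raise ValueError("at least one trial of agreement is required")
    if min(agreements, disagreements) < 0:
        raise ValueError("counts must be non-negative")
    p = agreements / n
    se = math.sqrt(p * (1.0 - p) / n)
    return AgreementRow(
        sign=sign,
        agreements=agreements,
        disagreements=disagreements,
        images=images,
        p_a=p,
        se=se,
        ci_low=max(0.0, p - Z_95 * se),
        ci_high=min(1.0, p + Z_95 * se),
    )


def agreement_table(
    session: AnnotationSession,
    signs: Sequence[str],
    cohort: Optional[str] = None,
    closure: Optional[SubsumptionClosure] = None,
) -> tuple[list[AgreementRow], AgreementRow]:
    """Per-sign agreement rows plus a pooled total row.

    The total pools agreement and trial counts over all listed signs before
    computing the proportion and its CI.
    """
    if not signs:
        raise ValueError("empty sign list")
    if session.observer_count() < 2:
        raise KBError("agreement requires at least 2 observers")
    if closure is None and session.kb is not None:
        closure = compute_closure(session.kb)
    rows: list[AgreementRow] = []
    total_a = total_d = 0
    for sign in signs:
        a = d = images = 0
        for _, k, x in annotation_matrix(session, sign, cohort=cohort, closure=closure):
            agree, trials = concordant_pairs(k, x)
            a += agree
            d += trials - agree
            images += 1
        if a + d == 0:
            continue  # sign never annotated in this cohort
        rows.append(agreement_row(a, d, sign=sign, images=images))
        total_a += a
        total_d += d
    if total_a + total_d == 0:
        raise KBError("none of the listed signs was annotated")
    total = agreement_row(total_a, total_d, sign="total",
                          images=sum(r.images for r in rows))
    return rows, total


def pooled_agreement(rows: Sequence[tuple[int, int]]) -> AgreementRow:
    """Pool (agreements, disagreements) count pairs into one row."""
    a = sum(r[0] for r in rows)
    d = sum(r[1] for r in rows)
    return agreement_row(a, d, sign="total")


def precision(
    observed: Mapping[tuple[str, str], frozenset[str]],
    gold: Mapping[str, frozenset[str]],
) -> PrecisionReport:
    """Micro-averaged precision of observed sign sets against the gold
    standard; units with empty observed sets are excluded upstream."""
    per_unit: dict[tuple[str, str], float] = {}
    obs_total = rel_total = 0
    for (image_id, observer), signs in sorted(observed.items()):
        if not signs:
            continue
        if image_id not in gold:
            raise KBError(f"no gold standard for image {image_id!r}")
        inter = len(signs & gold[image_id])
        per_unit[(image_id, observer)] = inter / len(signs)
        obs_total += len(signs)
        rel_total += inter
    return PrecisionReport(per_unit, obs_total, rel_total)


def session_precision(
    session: AnnotationSession,
    cohort: Optional[str] = None,
    closure: Optional[SubsumptionClosure] = None,
) -> PrecisionReport:
    if session.gold is None:
        raise KBError("session has no gold standard")
    observed = observed_sign_sets(session, cohort=cohort, closure=closure)
    return precision(observed, session.gold)


def single_observer_share(single: int, total: int, decimals: int = 1) -> float:
    """Percentage of annotations contributed by exactly one observer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * single / total, decimals)


def single_observer_annotations(
    session: AnnotationSession, cohort: Optional[str] = None
) -> tuple[int, int]:
    """(annotations made by exactly one observer, total annotations).

    An 'annotation' is one (image, observer, concept) record; a record is a
    single-observer one when no other observer selected the same concept on
    the same image.
    """
    wanted = set(session.image_ids(cohort))
    by_pair: dict[tuple[str, str], set[str]] = {}
    for a in session.annotations:
        if a.image_id in wanted:
            by_pair.setdefault((a.image_id, a.concept), set()).add(a.observer)
    single = sum(1 for obs in by_pair.values() if len(obs) == 1)
    total = sum(len(obs) for obs in by_pair.values())
    return single, total
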