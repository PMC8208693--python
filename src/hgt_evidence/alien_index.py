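"""The alien index: a log-ratio of best-hit E values for HGT detection.

For a query suspected of horizontal acquisition, let the *recipient* best
hit be the closest homologue in the query's own lineage and the *donor*
best hit the closest homologue in the candidate source lineage. Then

    AI = ln(best recipient E value + 1e-200) - ln(best donor E value + 1e-200)

Large positive AI means the query is enormously closer to the alien lineage
than to its own. With a missing recipient hit (E treated as 1) and a donor
E value of 0 the index attains its maximum, ln(1 + 1e-200) - ln(1e-200) =
460.517... ≈ 460.5.

Classification follows the standard three-category scheme: very likely HGT
(AI > 30), possible HGT (0 < AI ≤ 30), with an optional donor-identity rule
(≥70 % identity to the donor reclassifies a positive AI as likely
contamination) that matters for prokaryote-to-eukaryote screens; for
prokaryote-to-prokaryote comparisons it is disabled by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .io_formats import HomologyHit

#: pseudocount added to both E values before taking logs
EPSILON = 1e-200

#: AI attained by (recipient absent -> E=1, donor E = 0)
MAX_ALIEN_INDEX = math.log(1 + EPSILON) - math.log(EPSILON)  # 460.517...

VERY_LIKELY_HGT = "very_likely_hgt"
POSSIBLE_HGT = "possible_hgt"
LIKELY_CONTAMINATION = "likely_contamination"
NO_HGT_SIGNAL = "no_hgt_signal"

#: E value substituted for a lineage with no hit at all
MISSING_HIT_EVALUE = 1.0


@dataclass
class EvaluePair:
    """Best donor/recipient hits feeding one alien-index computation."""

    donor_best: Optional[HomologyHit]
    recipient_best: Optional[HomologyHit]
    epsilon: float = EPSILON


@dataclass
class AlienIndexResult:
    ai: float
    ai_rounded: int
    donor_evalue: float
    recipient_evalue: float
    donor_identity: float
    category: str


def alien_index(recipient_evalue: Optional[float],
                donor_evalue: Optional[float],
                epsilon: float = EPSILON) -> float:
    """ln(recipient E + ε) − ln(donor E + ε), at full precision.

    ``None`` (no hit in that lineage) is substituted by E = 1, consistent
    with the stated maximum 460.5 = ln(1) − ln(1e−200).
    """
    if recipient_evalue is None:
        recipient_evalue = MISSING_HIT_EVALUE
    if donor_evalue is None:
        donor_evalue = MISSING_HIT_EVALUE
    if recipient_evalue < 0 or donor_evalue < 0:
        raise ValueError("E values must be non-negative")
    return math.log(recipient_evalue + epsilon) - math.log(donor_evalue + epsilon)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def classify(ai: float, donor_identity: float,
             identity_rule_enabled: bool = False,
             very_likely_threshold: float = 30.0,
             possible_threshold: float = 0.0) -> str:
    """Map an AI (and optionally the donor identity) to an HGT category.

    With the identity rule disabled (prokaryote-to-prokaryote mode):
    AI > 30 → very likely HGT; 0 < AI ≤ 30 → possible HGT; AI ≤ 0 → no
    signal. With the rule enabled, a positive AI with ≥70 % donor identity
    is classified as likely contamination instead.
    """
    if not 0 <= donor_identity <= 100:
        raise ValueError(f"donor identity out of [0,100]: {donor_identity!r}")
    if ai <= possible_threshold:
        return NO_HGT_SIGNAL
    if identity_rule_enabled and donor_identity >= 70:
        return LIKELY_CONTAMINATION
    if ai > very_likely_threshold:
        return VERY_LIKELY_HGT
    return POSSIBLE_HGT


def best_hits(hits: Iterable[HomologyHit],
              exclude_subjects: frozenset = frozenset()) -> EvaluePair:
    """Select the best donor and recipient hits from a grouped hit table.

    Within each subject_group the minimal E value wins; ties break by larger
    bit score, then larger percent identity, then lexicographic subject id.
    ``exclude_subjects`` removes self-matches before selection. An empty
    group yields an absent best hit.
    """
    best: dict[str, Optional[HomologyHit]] = {"donor": None, "recipient": None}

    def key(h: HomologyHit):
        return (h.evalue, -h.bit_score, -h.percent_identity, h.subject_id)

    for h in hits:
        if h.subject_id in exclude_subjects or h.subject_group not in best:
            continue
        if best[h.subject_group] is None or key(h) < key(best[h.subject_group]):
            best[h.subject_group] = h
    return EvaluePair(donor_best=best["donor"], recipient_best=best["recipient"])


def evaluate(pair: EvaluePair, identity_rule_enabled: bool = False,
             very_likely_threshold: float = 30.0) -> AlienIndexResult:
    """Compute AI and category for one donor/recipient best-hit pair."""
    donor_e = pair.donor_best.evalue if pair.donor_best else MISSING_HIT_EVALUE
    recip_e = (pair.recipient_best.evalue if pair.recipient_best
               else MISSING_HIT_EVALUE)
    donor_ident = pair.donor_best.percent_identity if pair.donor_best else 0.0
    ai = alien_index(recip_e, donor_e, pair.epsilon)
    return AlienIndexResult(
        ai=ai,
        ai_rounded=round_half_up(ai),
        donor_evalue=donor_e,
        recipient_evalue=recip_e,
        donor_identity=donor_ident,
        category=classify(ai, donor_ident, identity_rule_enabled,
                          very_likely_threshold),
    )
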