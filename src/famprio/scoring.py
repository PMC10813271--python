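"""Predictor banding and the composite hazard score.

Three in-silico predictors feed the score.  SIFT calls a substitution
Deleterious (D) at score <= 0.05, otherwise Tolerated (T).  PolyPhen2
HDIV bands its score into Probably damaging (D, >= 0.957), Possibly
damaging (P, 0.453-0.956) and Benign (B, <= 0.452).  MutationTaster
emits Disease-causing automatic (A), Disease-causing (D), Polymorphism
(N) or Polymorphism automatic (P); A and D are the harmful calls.

The composite hazard score sums per-predictor weights: 1 for a harmful
call (SIFT D; PolyPhen D; MutationTaster A or D), 0.5 for PolyPhen P,
0 otherwise (an NA slot contributes nothing).  The resulting scale is
{0, 0.5, ..., 3}; higher means more consistently deleterious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import AnnotationRecord, CandidateTable

SIFT_DELETERIOUS_MAX = 0.05
PP2_PROBABLY_MIN = 0.957
PP2_POSSIBLY_MIN = 0.453
HARMFUL_MT_PREDS = frozenset({"A", "D"})


@dataclass(frozen=True)
class PredictorCall:
    """Categorical calls of the three predictors for one variant (None = NA)."""

    sift: Optional[str] = None  # D | T
    pp2: Optional[str] = None   # D | P | B
    mt: Optional[str] = None    # A | D | N | P

    def __post_init__(self) -> None:
        if self.sift not in (None, "D", "T"):
            raise ValueError(f"bad SIFT call {self.sift!r}")
        if self.pp2 not in (None, "D", "P", "B"):
            raise ValueError(f"bad PolyPhen2 call {self.pp2!r}")
        if self.mt not in (None, "A", "D", "N", "P"):
            raise ValueError(f"bad MutationTaster call {self.mt!r}")


def classify_sift(score: Optional[float]) -> Optional[str]:
    """Band a SIFT score: D at <= 0.05, else T; NA passes through."""
    if score is None:
        return None
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    return "D" if score <= SIFT_DELETERIOUS_MAX else "T"


def classify_pp2_hdiv(score: Optional[float]) -> Optional[str]:
    """Band a PolyPhen2-HDIV score into D / P / B.

    The published band edges leave the open gaps (0.452, 0.453) and
    (0.956, 0.957) unassigned; those are resolved to the lower (more
    benign) band.
    """
    if score is None:
        return None
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen2 score {score} outside [0, 1]")
    if score >= PP2_PROBABLY_MIN:
        return "D"
    if score >= PP2_POSSIBLY_MIN:
        return "P"
    return "B"


def harmful_mt(pred: Optional[str]) -> bool:
    """True for the MutationTaster disease-causing calls (A or D)."""
    if pred not in (None, "A", "D", "N", "P"):
        raise ValueError(f"bad MutationTaster call {pred!r}")
    return pred in HARMFUL_MT_PREDS


def hazard_score(call: PredictorCall) -> float:
    """Composite hazard score of one variant's predictor calls."""
    w_sift = 1.0 if call.sift == "D" else 0.0
    w_pp2 = 1.0 if call.pp2 == "D" else (0.5 if call.pp2 == "P" else 0.0)
    w_mt = 1.0 if harmful_mt(call.mt) else 0.0
    return w_sift + w_pp2 + w_mt


def predictor_call(ann: AnnotationRecord) -> PredictorCall:
    """Extract the predictor calls from an annotation record.

    Shipped categorical predictions take precedence; banding from the
    numeric score is used only to fill an NA prediction (annotation
    sources ship both, and the shipped call is authoritative).
    """
    sift = ann.sift_pred if ann.sift_pred is not None else classify_sift(ann.sift_score)
    pp2 = ann.pp2_hdiv_pred if ann.pp2_hdiv_pred is not None else classify_pp2_hdiv(ann.pp2_hdiv_score)
    return PredictorCall(sift=sift, pp2=pp2, mt=ann.mt_pred)


def _rank_key(row) -> tuple:
    ann = row.annotation
    pp2 = ann.pp2_hdiv_score
    sift = ann.sift_score
    return (
        -row.hazard_score,
        float("inf") if pp2 is None else -pp2,   # higher PolyPhen first, NA last
        float("inf") if sift is None else sift,  # lower SIFT first, NA last
        row.gene,
    )


def rank_candidates(table: CandidateTable) -> CandidateTable:
    """Order rows by hazard score (descending) and assign ranks 1..n.

    Ties break by PolyPhen2-HDIV score descending, then SIFT score
    ascending (NA last in both), then gene symbol.  The ordering is
    advisory: it surfaces the strongest candidates but performs no
    automatic single-gene selection.
    """
    table.rows.sort(key=_rank_key)
    for i, row in enumerate(table.rows, start=1):
        row.rank = i
    return table
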