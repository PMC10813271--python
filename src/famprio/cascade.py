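"""The multi-stage variant filter cascade.

Stages, applied in order to the family variant set:

1. ``intersect_affected`` — keep variants carried by every genotyped
   affected member (the shared-variant intersection).
2. ``exclude_controls``  — drop variants carried by any designated
   unaffected control.
3. ``filter_region``     — keep exonic and splice-site variants.
4. ``filter_function``   — drop synonymous changes.
5. ``filter_zygosity``   — drop variants homozygous-alt in every
   affected member (inconsistent with a rare dominant allele).
6. ``filter_af``         — drop variants whose catalogued East-Asian
   allele frequency exceeds a rarity threshold (default 0.001, strict).

Survivors are scored with the composite hazard score, ranked, and
annotated with their segregation result.  Every stage records an audit
count so the cascade's narrowing is inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    MISSING,
    AnnotationRecord,
    CandidateRow,
    CandidateTable,
    GenotypeMatrix,
    Pedigree,
    VariantRecord,
)
from .pedigree import check_segregation
from .scoring import hazard_score, predictor_call, rank_candidates

DEFAULT_KEEP_REGIONS = frozenset({"exonic", "splicing"})
DEFAULT_DROP_FUNCTIONS = frozenset({"synonymous_SNV"})
DEFAULT_AF_FIELDS = ("af_1000g_eas", "af_exac_eas")
DEFAULT_AF_THRESHOLD = 0.001


@dataclass
class CascadeConfig:
    """Configuration of the filter cascade.

    ``af_fields`` names the East-Asian frequency columns screened by the
    rarity filter; ``na_policy`` decides whether a variant absent from
    every catalogue passes ("pass", the default — absence from catalogues
    is evidence of rarity) or fails ("fail").
    """

    affected_ids: tuple[str, ...]
    control_ids: tuple[str, ...] = ()
    keep_regions: frozenset[str] = DEFAULT_KEEP_REGIONS
    drop_functions: frozenset[str] = DEFAULT_DROP_FUNCTIONS
    af_fields: tuple[str, ...] = DEFAULT_AF_FIELDS
    af_threshold: float = DEFAULT_AF_THRESHOLD
    na_policy: str = "pass"

    def __post_init__(self) -> None:
        self.affected_ids = tuple(self.affected_ids)
        self.control_ids = tuple(self.control_ids)
        self.keep_regions = frozenset(self.keep_regions)
        self.drop_functions = frozenset(self.drop_functions)
        self.af_fields = tuple(self.af_fields)
        if set(self.affected_ids) & set(self.control_ids):
            raise ValueError("affected and control sample sets overlap")
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError(f"af_threshold {self.af_threshold} outside [0, 1]")
        if self.na_policy not in ("pass", "fail"):
            raise ValueError(f"na_policy must be 'pass' or 'fail', got {self.na_policy!r}")

    def to_json(self, path) -> None:
        data = asdict(self)
        data["keep_regions"] = sorted(self.keep_regions)
        data["drop_functions"] = sorted(self.drop_functions)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "CascadeConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _carrier_mask(gt: GenotypeMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    cols = gt.sample_columns(sample_ids)
    sub = gt.calls[:, cols]
    return (sub == 1) | (sub == 2)


def intersect_affected(gt: GenotypeMatrix, affected_ids: Sequence[str]) -> set[str]:
    """Variants carried (call 1 or 2) by every affected member.

    A MISSING call excludes the variant: carriage cannot be confirmed.
    """
    affected_ids = list(affected_ids)
    if not affected_ids:
        raise ValueError("affected sample set is empty")
    keep = _carrier_mask(gt, affected_ids).all(axis=1)
    return {gt.vids[i] for i in np.flatnonzero(keep)}


def exclude_controls(
    vids: Iterable[str], gt: GenotypeMatrix, control_ids: Sequence[str]
) -> set[str]:
    """Drop variants carried by any control; MISSING in a control never drops."""
    vids = set(vids)
    control_ids = list(control_ids)
    if not control_ids:
        return vids
    any_carrier = _carrier_mask(gt, control_ids).any(axis=1)
    dropped = {gt.vids[i] for i in np.flatnonzero(any_carrier)}
    return vids - dropped


def _require_annotation(vid: str, annotations: Mapping[str, AnnotationRecord]) -> AnnotationRecord:
    try:
        return annotations[vid]
    except KeyError:
        raise KeyError(f"no annotation for variant {vid}") from None


def filter_region(
    vids: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    keep_regions: frozenset[str] = DEFAULT_KEEP_REGIONS,
) -> set[str]:
    return {v for v in vids if _require_annotation(v, annotations).region in keep_regions}


def filter_function(
    vids: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    drop_functions: frozenset[str] = DEFAULT_DROP_FUNCTIONS,
) -> set[str]:
    return {v for v in vids if _require_annotation(v, annotations).function not in drop_functions}


def filter_zygosity(
    vids: Iterable[str], gt: GenotypeMatrix, affected_ids: Sequence[str]
) -> set[str]:
    """Drop variants homozygous-alt in every affected member."""
    affected_ids = list(affected_ids)
    cols = gt.sample_columns(affected_ids)
    all_hom = (gt.calls[:, cols] == 2).all(axis=1)
    dropped = {gt.vids[i] for i in np.flatnonzero(all_hom)}
    return set(vids) - dropped


def filter_af(
    vids: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    af_fields: Sequence[str] = DEFAULT_AF_FIELDS,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    na_policy: str = "pass",
) -> set[str]:
    """Drop variants whose maximum non-NA screened frequency exceeds the threshold.

    The inequality is strict: a frequency exactly at the threshold is kept.
    Variants NA in every screened field pass under ``na_policy="pass"``.
    """
    out = set()
    for vid in vids:
        ann = _require_annotation(vid, annotations)
        values = ann.af_values(af_fields)
        if not values:
            if na_policy == "pass":
                out.add(vid)
            continue
        if max(values) <= af_threshold:
            out.add(vid)
    return out


def run_cascade(
    variants: Sequence[VariantRecord],
    gt: GenotypeMatrix,
    annotations: Mapping[str, AnnotationRecord],
    ped: Optional[Pedigree],
    config: CascadeConfig,
) -> CandidateTable:
    """Run the full cascade and return the scored, ranked candidate table.

    ``ped`` may be None when no pedigree is available; segregation results
    are then omitted.  Stage audit counts (including the input count) and
    ``stage=<name> in=<n> out=<m>`` log lines are attached to the table.
    """
    order = [v.vid for v in variants]
    if len(set(order)) != len(order):
        raise ValueError("duplicate variant ids in cascade input")

    current: set[str] = set(order)
    table = CandidateTable()
    table.stage_counts.append(("input", len(current)))

    def apply(name: str, result: set[str]) -> None:
        nonlocal current
        table.audit_log.append(f"stage={name} in={len(current)} out={len(result)}")
        if not result <= current:
            raise AssertionError(f"stage {name} produced variants not in its input")
        current = result
        table.stage_counts.append((name, len(current)))

    if current:
        apply("intersect_affected", intersect_affected(gt, config.affected_ids) & current)
        apply("exclude_controls", exclude_controls(current, gt, config.control_ids))
        apply("filter_region", filter_region(current, annotations, config.keep_regions))
        apply("filter_function", filter_function(current, annotations, config.drop_functions))
        apply("filter_zygosity", filter_zygosity(current, gt, config.affected_ids))
        apply(
            "filter_af",
            filter_af(current, annotations, config.af_fields, config.af_threshold, config.na_policy),
        )
    else:
        for name in (
            "intersect_affected", "exclude_controls", "filter_region",
            "filter_function", "filter_zygosity", "filter_af",
        ):
            apply(name, set())

    for vid in order:
        if vid not in current:
            continue
        ann = _require_annotation(vid, annotations)
        score = hazard_score(predictor_call(ann))
        table.rows.append(CandidateRow(vid=vid, gene=ann.gene, annotation=ann, hazard_score=score))
        if ped is not None:
            table.segregation[vid] = check_segregation(ped, gt, vid)

    rank_candidates(table)
    table.validate()
    return table
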