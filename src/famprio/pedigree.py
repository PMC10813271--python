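"""Segregation checks and the chance-cosegregation probability.

Under an autosomal-dominant model a candidate variant segregates with
the phenotype when every genotyped affected member carries it and no
designated control does.  The strength of that observation as
supporting evidence is quantified by the probability that the observed
pattern arose by chance: (1/2) per informative meiosis, i.e. per
genotyped carrier offspring of a genotyped carrier parent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import MISSING, GenotypeMatrix, Pedigree


def _is_carrier(call: int) -> bool:
    return call in (1, 2)


@dataclass(frozen=True)
class SegregationResult:
    """Outcome of a per-variant segregation check in one pedigree."""

    vid: str
    segregates: bool
    affected_carriers: int
    control_carriers: int
    informative_meioses: int

    @property
    def cosegregation_probability(self) -> float:
        return cosegregation_probability(self.informative_meioses)


def check_segregation(ped: Pedigree, gt: GenotypeMatrix, vid: str) -> SegregationResult:
    """Test whether a variant co-occurs with affection status in the family.

    Carrier status is call 1 or 2.  A MISSING call in an affected member
    means presence cannot be confirmed, so segregation fails; a MISSING
    call in a control is not treated as carriage.  Members with unknown
    affection are ignored.
    """
    genotyped = set(gt.samples)
    affected = [m for m in ped.affected_ids() if m in genotyped]
    if not affected:
        raise ValueError(f"no genotyped affected members to assess segregation of {vid}")
    controls = [c for c in sorted(ped.controls) if c in genotyped]

    affected_calls = [gt.call(vid, s) for s in affected]
    affected_carriers = sum(_is_carrier(c) for c in affected_calls)
    any_affected_missing = any(c == MISSING for c in affected_calls)
    control_carriers = sum(_is_carrier(gt.call(vid, s)) for s in controls)

    segregates = (
        not any_affected_missing
        and affected_carriers == len(affected)
        and control_carriers == 0
    )
    m = informative_meioses(ped, gt, vid)
    return SegregationResult(
        vid=vid,
        segregates=segregates,
        affected_carriers=affected_carriers,
        control_carriers=control_carriers,
        informative_meioses=m,
    )


def informative_meioses(ped: Pedigree, gt: GenotypeMatrix, vid: str) -> int:
    """Count observed carrier transmissions for a variant.

    A meiosis is informative when a genotyped non-founder carrier has a
    genotyped carrier parent: the transmission of the variant allele was
    directly observed.  Genotyped non-carrier offspring are not counted;
    the tally reflects carrier transmissions only.
    """
    genotyped = set(gt.samples)
    m = 0
    for mid in ped.members:
        if mid not in genotyped or ped.is_founder(mid):
            continue
        if not _is_carrier(gt.call(vid, mid)):
            continue
        for parent in ped.parents_of(mid):
            if parent is not None and parent in genotyped and _is_carrier(gt.call(vid, parent)):
                m += 1
                break  # one transmission per offspring
    return m


def cosegregation_probability(m: int) -> float:
    """Probability of the observed cosegregation arising by chance: (1/2)^m."""
    if m < 0:
        raise ValueError(f"meiosis count must be non-negative, got {m}")
    return 0.5 ** m


def cosegregation_percent(m: int) -> str:
    """Chance-cosegregation probability rendered as a percentage, e.g. ``12.5%``."""
    return f"{cosegregation_probability(m) * 100:.1f}%"
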