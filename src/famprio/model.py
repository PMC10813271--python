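"""Core domain types for family-based variant prioritization.

The pipeline works on four kinds of objects: biallelic variant sites
(:class:`VariantRecord`), a per-variant x per-sample alternate-allele
count matrix (:class:`GenotypeMatrix`), functional/population annotation
for each variant (:class:`AnnotationRecord`), and the family structure
with affection status (:class:`Pedigree`).  The cascade's output is a
:class:`CandidateTable` carrying per-stage audit counts alongside the
surviving, scored, ranked candidates.

Genotypes are coded as alternate-allele counts 0/1/2; a missing call is
the distinct sentinel :data:`MISSING` (never coerced to 0 — downstream
filters treat missingness explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Sentinel for an uncalled genotype.  Distinct from 0 (homozygous reference).
MISSING: int = -1

VALID_CALLS = frozenset({0, 1, 2, MISSING})

REGION_CATEGORIES = frozenset(
    {"exonic", "splicing", "intronic", "UTR3", "UTR5", "intergenic", "ncRNA", "other"}
)
FUNCTION_CATEGORIES = frozenset(
    {
        "nonsynonymous_SNV",
        "synonymous_SNV",
        "stopgain",
        "stoploss",
        "frameshift",
        "nonframeshift",
        "unknown",
    }
)
SIFT_PREDS = frozenset({"D", "T"})
PP2_PREDS = frozenset({"D", "P", "B"})
MT_PREDS = frozenset({"A", "D", "N", "P"})

_ALLELE_ALPHABET = frozenset("ACGT")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr14`` and ``14`` share an identity."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic substitution site (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele:
                raise ValueError(f"{name} allele is empty at {self.chrom}:{self.pos}")
            if not set(allele) <= _ALLELE_ALPHABET:
                raise ValueError(
                    f"{name} allele {allele!r} at {self.chrom}:{self.pos} is not an A/C/G/T string"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def vid(self) -> str:
        """Stable identity key: ``<chrom-without-chr>:<pos>:<ref>:<alt>``."""
        return f"{normalize_chrom(self.chrom)}:{self.pos}:{self.ref}:{self.alt}"


class GenotypeMatrix:
    """Alt-allele counts for an ordered variant set over an ordered sample set.

    Calls are stored as an int8 array with values in {0, 1, 2, MISSING}.
    """

    def __init__(
        self,
        vids: Sequence[str],
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        vids = list(vids)
        samples = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(vids), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} does not match {len(vids)} variants x {len(samples)} samples"
            )
        if len(set(vids)) != len(vids):
            dupes = sorted({v for v in vids if vids.count(v) > 1})
            raise ValueError(f"duplicate variant ids: {dupes}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        bad = set(np.unique(calls)) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        self.vids = vids
        self.samples = samples
        self.calls = calls
        self._vidx = {v: i for i, v in enumerate(vids)}
        self._sidx = {s: i for i, s in enumerate(samples)}

    @property
    def n_variants(self) -> int:
        return len(self.vids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_index(self, vid: str) -> int:
        try:
            return self._vidx[vid]
        except KeyError:
            raise KeyError(f"unknown variant id {vid!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self._sidx[sample]
        except KeyError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def call(self, vid: str, sample: str) -> int:
        return int(self.calls[self.variant_index(vid), self.sample_index(sample)])

    def row(self, vid: str) -> np.ndarray:
        """Calls for one variant across all samples."""
        return self.calls[self.variant_index(vid)]

    def sample_columns(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Column indices for the given sample ids (errors on unknown ids)."""
        return np.array([self.sample_index(s) for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = self.sample_columns(sample_ids)
        return GenotypeMatrix(self.vids, list(sample_ids), self.calls[:, cols])


def _check_unit_interval(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value} outside [0, 1]")


@dataclass
class AnnotationRecord:
    """Functional and population-frequency annotation for one variant.

    Population allele frequencies come from catalogue columns (overall and
    East-Asian subsets of 1000 Genomes and ExAC style resources); predictor
    scores/calls are SIFT, PolyPhen2-HDIV and MutationTaster as shipped by
    dbNSFP-style annotation.  ``None`` encodes NA throughout.
    """

    vid: str
    gene: str
    region: str
    function: str
    af_1000g_all: Optional[float] = None
    af_1000g_eas: Optional[float] = None
    af_exac_all: Optional[float] = None
    af_exac_eas: Optional[float] = None
    sift_score: Optional[float] = None
    sift_pred: Optional[str] = None
    pp2_hdiv_score: Optional[float] = None
    pp2_hdiv_pred: Optional[str] = None
    mt_score: Optional[float] = None
    mt_pred: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region not in REGION_CATEGORIES:
            raise ValueError(f"unknown region category {self.region!r} for {self.vid}")
        if self.function not in FUNCTION_CATEGORIES:
            raise ValueError(f"unknown function category {self.function!r} for {self.vid}")
        for name in ("af_1000g_all", "af_1000g_eas", "af_exac_all", "af_exac_eas",
                     "sift_score", "pp2_hdiv_score", "mt_score"):
            _check_unit_interval(name, getattr(self, name))
        for name, valid in (("sift_pred", SIFT_PREDS), ("pp2_hdiv_pred", PP2_PREDS),
                            ("mt_pred", MT_PREDS)):
            v = getattr(self, name)
            if v is not None and v not in valid:
                raise ValueError(f"unknown {name} value {v!r} for {self.vid}")

    def af_values(self, fields: Iterable[str]) -> list[float]:
        """Non-NA values of the requested frequency fields."""
        out = []
        for f in fields:
            v = getattr(self, f)
            if v is not None:
                out.append(v)
        return out


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affection: str  # "affected" | "unaffected" | "unknown"


class Pedigree:
    """Family members with parent links, sex, affection and control designations.

    ``controls`` are unaffected members explicitly used to exclude shared
    variants during filtering (e.g. an elderly unaffected relative).
    """

    def __init__(self, members: Sequence[PedigreeMember], controls: Iterable[str] = ()) -> None:
        self.members: dict[str, PedigreeMember] = {}
        for m in members:
            if m.id in self.members:
                raise ValueError(f"duplicate member id {m.id!r}")
            if m.affection not in ("affected", "unaffected", "unknown"):
                raise ValueError(f"bad affection {m.affection!r} for {m.id}")
            self.members[m.id] = m
        for m in self.members.values():
            for parent in (m.father, m.mother):
                if parent is not None and parent not in self.members:
                    raise ValueError(f"member {m.id!r} references unknown parent {parent!r}")
        self._check_acyclic()
        self.controls = frozenset(controls)
        for c in self.controls:
            if c not in self.members:
                raise ValueError(f"control {c!r} is not a pedigree member")
            if self.members[c].affection != "unaffected":
                raise ValueError(f"control {c!r} is not unaffected")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(mid: str, stack: tuple[str, ...]) -> None:
            if mid in stack:
                raise ValueError(f"member {mid!r} is its own ancestor")
            if state.get(mid) == 1:
                return
            m = self.members[mid]
            for parent in (m.father, m.mother):
                if parent is not None:
                    visit(parent, stack + (mid,))
            state[mid] = 1

        for mid in self.members:
            visit(mid, ())

    def __contains__(self, mid: str) -> bool:
        return mid in self.members

    def __len__(self) -> int:
        return len(self.members)

    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members.values() if m.affection == "affected"]

    def unaffected_ids(self) -> list[str]:
        return [m.id for m in self.members.values() if m.affection == "unaffected"]

    def parents_of(self, mid: str) -> tuple[Optional[str], Optional[str]]:
        m = self.members[mid]
        return m.father, m.mother

    def is_founder(self, mid: str) -> bool:
        m = self.members[mid]
        return m.father is None and m.mother is None

    def topological_order(self) -> list[str]:
        """Member ids ordered so every parent precedes its children."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(mid: str) -> None:
            if mid in seen:
                return
            m = self.members[mid]
            for parent in (m.father, m.mother):
                if parent is not None:
                    visit(parent)
            seen.add(mid)
            order.append(mid)

        for mid in self.members:
            visit(mid)
        return order


@dataclass
class CandidateRow:
    vid: str
    gene: str
    annotation: AnnotationRecord
    hazard_score: float
    rank: int = 0


@dataclass
class CandidateTable:
    """Ranked cascade survivors plus the per-stage audit trail."""

    rows: list[CandidateRow] = field(default_factory=list)
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    segregation: dict[str, "object"] = field(default_factory=dict)
    audit_log: list[str] = field(default_factory=list)

    def validate(self) -> None:
        counts = [n for _, n in self.stage_counts]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"stage counts increase along the cascade: {self.stage_counts}")
        ranks = sorted(r.rank for r in self.rows)
        if ranks != list(range(1, len(self.rows) + 1)):
            raise ValueError(f"ranks are not a permutation of 1..n: {ranks}")

    def genes(self) -> list[str]:
        return [r.gene for r in self.rows]

    def vids(self) -> list[str]:
        return [r.vid for r in self.rows]
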