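"""Seeded generator of complete synthetic family exome studies.

Emulates the statistical structure the filter cascade assumes: a fully
penetrant autosomal-dominant causal variant planted in an affected
founder of a two-generation family and transmitted by Mendelian rules;
a background of common, rare and uncatalogued variants with founder
genotypes drawn from Hardy-Weinberg proportions; and predictor-score
distributions that exercise every classification band (benign-leaning
for background variants, deleterious-leaning for the causal one).

Every draw flows from a single integer seed, and a fixed config + seed
produces byte-identical output files, so generated studies double as
regression fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import reference_study as ref
from .io import write_annotations, write_ped, write_vcf
from .model import (
    MISSING,
    AnnotationRecord,
    GenotypeMatrix,
    Pedigree,
    PedigreeMember,
    VariantRecord,
)

_DEFAULT_REGION_PROBS = {
    "exonic": 0.55,
    "splicing": 0.02,
    "intronic": 0.20,
    "UTR3": 0.08,
    "UTR5": 0.05,
    "ncRNA": 0.05,
    "intergenic": 0.05,
}

# rng stream tags: one independent stream per simulation stage
_STREAM_VARIANTS, _STREAM_GENOTYPES, _STREAM_ANNOTATIONS, _STREAM_COHORT = range(4)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic family-exome study.

    Background variants carry a catalogue-frequency class drawn from
    ``background_af_weights`` over (uncatalogued NA, rare (0, 0.001],
    common (0.001, 0.2]); uncatalogued variants segregate at founder
    frequency ``na_founder_af`` (absence from a catalogue means "not
    seen", not "impossible").  ``penetrance`` is the probability that a
    causal-allele carrier is affected; at 1.0 the template's affection
    states force the carrier set exactly.
    """

    pedigree_template: str = "reference"
    custom_members: Optional[Sequence[PedigreeMember]] = None
    genotyped_ids: Optional[Sequence[str]] = None
    n_background: int = 5000
    causal_present: bool = True
    causal_variant: VariantRecord = field(default_factory=lambda: ref.CAUSAL_VARIANT)
    carrier_founder: str = "II3"
    penetrance: float = 1.0
    background_af_weights: tuple[float, float, float] = (0.1, 0.2, 0.7)
    na_founder_af: float = 0.0005
    rare_af_max: float = 0.001
    common_af_max: float = 0.2
    region_probs: dict = field(default_factory=lambda: dict(_DEFAULT_REGION_PROBS))
    synonymous_prob: float = 0.4
    stopgain_prob: float = 0.02
    predictor_na_prob: float = 0.05
    causal_mt_d_prob: float = 0.9
    missing_rate: float = 0.0
    cohort_n_samples: int = 248
    cohort_carrier_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.background_af_weights) - 1.0) > 1e-9:
            raise ValueError("background_af_weights must sum to 1")
        if abs(sum(self.region_probs.values()) - 1.0) > 1e-9:
            raise ValueError("region_probs must sum to 1")
        for name in ("penetrance", "synonymous_prob", "stopgain_prob",
                     "predictor_na_prob", "causal_mt_d_prob", "missing_rate",
                     "cohort_carrier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated study's planted causal variant."""

    causal_vid: str
    carrier_ids: list[str]
    expected_segregation: bool

    def to_dict(self) -> dict:
        return {
            "causal_vid": self.causal_vid,
            "carrier_ids": self.carrier_ids,
            "expected_segregation": self.expected_segregation,
        }


@dataclass
class SimulatedStudy:
    """An in-memory synthetic study, ready for the cascade."""

    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    annotations: dict[str, AnnotationRecord]
    pedigree: Pedigree
    truth: Optional[TruthRecord]
    sim_afs: dict[str, float]
    cohort: GenotypeMatrix


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Build the study pedigree from the configured template.

    The default template is the bundled two-generation FNMTC family
    (four affected, elderly control, unaffected sibling); custom
    member lists build arbitrary families.
    """
    if config.pedigree_template == "reference":
        return ref.reference_pedigree()
    if config.pedigree_template == "custom":
        if not config.custom_members:
            raise ValueError("custom template requires custom_members")
        controls = [
            m.id for m in config.custom_members if m.affection == "unaffected"
        ][:1]
        return Pedigree(list(config.custom_members), controls=controls)
    raise ValueError(f"unknown pedigree template {config.pedigree_template!r}")


def simulate_variants(
    config: SimulationConfig, seed: int
) -> tuple[list[VariantRecord], np.ndarray, np.ndarray]:
    """Draw the variant set: positions, alleles, and per-variant founder AFs.

    Returns (variants, founder allele frequencies, catalogue-class codes)
    with class 0 = uncatalogued, 1 = rare, 2 = common.  The causal
    variant, when present, is the last entry (class -1).  Positions are
    unique by construction: strictly increasing offsets per chromosome.
    """
    rng = _rng(seed, _STREAM_VARIANTS)
    n = config.n_background
    chroms = [f"chr{(i % 22) + 1}" for i in range(n)]
    gaps = rng.integers(1, 50_000, size=n)
    pos_counter: dict[str, int] = {}
    positions = []
    for c, g in zip(chroms, gaps):
        pos_counter[c] = pos_counter.get(c, 1_000_000) + int(g)
        positions.append(pos_counter[c])
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_shift) % 4

    klass = rng.choice(3, size=n, p=list(config.background_af_weights))
    afs = np.empty(n)
    afs[klass == 0] = config.na_founder_af
    n_rare = int((klass == 1).sum())
    n_common = int((klass == 2).sum())
    afs[klass == 1] = rng.uniform(0.0, config.rare_af_max, size=n_rare)
    afs[klass == 2] = rng.uniform(config.rare_af_max, config.common_af_max, size=n_common)

    variants = [
        VariantRecord(c, p, bases[r], bases[a])
        for c, p, r, a in zip(chroms, positions, ref_idx, alt_idx)
    ]
    if config.causal_present:
        variants.append(config.causal_variant)
        afs = np.append(afs, 0.0)  # never drawn in founders; planted explicitly
        klass = np.append(klass, -1)
    return variants, afs, klass


def simulate_genotypes(
    ped: Pedigree,
    config: SimulationConfig,
    seed: int,
    variants: Optional[list[VariantRecord]] = None,
    afs: Optional[np.ndarray] = None,
) -> tuple[GenotypeMatrix, list[VariantRecord], dict[str, float], Optional[TruthRecord]]:
    """Simulate genotypes for every pedigree member, then restrict to the genotyped set.

    Founder genotypes are Hardy-Weinberg draws at each variant's founder
    frequency; a missing parent contributes a population allele.  The
    causal variant is planted heterozygous in the affected members (an
    affected individual is a carrier under the no-phenocopy dominant
    model); an unaffected child of a carrier is a silent carrier with
    probability (1 - penetrance) / (2 - penetrance), the Mendelian
    carrier probability conditioned on being unaffected.
    """
    if variants is None:
        variants, afs, _ = simulate_variants(config, seed)
    assert afs is not None
    rng = _rng(seed, _STREAM_GENOTYPES)
    order = ped.topological_order()
    n = len(variants)
    calls: dict[str, np.ndarray] = {}
    for mid in order:
        father, mother = ped.parents_of(mid)
        total = np.zeros(n, dtype=np.int8)
        for parent in (father, mother):
            if parent is None:
                total += rng.binomial(1, afs).astype(np.int8)
            else:
                total += rng.binomial(1, calls[parent] / 2.0).astype(np.int8)
        calls[mid] = total

    truth: Optional[TruthRecord] = None
    if config.causal_present:
        ci = n - 1
        causal_vid = variants[ci].vid
        silent_p = (
            (1.0 - config.penetrance) / (2.0 - config.penetrance)
            if config.penetrance < 1.0
            else 0.0
        )
        planted: dict[str, int] = {}
        for mid in order:
            member = ped.members[mid]
            if member.affection == "affected":
                planted[mid] = 1
            else:
                father, mother = ped.parents_of(mid)
                parent_carrier = any(
                    p is not None and planted.get(p, 0) >= 1 for p in (father, mother)
                )
                planted[mid] = (
                    1 if parent_carrier and rng.random() < silent_p else 0
                )
            calls[mid][ci] = planted[mid]
        carriers = [mid for mid in order if planted[mid] >= 1]
        truth = TruthRecord(causal_vid=causal_vid, carrier_ids=sorted(carriers),
                            expected_segregation=True)  # refined below

    genotyped = list(config.genotyped_ids or
                     (ref.GENOTYPED_MEMBERS if config.pedigree_template == "reference"
                      else ped.members.keys()))
    matrix = np.stack([calls[mid] for mid in genotyped], axis=1)
    if config.missing_rate > 0:
        mask = rng.random(matrix.shape) < config.missing_rate
        matrix = np.where(mask, np.int8(MISSING), matrix).astype(np.int8)
    gt = GenotypeMatrix([v.vid for v in variants], genotyped, matrix)

    if truth is not None:
        affected = [m for m in ped.affected_ids() if m in genotyped]
        controls = [c for c in ped.controls if c in genotyped]
        ok_affected = all(gt.call(truth.causal_vid, s) in (1, 2) for s in affected)
        ok_controls = all(gt.call(truth.causal_vid, s) not in (1, 2) for s in controls)
        truth.expected_segregation = ok_affected and ok_controls
    return gt, variants, {v.vid: float(a) for v, a in zip(variants, afs)}, truth


def _band_sift(rng: np.random.Generator) -> float:
    # benign-leaning: 10% of background draws land in the deleterious band
    if rng.random() < 0.1:
        return float(rng.uniform(0.0, 0.05))
    return float(rng.uniform(0.05, 1.0))


def _band_pp2(rng: np.random.Generator) -> float:
    u = rng.random()
    if u < 0.80:
        return float(rng.uniform(0.0, 0.452))
    if u < 0.95:
        return float(rng.uniform(0.453, 0.956))
    return float(rng.uniform(0.957, 1.0))


_MT_BACKGROUND = (("N", 0.85), ("D", 0.10), ("P", 0.04), ("A", 0.01))


def simulate_annotations(
    variants: list[VariantRecord],
    truth: Optional[TruthRecord],
    config: SimulationConfig,
    seed: int,
    sim_afs: Optional[dict[str, float]] = None,
    uncatalogued: Optional[set[str]] = None,
) -> dict[str, AnnotationRecord]:
    """Draw annotation records consistent with each variant's simulated class.

    The causal variant is exonic nonsynonymous with all catalogue
    frequencies NA and a deleterious predictor profile (SIFT in the
    deleterious band, PolyPhen2 probably-damaging, MutationTaster
    disease-causing with high probability).  Background variants draw
    regions/functions from the configured mixtures, catalogue AFs equal
    to their simulated founder frequency (NA for the uncatalogued
    class), and benign-leaning predictor scores.
    """
    rng = _rng(seed, _STREAM_ANNOTATIONS)
    regions = list(config.region_probs)
    region_p = [config.region_probs[r] for r in regions]
    out: dict[str, AnnotationRecord] = {}
    causal_vid = truth.causal_vid if truth is not None else None
    for i, v in enumerate(variants):
        if v.vid == causal_vid:
            sift = float(rng.uniform(0.0, 0.05))
            pp2 = float(rng.uniform(0.957, 1.0))
            mt_pred = "D" if rng.random() < config.causal_mt_d_prob else "N"
            out[v.vid] = AnnotationRecord(
                vid=v.vid, gene=f"GENE{i:05d}", region="exonic",
                function="nonsynonymous_SNV",
                sift_score=sift, sift_pred="D",
                pp2_hdiv_score=pp2, pp2_hdiv_pred="D",
                mt_score=float(rng.uniform(0.9, 1.0)), mt_pred=mt_pred,
            )
            continue
        region = regions[int(rng.choice(len(regions), p=region_p))]
        if region in ("exonic", "splicing"):
            u = rng.random()
            if u < config.synonymous_prob:
                function = "synonymous_SNV"
            elif u < config.synonymous_prob + config.stopgain_prob:
                function = "stopgain"
            else:
                function = "nonsynonymous_SNV"
        else:
            function = "unknown"
        af = sim_afs.get(v.vid) if sim_afs else None
        catalogued = af is not None and (uncatalogued is None or v.vid not in uncatalogued)
        af_value = float(af) if catalogued else None

        sift_s = None if rng.random() < config.predictor_na_prob else _band_sift(rng)
        pp2_s = None if rng.random() < config.predictor_na_prob else _band_pp2(rng)
        if rng.random() < config.predictor_na_prob:
            mt_pred, mt_s = None, None
        else:
            u = rng.random()
            acc = 0.0
            mt_pred = "N"
            for pred, p in _MT_BACKGROUND:
                acc += p
                if u < acc:
                    mt_pred = pred
                    break
            mt_s = float(rng.uniform(0.5, 1.0))
        out[v.vid] = AnnotationRecord(
            vid=v.vid, gene=f"GENE{i:05d}", region=region, function=function,
            af_1000g_all=af_value, af_1000g_eas=af_value,
            af_exac_all=af_value, af_exac_eas=af_value,
            sift_score=sift_s,
            sift_pred=None if sift_s is None else ("D" if sift_s <= 0.05 else "T"),
            pp2_hdiv_score=pp2_s,
            pp2_hdiv_pred=None if pp2_s is None else (
                "D" if pp2_s >= 0.957 else ("P" if pp2_s >= 0.453 else "B")
            ),
            mt_score=mt_s, mt_pred=mt_pred,
        )
    return out


def simulate_cohort(config: SimulationConfig, seed: int) -> GenotypeMatrix:
    """A sporadic-case cohort genotyped at the causal site.

    Each sample is an independent heterozygous carrier with probability
    ``cohort_carrier_rate`` (0 by default: the variant is family-private).
    """
    rng = _rng(seed, _STREAM_COHORT)
    samples = [f"SP{i + 1:04d}" for i in range(config.cohort_n_samples)]
    if config.causal_present:
        calls = rng.binomial(1, config.cohort_carrier_rate,
                             size=(1, len(samples))).astype(np.int8)
        return GenotypeMatrix([config.causal_variant.vid], samples, calls)
    return GenotypeMatrix([], samples, np.empty((0, len(samples)), dtype=np.int8))


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Generate a complete in-memory study (pedigree, genotypes, annotations, cohort)."""
    ped = simulate_pedigree(config)
    variants, afs, klass = simulate_variants(config, seed)
    gt, variants, sim_afs, truth = simulate_genotypes(ped, config, seed, variants, afs)
    uncatalogued = {v.vid for v, k in zip(variants, klass) if k == 0}
    annotations = simulate_annotations(variants, truth, config, seed, sim_afs, uncatalogued)
    cohort = simulate_cohort(config, seed)
    return SimulatedStudy(
        variants=variants, genotypes=gt, annotations=annotations,
        pedigree=ped, truth=truth, sim_afs=sim_afs, cohort=cohort,
    )


def generate_study(config: SimulationConfig, seed: int, out_dir) -> dict[str, Path]:
    """Write a complete runnable study to ``out_dir``.

    Emits ``study.vcf`` (family genotypes), ``family.ped``,
    ``annotations.tsv``, ``cohort.vcf`` and ``truth.json``; returns the
    paths.  Fixed config + seed yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config, seed)
    paths = {
        "vcf": out / "study.vcf",
        "ped": out / "family.ped",
        "annotations": out / "annotations.tsv",
        "cohort_vcf": out / "cohort.vcf",
        "truth": out / "truth.json",
    }
    write_vcf(study.variants, study.genotypes, paths["vcf"])
    write_ped(study.pedigree, paths["ped"])
    write_annotations(study.annotations, paths["annotations"])
    cohort_variants = (
        [config.causal_variant] if config.causal_present else []
    )
    write_vcf(cohort_variants, study.cohort, paths["cohort_vcf"])
    truth_payload = study.truth.to_dict() if study.truth else {}
    paths["truth"].write_text(json.dumps(truth_payload, indent=2) + "\n")
    return paths
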