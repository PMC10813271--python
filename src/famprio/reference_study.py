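"""Bundled reference study: a familial non-medullary thyroid carcinoma pedigree.

A two-generation FNMTC family in which four relatives (II3 and her three
children III3, III5, III7) have papillary thyroid carcinoma, with an
elderly unaffected relative (II2) serving as the filtering control and
an unaffected sibling (III9) as a validation control.  Six members were
exome-sequenced.  Twelve exonic nonsynonymous candidate variants shared
by all four patients (and absent from II2) enter allele-frequency
screening; seven exceed the East-Asian rarity threshold of 0.001 and
five remain, led by a private missense substitution in PPP4R3A
(chr14:91942196 C>T, p.Asp409Asn).

The tables here are the package's worked example and regression fixture;
every value is used as input, never recomputed.
"""

from __future__ import annotations

import numpy as np

from .cascade import CascadeConfig
from .model import (
    AnnotationRecord,
    GenotypeMatrix,
    Pedigree,
    PedigreeMember,
    VariantRecord,
)

#: Family members: four affected (II3 and children III3/III5/III7), the
#: elderly control II2, the unaffected sibling III9, plus the paternal
#: line (I4, II4) confirmed wild type by targeted sequencing.
PEDIGREE_MEMBERS = [
    PedigreeMember("I4", None, None, "male", "unaffected"),
    PedigreeMember("II2", None, None, "female", "unaffected"),
    PedigreeMember("II3", None, None, "female", "affected"),
    PedigreeMember("II4", "I4", None, "male", "unaffected"),
    PedigreeMember("III3", "II4", "II3", "male", "affected"),
    PedigreeMember("III5", "II4", "II3", "female", "affected"),
    PedigreeMember("III7", "II4", "II3", "female", "affected"),
    PedigreeMember("III9", "II4", "II3", "male", "unaffected"),
]

GENOTYPED_MEMBERS = ["II2", "II3", "III3", "III5", "III7", "III9"]
AFFECTED_MEMBERS = ["II3", "III3", "III5", "III7"]
CASCADE_CONTROLS = ["II2"]        # used during filtering
VALIDATION_CONTROLS = ["III9"]    # checked after filtering

#: The causal candidate: PPP4R3A missense substitution p.Asp409Asn.
CAUSAL_VARIANT = VariantRecord("chr14", 91942196, "C", "T")

# gene, chrom, pos, ref, alt, region,
# af_1000g_all, af_1000g_eas, af_exac_all, af_exac_eas,
# sift_score, sift_pred, pp2_score, pp2_pred, mt_score, mt_pred
_CANDIDATES = [
    ("PPP4R3A", "chr14", 91942196, "C", "T", "exonic",
     None, None, None, None, 0.24, "T", 1.0, "D", 1.0, "D"),
    ("MANSC1", "chr12", 12483454, "G", "C", "exonic",
     None, None, 0.0, 0.0001, 0.016, "D", 0.025, "B", 1.0, "N"),
    ("IQSEC3", "chr12", 283790, "C", "T", "exonic",
     None, None, 0.0, 0.0001, 0.001, "D", 0.961, "D", 1.0, "D"),
    ("MYL1", "chr2", 211179708, "G", "A", "exonic",
     0.0002, None, 0.0, 0.0006, 0.007, "D", 0.702, "P", 1.0, "D"),
    ("VWF", "chr12", 6153513, "C", "T", "exonic",
     None, None, 0.0, 0.0003, 0.017, "D", 0.999, "D", 1.0, "D"),
    ("DUSP16", "chr12", 12630669, "C", "T", "exonic",
     0.013, 0.005, 0.026, 0.013, None, None, 0.005, "B", 1.0, "N"),
    ("CHD4", "chr12", 6711144, "A", "C", "exonic",
     0.0074, 0.034, 0.013, 0.0093, 0.267, "T", 0.0, "B", 0.939, "N"),
    ("SSPO", "chr7", 149475053, "C", "T", "exonic",
     0.004, 0.018, 0.001, 0.012, None, None, 0.001, "B", None, None),
    ("NLRP9", "chr19", 56228104, "C", "T", "exonic",
     0.0026, 0.013, 0.0013, 0.018, 0.54, "T", 0.059, "B", 1.0, "N"),
    ("ANO2", "chr12", 5853474, "C", "T", "exonic",
     0.015, 0.025, 0.0059, 0.024, 0.973, "T", 0.285, "B", 1.0, "D"),
    ("CTBS", "chr1", 85029077, "C", "T", "exonic",
     0.15, 0.03, 0.2, 0.032, 0.109, "T", 0.489, "P", 0.017, "P"),
    ("OR51B4", "chr11", 5322776, "G", "A", "exonic",
     0.01, 0.044, 0.0049, 0.041, 0.012, "D", 0.185, "B", 1.0, "N"),
]

#: Genes retained by the rarity filter, in the study's reporting order,
#: with their composite hazard scores.
RETAINED_GENES = ["PPP4R3A", "MANSC1", "IQSEC3", "MYL1", "VWF"]
RETAINED_HAZARD_SCORES = [2.0, 1.0, 3.0, 2.5, 3.0]
EXCLUDED_GENES = ["DUSP16", "CHD4", "SSPO", "NLRP9", "ANO2", "CTBS", "OR51B4"]


def reference_pedigree() -> Pedigree:
    return Pedigree(PEDIGREE_MEMBERS, controls=CASCADE_CONTROLS)


def reference_variants() -> list[VariantRecord]:
    return [VariantRecord(row[1], row[2], row[3], row[4]) for row in _CANDIDATES]


def reference_genotypes() -> GenotypeMatrix:
    """Genotypes of the six sequenced members for the twelve candidates.

    All twelve are heterozygous in every patient and absent from the
    unaffected members — the sharing pattern that defines the candidate
    set entering frequency screening.
    """
    variants = reference_variants()
    calls = np.zeros((len(variants), len(GENOTYPED_MEMBERS)), dtype=np.int8)
    for s in AFFECTED_MEMBERS:
        calls[:, GENOTYPED_MEMBERS.index(s)] = 1
    return GenotypeMatrix([v.vid for v in variants], GENOTYPED_MEMBERS, calls)


def reference_annotations() -> dict[str, AnnotationRecord]:
    out: dict[str, AnnotationRecord] = {}
    for row in _CANDIDATES:
        (gene, chrom, pos, ref, alt, region,
         g_all, g_eas, x_all, x_eas,
         sift_s, sift_p, pp2_s, pp2_p, mt_s, mt_p) = row
        rec = AnnotationRecord(
            vid=VariantRecord(chrom, pos, ref, alt).vid,
            gene=gene,
            region=region,
            function="nonsynonymous_SNV",
            af_1000g_all=g_all,
            af_1000g_eas=g_eas,
            af_exac_all=x_all,
            af_exac_eas=x_eas,
            sift_score=sift_s,
            sift_pred=sift_p,
            pp2_hdiv_score=pp2_s,
            pp2_hdiv_pred=pp2_p,
            mt_score=mt_s,
            mt_pred=mt_p,
        )
        out[rec.vid] = rec
    return out


def reference_config() -> CascadeConfig:
    return CascadeConfig(
        affected_ids=tuple(AFFECTED_MEMBERS),
        control_ids=tuple(CASCADE_CONTROLS),
    )


def reference_study() -> tuple[list[VariantRecord], GenotypeMatrix, dict[str, AnnotationRecord], Pedigree, CascadeConfig]:
    """The full reference inputs, ready for :func:`famprio.cascade.run_cascade`."""
    return (
        reference_variants(),
        reference_genotypes(),
        reference_annotations(),
        reference_pedigree(),
        reference_config(),
    )
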