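"""Readers and writers for the pipeline's file formats.

Supported formats: a VCF 4.x subset (biallelic sites, GT genotypes), the
six-column pre-MAKEPED PED dialect, a flat annotation TSV mirroring the
dbNSFP-style column set, a population frequency TSV, and the candidate
table TSV with its JSON audit sidecar.  The NA token is always the
literal string ``NA`` (case-insensitive on input).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
from cyvcf2 import VCF

from .model import (
    MISSING,
    AnnotationRecord,
    CandidateRow,
    CandidateTable,
    GenotypeMatrix,
    Pedigree,
    PedigreeMember,
    VariantRecord,
)

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = [
    "vid", "gene", "region", "function",
    "af_1000g_all", "af_1000g_eas", "af_exac_all", "af_exac_eas",
    "sift_score", "sift_pred", "pp2_hdiv_score", "pp2_hdiv_pred",
    "mt_score", "mt_pred",
]

_NUMERIC_COLUMNS = {
    "af_1000g_all", "af_1000g_eas", "af_exac_all", "af_exac_eas",
    "sift_score", "pp2_hdiv_score", "mt_score",
}


def _is_na(token: str) -> bool:
    return token == "" or token.upper() == "NA"


def read_vcf(path: PathLike) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Parse a biallelic VCF into variant records and a genotype matrix.

    GT is required in FORMAT.  ``0/0`` -> 0, ``0/1``/``1/0`` -> 1,
    ``1/1`` -> 2, ``./.`` -> MISSING; phased separators are treated as
    unphased.  Multiallelic ALT fields and duplicate variant identities
    are errors (splitting is deliberately not performed).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    for v in vcf:
        where = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic site at {where} (ALT={','.join(v.ALT)}); split upstream")
        if "GT" not in (v.FORMAT or []):
            raise ValueError(f"no GT key in FORMAT at {where}")
        rec = VariantRecord(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0])
        if rec.vid in seen:
            raise ValueError(f"duplicate variant identity {rec.vid} at {where}")
        seen.add(rec.vid)
        variants.append(rec)
        calls = []
        for g in v.genotypes:  # [allele0, allele1, phased]
            a0, a1 = g[0], g[1]
            calls.append(MISSING if a0 < 0 or a1 < 0 else a0 + a1)
        rows.append(calls)
    vcf.close()
    calls_arr = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    gt = GenotypeMatrix([v.vid for v in variants], samples, calls_arr)
    return variants, gt


_PED_SEX = {"1": "male", "2": "female", "0": "unknown", "-9": "unknown"}
_PED_AFFECTION = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_SEX_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFFECTION_PED = {"affected": "2", "unaffected": "1", "unknown": "0"}


def read_ped(path: PathLike, controls: tuple[str, ...] = ()) -> Pedigree:
    """Parse a six-column whitespace-delimited PED file.

    Columns: family, individual, father, mother, sex, phenotype
    (2 = affected, 1 = unaffected, 0/-9 = unknown).  A ``0`` parent is
    recorded as no link.
    """
    members: list[PedigreeMember] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
        _fam, mid, father, mother, sex, pheno = fields[:6]
        if sex not in _PED_SEX:
            raise ValueError(f"PED line {lineno}: bad sex code {sex!r}")
        if pheno not in _PED_AFFECTION:
            raise ValueError(f"PED line {lineno}: bad phenotype code {pheno!r}")
        members.append(
            PedigreeMember(
                id=mid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=_PED_SEX[sex],
                affection=_PED_AFFECTION[pheno],
            )
        )
    return Pedigree(members, controls=controls)


def write_ped(ped: Pedigree, path: PathLike, family_id: str = "FAM1") -> None:
    lines = []
    for m in ped.members.values():
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.id,
                    m.father or "0",
                    m.mother or "0",
                    _SEX_PED[m.sex],
                    _AFFECTION_PED[m.affection],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_annotation_row(fields: dict[str, str], lineno: int) -> AnnotationRecord:
    kwargs: dict[str, object] = {}
    for col in ANNOTATION_COLUMNS:
        token = fields[col].strip()
        if col in ("vid", "gene", "region", "function"):
            kwargs[col] = token
            continue
        if _is_na(token):
            kwargs[col] = None
        elif col in _NUMERIC_COLUMNS:
            try:
                value = float(token)
            except ValueError:
                raise ValueError(f"annotation line {lineno}, column {col}: bad number {token!r}") from None
            kwargs[col] = value
        else:
            kwargs[col] = token
    try:
        return AnnotationRecord(**kwargs)  # type: ignore[arg-type]
    except ValueError as exc:
        raise ValueError(f"annotation line {lineno}: {exc}") from None


def read_annotations(path: PathLike) -> dict[str, AnnotationRecord]:
    """Parse the annotation TSV into a vid -> record mapping."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise ValueError("empty annotation file")
    header = text[0].rstrip("\n").split("\t")
    if header != ANNOTATION_COLUMNS:
        raise ValueError(
            f"annotation header mismatch: expected {ANNOTATION_COLUMNS}, got {header}"
        )
    out: dict[str, AnnotationRecord] = {}
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        values = line.split("\t")
        if len(values) != len(header):
            raise ValueError(f"annotation line {lineno}: expected {len(header)} columns")
        rec = _parse_annotation_row(dict(zip(header, values)), lineno)
        if rec.vid in out:
            raise ValueError(f"annotation line {lineno}: duplicate vid {rec.vid}")
        out[rec.vid] = rec
    return out


def _fmt(value: Optional[object]) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value) if value != int(value) else str(int(value))
    return str(value)


def write_annotations(records: dict[str, AnnotationRecord], path: PathLike) -> None:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for rec in records.values():
        lines.append("\t".join(_fmt(getattr(rec, col)) for col in ANNOTATION_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


CANDIDATE_COLUMNS = ANNOTATION_COLUMNS + ["hazard_score", "rank"]


def write_candidates(table: CandidateTable, path: PathLike) -> None:
    """Write the candidate TSV plus a ``<path>.stages.json`` audit sidecar.

    The sidecar carries stage survivor counts, per-candidate segregation
    results and the cascade's audit log lines.
    """
    table.validate()
    path = Path(path)
    lines = ["\t".join(CANDIDATE_COLUMNS)]
    for row in table.rows:
        fields = [_fmt(getattr(row.annotation, col)) for col in ANNOTATION_COLUMNS]
        fields += [_fmt(row.hazard_score), str(row.rank)]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "stage_counts": [[name, n] for name, n in table.stage_counts],
        "segregation": {
            vid: {
                "segregates": seg.segregates,
                "affected_carriers": seg.affected_carriers,
                "control_carriers": seg.control_carriers,
                "informative_meioses": seg.informative_meioses,
            }
            for vid, seg in table.segregation.items()
        },
        "audit_log": table.audit_log,
    }
    Path(str(path) + ".stages.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_candidates(path: PathLike) -> CandidateTable:
    """Read back a candidate TSV (and its sidecar, if present)."""
    text = Path(path).read_text().splitlines()
    header = text[0].split("\t")
    if header != CANDIDATE_COLUMNS:
        raise ValueError(f"candidate header mismatch: got {header}")
    rows: list[CandidateRow] = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        values = line.split("\t")
        fields = dict(zip(header, values))
        ann = _parse_annotation_row(fields, lineno)
        rows.append(
            CandidateRow(
                vid=ann.vid,
                gene=ann.gene,
                annotation=ann,
                hazard_score=float(fields["hazard_score"]),
                rank=int(fields["rank"]),
            )
        )
    table = CandidateTable(rows=rows)
    sidecar = Path(str(path) + ".stages.json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        table.stage_counts = [(name, n) for name, n in data.get("stage_counts", [])]
        table.audit_log = list(data.get("audit_log", []))
    return table


def read_population_table(path: PathLike, population: Optional[str] = None) -> dict[str, float]:
    """Read a ``vid<TAB>population<TAB>af`` frequency table into a lookup dict.

    With ``population`` given, only rows for that population are kept.
    """
    out: dict[str, float] = {}
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].split("\t")[:1] == ["vid"]:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"population table line {lineno}: expected 3 columns")
        vid, pop, af_token = fields
        if population is not None and pop != population:
            continue
        try:
            af = float(af_token)
        except ValueError:
            raise ValueError(f"population table line {lineno}: bad frequency {af_token!r}") from None
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"population table line {lineno}: frequency {af} outside [0, 1]")
        out[vid] = af
    return out


def write_vcf(
    variants: list[VariantRecord],
    gt: GenotypeMatrix,
    path: PathLike,
) -> None:
    """Write a minimal VCF 4.2 file with GT-only genotype columns."""
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    for c in chroms:
        header.append(f"##contig=<ID={c}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gt.samples))
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = header
    for v in variants:
        calls = gt.row(v.vid)
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".", "GT"]
        fields += [gt_text[int(c)] for c in calls]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
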