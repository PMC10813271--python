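"""Domain types and file-format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famprio import (
    MISSING,
    AnnotationRecord,
    GenotypeMatrix,
    Pedigree,
    PedigreeMember,
    VariantRecord,
    read_annotations,
    read_candidates,
    read_ped,
    read_vcf,
    write_annotations,
    write_candidates,
)
from famprio.io import ANNOTATION_COLUMNS
from famprio.model import CandidateRow, CandidateTable


# ---------------------------------------------------------------- variants

def test_variant_identity_normalizes_chromosome_prefix():
    assert VariantRecord("chr14", 91942196, "C", "T").vid == "14:91942196:C:T"
    assert VariantRecord("14", 91942196, "C", "T").vid == "14:91942196:C:T"


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(chrom="1", pos=0, ref="A", alt="C"),
        dict(chrom="1", pos=5, ref="A", alt="A"),
        dict(chrom="1", pos=5, ref="", alt="C"),
        dict(chrom="1", pos=5, ref="A", alt="Z"),
    ],
)
def test_invalid_variants_rejected(kwargs):
    with pytest.raises(ValueError):
        VariantRecord(**kwargs)


def test_genotype_matrix_rejects_duplicates_and_bad_codes():
    with pytest.raises(ValueError, match="duplicate variant"):
        GenotypeMatrix(["v1", "v1"], ["s1"], np.zeros((2, 1), dtype=np.int8))
    with pytest.raises(ValueError, match="invalid genotype"):
        GenotypeMatrix(["v1"], ["s1"], np.array([[3]], dtype=np.int8))


# ---------------------------------------------------------------- VCF

def _write_vcf_text(tmp_path, body, samples=("S1", "S2")):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    path = tmp_path / "test.vcf"
    path.write_text(header + body)
    return path


def _brute_force_gt(path):
    """Character-level reference parse of a tiny VCF: vid -> {sample: call}."""
    lines = path.read_text().splitlines()
    samples = []
    table = {}
    for line in lines:
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            continue
        if line.startswith("#"):
            continue
        f = line.split("\t")
        chrom = f[0][3:] if f[0].startswith("chr") else f[0]
        vid = f"{chrom}:{f[1]}:{f[3]}:{f[4]}"
        gt_index = f[8].split(":").index("GT")
        calls = {}
        for s, cell in zip(samples, f[9:]):
            g = cell.split(":")[gt_index].replace("|", "/")
            calls[s] = MISSING if "." in g else sum(int(a) for a in g.split("/"))
        table[vid] = calls
    return table


def test_read_vcf_matches_character_level_parse(tmp_path):
    body = (
        "chr14\t91942196\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        "chr2\t100\t.\tG\tA\t.\tPASS\t.\tGT\t1|1\t./.\n"
        "chr2\t200\t.\tA\tC\t.\tPASS\t.\tGT\t1/0\t0/1\n"
    )
    path = _write_vcf_text(tmp_path, body)
    variants, gt = read_vcf(path)
    oracle = _brute_force_gt(path)
    assert len(variants) == 3
    assert [v.vid for v in variants] == list(oracle)
    for vid, calls in oracle.items():
        for sample, expected in calls.items():
            assert gt.call(vid, sample) == expected


def test_read_vcf_missing_call_is_not_reference(tmp_path):
    path = _write_vcf_text(tmp_path, "chr1\t10\t.\tA\tG\t.\t.\t.\tGT\t./.\t0/0\n")
    _, gt = read_vcf(path)
    assert gt.call("1:10:A:G", "S1") == MISSING
    assert gt.call("1:10:A:G", "S1") != 0


def test_read_vcf_canonical_site(tmp_path):
    path = _write_vcf_text(tmp_path, "chr14\t91942196\t.\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\n")
    variants, gt = read_vcf(path)
    assert variants[0].vid == "14:91942196:C:T"
    assert gt.call("14:91942196:C:T", "S1") == 1


def test_read_vcf_rejects_multiallelic_and_duplicates(tmp_path):
    path = _write_vcf_text(tmp_path, "chr1\t10\t.\tA\tG,C\t.\t.\t.\tGT\t0/1\t0/0\n")
    with pytest.raises(ValueError, match="multiallelic.*1:10"):
        read_vcf(path)
    dup = (
        "chr1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n"
        "1\t10\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\n"
    )
    path = _write_vcf_text(tmp_path, dup)
    with pytest.raises(ValueError, match="duplicate variant identity"):
        read_vcf(path)


def test_read_vcf_requires_gt_key(tmp_path):
    path = _write_vcf_text(tmp_path, "chr1\t10\t.\tA\tG\t.\t.\t.\tDP\t10\t12\n")
    with pytest.raises(ValueError, match="GT"):
        read_vcf(path)


# ---------------------------------------------------------------- PED

def test_read_ped_reference_family(tmp_path):
    ped_text = "\n".join(
        [
            "FAM1 I4 0 0 1 1",
            "FAM1 II2 0 0 2 1",
            "FAM1 II3 0 0 2 2",
            "FAM1 II4 I4 0 1 1",
            "FAM1 III3 II4 II3 1 2",
            "FAM1 III5 II4 II3 2 2",
            "FAM1 III7 II4 II3 2 2",
            "FAM1 III9 II4 II3 1 1",
        ]
    )
    path = tmp_path / "fam.ped"
    path.write_text(ped_text + "\n")
    ped = read_ped(path, controls=("II2",))
    genotyped = ["II2", "II3", "III3", "III5", "III7", "III9"]
    affected = [m for m in genotyped if ped.members[m].affection == "affected"]
    unaffected = [m for m in genotyped if ped.members[m].affection == "unaffected"]
    assert len(affected) == 4 and len(unaffected) == 2


def test_read_ped_singleton_and_errors(tmp_path):
    path = tmp_path / "one.ped"
    path.write_text("F P1 0 0 1 2\n")
    ped = read_ped(path)
    assert len(ped) == 1

    path.write_text("F P1 0 P2 1 2\n")
    with pytest.raises(ValueError, match="unknown parent"):
        read_ped(path)

    path.write_text("F P1 0 0 1 2\nF P1 0 0 1 2\n")
    with pytest.raises(ValueError, match="duplicate member"):
        read_ped(path)


def test_cyclic_parentage_rejected():
    members = [
        PedigreeMember("A", "B", None, "male", "unknown"),
        PedigreeMember("B", "A", None, "male", "unknown"),
    ]
    with pytest.raises(ValueError, match="ancestor"):
        Pedigree(members)


def test_controls_must_be_unaffected():
    members = [PedigreeMember("A", None, None, "male", "affected")]
    with pytest.raises(ValueError, match="not unaffected"):
        Pedigree(members, controls=("A",))


# ---------------------------------------------------------------- annotations

def test_annotation_tsv_round_trip_reference(tmp_path, ref_inputs):
    _, _, annotations, _, _ = ref_inputs
    path = tmp_path / "ann.tsv"
    write_annotations(annotations, path)
    back = read_annotations(path)
    assert len(back) == 12
    assert back == annotations

    causal = back["14:91942196:C:T"]
    assert causal.af_1000g_eas is None
    assert causal.sift_score == 0.24
    assert causal.sift_pred == "T"
    assert causal.pp2_hdiv_pred == "D"
    assert causal.mt_pred == "D"


def test_annotation_bad_category_and_af_rejected(tmp_path):
    header = "\t".join(ANNOTATION_COLUMNS)
    good = "1:10:A:G\tGENE\texonic\tnonsynonymous_SNV" + "\tNA" * 10
    bad_pred = good.replace("nonsynonymous_SNV\t" + "NA\t" * 7 + "NA",
                            "nonsynonymous_SNV\t" + "NA\t" * 7 + "X")
    path = tmp_path / "ann.tsv"
    path.write_text(header + "\n" + bad_pred + "\n")
    with pytest.raises(ValueError, match="line 2"):
        read_annotations(path)

    bad_af = "1:10:A:G\tGENE\texonic\tnonsynonymous_SNV\t1.5" + "\tNA" * 9
    path.write_text(header + "\n" + bad_af + "\n")
    with pytest.raises(ValueError, match="line 2"):
        read_annotations(path)


_maybe_af = st.one_of(st.none(), st.floats(0, 1, allow_nan=False))


@st.composite
def annotation_records(draw, index):
    return AnnotationRecord(
        vid=f"1:{100 + index}:A:G",
        gene=f"G{index}",
        region=draw(st.sampled_from(["exonic", "splicing", "intronic", "UTR3"])),
        function=draw(st.sampled_from(["nonsynonymous_SNV", "synonymous_SNV", "stopgain"])),
        af_1000g_all=draw(_maybe_af),
        af_1000g_eas=draw(_maybe_af),
        af_exac_all=draw(_maybe_af),
        af_exac_eas=draw(_maybe_af),
        sift_score=draw(_maybe_af),
        sift_pred=draw(st.one_of(st.none(), st.sampled_from(["D", "T"]))),
        pp2_hdiv_score=draw(_maybe_af),
        pp2_hdiv_pred=draw(st.one_of(st.none(), st.sampled_from(["D", "P", "B"]))),
        mt_score=draw(_maybe_af),
        mt_pred=draw(st.one_of(st.none(), st.sampled_from(["A", "D", "N", "P"]))),
    )


@settings(max_examples=25, derandomize=True)
@given(data=st.data(), n=st.integers(0, 8))
def test_annotation_round_trip_randomized(data, n, tmp_path_factory):
    records = {}
    for i in range(n):
        rec = data.draw(annotation_records(i))
        records[rec.vid] = rec
    path = tmp_path_factory.mktemp("rt") / "ann.tsv"
    write_annotations(records, path)
    assert read_annotations(path) == records


# ---------------------------------------------------------------- candidates

def test_candidate_table_round_trip(tmp_path, ref_table):
    path = tmp_path / "candidates.tsv"
    write_candidates(ref_table, path)
    back = read_candidates(path)
    assert [r.vid for r in back.rows] == [r.vid for r in ref_table.rows]
    assert [r.hazard_score for r in back.rows] == [r.hazard_score for r in ref_table.rows]
    assert [r.rank for r in back.rows] == [r.rank for r in ref_table.rows]
    assert back.stage_counts == ref_table.stage_counts
    for a, b in zip(back.rows, ref_table.rows):
        assert a.annotation == b.annotation


def test_empty_candidate_table_written_with_stage_counts(tmp_path):
    table = CandidateTable(stage_counts=[("input", 0), ("filter_af", 0)])
    path = tmp_path / "empty.tsv"
    write_candidates(table, path)
    assert path.read_text().count("\n") == 1  # header only
    back = read_candidates(path)
    assert back.rows == []
    assert back.stage_counts == [("input", 0), ("filter_af", 0)]
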