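"""The filter cascade: per-stage behavior, oracle equivalence, invariants."""

import itertools

import numpy as np
import pytest

from famprio import (
    MISSING,
    AnnotationRecord,
    CascadeConfig,
    GenotypeMatrix,
    exclude_controls,
    filter_af,
    filter_function,
    filter_region,
    filter_zygosity,
    intersect_affected,
    run_cascade,
)
from famprio.model import VariantRecord
from famprio.reference_study import (
    EXCLUDED_GENES,
    RETAINED_GENES,
    reference_study,
)

AFFECTED = ["A1", "A2", "A3", "A4"]
CONTROLS = ["C1"]


def _gt(rows, samples):
    vids = [f"v{i}" for i in range(len(rows))]
    return GenotypeMatrix(vids, samples, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------- stages

def test_intersect_affected_requires_carriage_in_all():
    gt = _gt([[1, 1, 1, 1], [1, 1, 1, 0], [2, 1, 1, 1], [1, MISSING, 1, 1]], AFFECTED)
    assert intersect_affected(gt, AFFECTED) == {"v0", "v2"}
    with pytest.raises(ValueError, match="empty"):
        intersect_affected(gt, [])
    with pytest.raises(KeyError):
        intersect_affected(gt, ["nobody"])


def test_exclude_controls_drops_on_carriage_not_missingness():
    gt = _gt([[0], [1], [2], [MISSING]], CONTROLS)
    kept = exclude_controls({"v0", "v1", "v2", "v3"}, gt, CONTROLS)
    assert kept == {"v0", "v3"}


def _ann(vid, region="exonic", function="nonsynonymous_SNV", **afs):
    return AnnotationRecord(vid=vid, gene=vid.upper(), region=region, function=function, **afs)


def test_filter_region_and_function_defaults():
    anns = {
        "v0": _ann("v0", region="exonic"),
        "v1": _ann("v1", region="intronic"),
        "v2": _ann("v2", region="splicing"),
        "v3": _ann("v3", function="synonymous_SNV"),
        "v4": _ann("v4", function="stopgain"),
    }
    vids = set(anns)
    assert filter_region(vids, anns) == {"v0", "v2", "v3", "v4"}
    assert filter_function(vids, anns) == {"v0", "v1", "v2", "v4"}
    with pytest.raises(KeyError, match="v9"):
        filter_region({"v9"}, anns)


def test_filter_zygosity_drops_only_uniformly_homozygous():
    gt = _gt([[2, 2, 2, 2], [1, 1, 1, 1], [1, 2, 1, 2]], AFFECTED)
    assert filter_zygosity({"v0", "v1", "v2"}, gt, AFFECTED) == {"v1", "v2"}


def test_filter_af_threshold_is_strict_and_na_passes():
    anns = {
        "ctbs": _ann("ctbs", af_1000g_eas=0.03, af_1000g_all=0.15, af_exac_eas=0.032),
        "private": _ann("private"),
        "edge": _ann("edge", af_exac_eas=0.001),
        "over": _ann("over", af_exac_eas=0.0011),
    }
    kept = filter_af(set(anns), anns)
    assert kept == {"private", "edge"}
    assert filter_af({"private"}, anns, na_policy="fail") == set()
    # non-screened columns do not participate under the default field set
    anns2 = {"x": _ann("x", af_1000g_all=0.5)}
    assert filter_af({"x"}, anns2) == {"x"}


# ---------------------------------------------------------------- full cascade

def test_reference_cascade_counts_and_membership(ref_table):
    assert ref_table.stage_counts[0] == ("input", 12)
    assert ref_table.stage_counts[-1] == ("filter_af", 5)
    # all pre-frequency stages pass the full candidate set
    for name, n in ref_table.stage_counts[:-1]:
        assert n == 12
    assert set(ref_table.genes()) == set(RETAINED_GENES)
    assert set(ref_table.genes()) & set(EXCLUDED_GENES) == set()


def test_reference_cascade_counts_non_increasing(ref_table):
    counts = [n for _, n in ref_table.stage_counts]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_empty_input_yields_empty_table():
    variants, gt, annotations, ped, config = reference_study()
    empty_gt = GenotypeMatrix([], gt.samples, np.empty((0, gt.n_samples), dtype=np.int8))
    table = run_cascade([], empty_gt, {}, ped, config)
    assert table.rows == []
    assert all(n == 0 for _, n in table.stage_counts)


def test_control_carriage_removes_the_causal_variant():
    variants, gt, annotations, ped, config = reference_study()
    vid = "14:91942196:C:T"
    calls = gt.calls.copy()
    calls[gt.variant_index(vid), gt.sample_index("II2")] = 1
    gt2 = GenotypeMatrix(gt.vids, gt.samples, calls)
    table = run_cascade(variants, gt2, annotations, ped, config)
    assert vid not in table.vids()


# ---------------------------------------------------------------- oracle equivalence

REGIONS = ["exonic", "splicing", "intronic", "UTR3", "intergenic"]
FUNCTIONS = ["nonsynonymous_SNV", "synonymous_SNV", "stopgain", "unknown"]


def _random_inputs(rng, n_variants, n_samples):
    samples = [f"S{i}" for i in range(n_samples)]
    affected = samples[:4]
    controls = samples[4:6]
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=(n_variants, n_samples),
        p=[0.55, 0.25, 0.15, 0.05],
    )
    variants = [VariantRecord("1", 100 + i, "A", "G") for i in range(n_variants)]
    gt = GenotypeMatrix([v.vid for v in variants], samples, calls)
    annotations = {}
    for v in variants:
        def af():
            return None if rng.random() < 0.4 else float(rng.uniform(0, 0.01))
        annotations[v.vid] = AnnotationRecord(
            vid=v.vid, gene=v.vid,
            region=REGIONS[rng.integers(len(REGIONS))],
            function=FUNCTIONS[rng.integers(len(FUNCTIONS))],
            af_1000g_all=af(), af_1000g_eas=af(), af_exac_all=af(), af_exac_eas=af(),
        )
    config = CascadeConfig(affected_ids=tuple(affected), control_ids=tuple(controls))
    return variants, gt, annotations, config


def _survives_brute_force(vid, gt, ann, config):
    """Single boolean conjunction per variant, written independently of the
    cascade implementation."""
    calls = {s: gt.call(vid, s) for s in gt.samples}
    if not all(calls[s] in (1, 2) for s in config.affected_ids):
        return False
    if any(calls[s] in (1, 2) for s in config.control_ids):
        return False
    if ann.region not in config.keep_regions:
        return False
    if ann.function in config.drop_functions:
        return False
    if all(calls[s] == 2 for s in config.affected_ids):
        return False
    values = [getattr(ann, f) for f in config.af_fields if getattr(ann, f) is not None]
    if not values:
        return config.na_policy == "pass"
    return max(values) <= config.af_threshold


@pytest.mark.parametrize("trial", range(50))
def test_cascade_equals_brute_force_predicate(trial):
    rng = np.random.default_rng(1000 + trial)
    n_variants = int(rng.integers(1, 501))
    variants, gt, annotations, config = _random_inputs(rng, n_variants, 12)
    table = run_cascade(variants, gt, annotations, None, config)
    expected = {
        v.vid for v in variants
        if _survives_brute_force(v.vid, gt, annotations[v.vid], config)
    }
    assert set(table.vids()) == expected
    counts = [n for _, n in table.stage_counts]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_cascade_is_idempotent_on_its_own_output():
    rng = np.random.default_rng(42)
    variants, gt, annotations, config = _random_inputs(rng, 300, 12)
    table = run_cascade(variants, gt, annotations, None, config)
    survivors = set(table.vids())
    sub_variants = [v for v in variants if v.vid in survivors]
    table2 = run_cascade(sub_variants, gt, annotations, None, config)
    assert set(table2.vids()) == survivors


def test_annotation_stage_order_does_not_change_final_set():
    """filter_region / filter_function / filter_zygosity / filter_af commute:
    only the audit counts depend on their order."""
    rng = np.random.default_rng(7)
    variants, gt, annotations, config = _random_inputs(rng, 200, 12)
    start = exclude_controls(
        intersect_affected(gt, config.affected_ids), gt, config.control_ids
    )
    stages = {
        "region": lambda s: filter_region(s, annotations, config.keep_regions),
        "function": lambda s: filter_function(s, annotations, config.drop_functions),
        "zygosity": lambda s: filter_zygosity(s, gt, config.affected_ids),
        "af": lambda s: filter_af(s, annotations, config.af_fields,
                                  config.af_threshold, config.na_policy),
    }
    results = set()
    for order in itertools.permutations(stages):
        current = set(start)
        for name in order:
            current = stages[name](current)
        results.add(frozenset(current))
    assert len(results) == 1


def test_config_json_round_trip(tmp_path):
    config = CascadeConfig(affected_ids=("A1",), control_ids=("C1",), af_threshold=0.005)
    path = tmp_path / "config.json"
    config.to_json(path)
    assert CascadeConfig.from_json(path) == config


def test_config_rejects_overlapping_sample_sets():
    with pytest.raises(ValueError, match="overlap"):
        CascadeConfig(affected_ids=("A",), control_ids=("A",))
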