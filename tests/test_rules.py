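"""Rule engine: rule-set contracts, the decision procedure against a
brute-force oracle, concordance logic and cohort summaries."""
import numpy as np
import pandas as pd
import pytest

import leukotype as lk
from leukotype import rules as rl
from leukotype import simulate as sim
from leukotype.drivers import FusionCall, HotspotCall
from leukotype.karyotype import KaryotypeCall


def _fusion(subtype, g5="GENEA", g3="GENEB"):
    return FusionCall(g5, g3, {"arriba"}, 10, "high",
                      defining_subtype=subtype)


def _snv(subtype, gene, change):
    return HotspotCall(gene, change, 0.4, 100, 40, defining_subtype=subtype)


def _bundle(expr_label, tier="high_confidence", fusions=(), hotspots=(),
            karyotype=None):
    return rl.EvidenceBundle(
        sample_id="S1",
        expression=rl.ExpressionPrediction(expr_label, tier, 70.0, "female",
                                           "pre-B"),
        karyotype=karyotype, fusions=list(fusions), hotspots=list(hotspots))


# --------------------------------------------------------------------------
# rule-set contracts
# --------------------------------------------------------------------------
def test_bundled_ruleset_emits_26_icc_and_10_who_classes(ruleset):
    assert len(ruleset.icc_labels) == 26
    assert len(ruleset.who_labels) == 10


def test_allowance_restricted_to_driver_cryptic_subtypes(ruleset):
    allowed = {r.icc_label for r in ruleset if r.allowance}
    assert allowed == {"DUX4-r", "CEBP", "BCR::ABL1-like, NOS", "PAX5alt"}


def test_igh_il3_not_represented(ruleset):
    assert not any("IL3" in label for label in ruleset.icc_labels)


def test_ruleset_with_unresolvable_fusion_errors(tmp_path):
    import yaml
    doc = {"version": "test", "subtypes": [
        {"icc_label": "Novel-r", "who_label": "", "expression": ["Novel"],
         "defining_fusions": True, "defining_snvs": [],
         "defining_karyotype": None, "allowance": False}]}
    path = tmp_path / "rules.yaml"
    path.write_text(yaml.safe_dump(doc))
    with pytest.raises(rl.RuleSetError, match="no fusion catalog entries"):
        rl.load_ruleset(path)


# --------------------------------------------------------------------------
# decision procedure vs brute-force oracle
# --------------------------------------------------------------------------
def oracle_classify(n_drivers, expr_kind, tier, allowance_subtype):
    """Independent hand-written restatement of the 7-step procedure."""
    if n_drivers >= 2:
        return "manual_curation", "additional_driver"
    if n_drivers == 1:
        return (("automatic", "none") if expr_kind == "concordant"
                else ("manual_curation", "discordant_driver"))
    if tier == "high_confidence" and allowance_subtype and expr_kind == "concordant":
        return "automatic", "none"
    if expr_kind != "absent" and tier != "unclassified":
        return "manual_curation", "missed_driver"
    return "manual_curation", "unclassified"


@pytest.mark.parametrize("allowance_subtype", [False, True])
@pytest.mark.parametrize("tier", rl.CONFIDENCE_TIERS)
@pytest.mark.parametrize("expr_kind", ["concordant", "discordant", "absent"])
@pytest.mark.parametrize("n_drivers", [0, 1, 2])
def test_classify_matches_truth_table_oracle(ruleset, n_drivers, expr_kind,
                                             tier, allowance_subtype):
    # primary subtype: fusion-defined; allowance variant is expression-only
    primary = "PAX5alt" if allowance_subtype else "KMT2A-r"
    rule = ruleset[primary]
    fusions = []
    if n_drivers >= 1:
        fusions.append(_fusion(primary))
    if n_drivers >= 2:
        fusions.append(_fusion("TCF3::PBX1"))
    if tier == "unclassified":
        label, expr_kind_eff = "", "absent"
    elif expr_kind == "concordant":
        label, expr_kind_eff = rule.primary_expression, "concordant"
    elif expr_kind == "discordant":
        label, expr_kind_eff = "ETV6::RUNX1", "discordant"
    else:
        label, expr_kind_eff = "", "absent"
    a = rl.classify(_bundle(label, tier, fusions=fusions), ruleset)
    status, category = oracle_classify(
        n_drivers, expr_kind_eff, tier,
        allowance_subtype and expr_kind_eff == "concordant")
    assert a.status == status
    assert a.curation_category == category
    assert (a.status == "automatic") == (a.curation_category == "none")


# --------------------------------------------------------------------------
# worked classification cases
# --------------------------------------------------------------------------
def test_concordant_fusion_is_automatic(ruleset):
    a = rl.classify(_bundle("BCR::ABL1", fusions=[_fusion("BCR::ABL1")]),
                    ruleset)
    assert (a.status, a.basis) == ("automatic", "fusion+GEP")
    assert a.icc_label == "BCR::ABL1"
    assert a.who_label == "B-ALL with BCR::ABL1 fusion"


def test_high_confidence_dux4_without_driver_is_gep_only(ruleset):
    a = rl.classify(_bundle("DUX4"), ruleset)
    assert (a.status, a.basis) == ("automatic", "GEP_only")
    assert a.icc_label == "DUX4-r"


def test_candidate_tier_allowance_without_driver_is_missed(ruleset):
    a = rl.classify(_bundle("BCR::ABL1-like", tier="candidate"), ruleset)
    assert (a.status, a.curation_category) == ("manual_curation",
                                               "missed_driver")


def test_fusion_plus_aneuploid_karyotype_is_additional_driver(ruleset):
    a = rl.classify(_bundle("KMT2A", fusions=[_fusion("KMT2A-r")],
                            karyotype=KaryotypeCall.certain(
                                "high_hyperdiploid")), ruleset)
    assert (a.status, a.curation_category) == ("manual_curation",
                                               "additional_driver")


def test_discordant_snv_driver_flagged(ruleset):
    a = rl.classify(_bundle("CEBP",
                            hotspots=[_snv("PAX5 P80R", "PAX5", "P80R")]),
                    ruleset)
    assert (a.status, a.curation_category) == ("manual_curation",
                                               "discordant_driver")


def test_karyotype_driver_with_shared_signature_is_automatic(ruleset):
    # near-haploid call corrects a hyperdiploid expression prediction
    a = rl.classify(_bundle("Hyperdiploid",
                            karyotype=KaryotypeCall.certain("near_haploid")),
                    ruleset)
    assert (a.status, a.basis) == ("automatic", "karyotype+GEP")
    assert a.icc_label == "Near haploid"


def test_cooperating_snvs_never_drive_classification(ruleset):
    a = rl.classify(_bundle("DUX4",
                            hotspots=[_snv("", "NRAS", "G12D")]), ruleset)
    assert (a.status, a.basis) == ("automatic", "GEP_only")


def test_unclassified_expression_without_driver(ruleset):
    a = rl.classify(_bundle("", tier="unclassified"), ruleset)
    assert a.curation_category == "unclassified"


# --------------------------------------------------------------------------
# karyotype concordance
# --------------------------------------------------------------------------
@pytest.mark.parametrize("karyotype,label,expected", [
    ("near_haploid", "Hyperdiploid", True),
    ("high_hyperdiploid", "Near haploid", True),
    ("high_hyperdiploid", "DUX4", False),
    ("iamp21_chr21amp", "BCR::ABL1-like", True),
    ("low_hypodiploid", "Low hypodiploid", True),
    ("low_hypodiploid", "Hyperdiploid", False),
])
def test_karyotype_concordance(ruleset, karyotype, label, expected):
    assert rl.karyotype_concordance(
        KaryotypeCall.certain(karyotype),
        rl.ExpressionPrediction(label), ruleset) is expected


def test_karyotype_concordance_rejects_other(ruleset):
    with pytest.raises(ValueError, match="aneuploid"):
        rl.karyotype_concordance(KaryotypeCall.certain("other"),
                                 rl.ExpressionPrediction("DUX4"), ruleset)


# --------------------------------------------------------------------------
# properties
# --------------------------------------------------------------------------
def test_additional_driver_demotion_is_monotone(ruleset):
    """Adding a second distinct-subtype driver to any automatic bundle
    always flips it to additional_driver."""
    automatic = [
        _bundle("BCR::ABL1", fusions=[_fusion("BCR::ABL1")]),
        _bundle("PAX5 P80R", hotspots=[_snv("PAX5 P80R", "PAX5", "P80R")]),
        _bundle("Hyperdiploid",
                karyotype=KaryotypeCall.certain("high_hyperdiploid")),
    ]
    for bundle in automatic:
        assert rl.classify(bundle, ruleset).status == "automatic"
        bundle.fusions.append(_fusion("NUTM1-r"))
        demoted = rl.classify(bundle, ruleset)
        assert (demoted.status, demoted.curation_category) == \
            ("manual_curation", "additional_driver")
    # a GEP-only automatic bundle gains its *first* driver instead: the
    # driver outranks the expression-only allowance and flags discordance
    gep_only = _bundle("DUX4")
    assert rl.classify(gep_only, ruleset).basis == "GEP_only"
    gep_only.fusions.append(_fusion("NUTM1-r"))
    flagged = rl.classify(gep_only, ruleset)
    assert (flagged.status, flagged.curation_category) == \
        ("manual_curation", "discordant_driver")


def test_removed_subtype_is_never_emitted(ruleset):
    reduced = rl.RuleSet(
        rules={k: v for k, v in ruleset.rules.items() if k != "KMT2A-r"},
        version="reduced")
    a = rl.classify(_bundle("KMT2A", fusions=[_fusion("KMT2A-r")]), reduced)
    assert a.icc_label != "KMT2A-r"
    assert a.status == "manual_curation"


def test_summarize_cohort_consistency(ruleset):
    bundles = ([_bundle("BCR::ABL1", fusions=[_fusion("BCR::ABL1")])] * 3
               + [_bundle("", tier="unclassified")] * 2)
    assignments = [rl.classify(b, ruleset) for b in bundles]
    summary = rl.summarize_cohort(assignments)
    assert summary["status"].loc["automatic", "count"] == 3
    assert summary["status"]["percent"].sum() == pytest.approx(100)
    flagged = summary["curation_category"].drop("none", errors="ignore")
    assert flagged["count"].sum() == 2


def test_all_automatic_cohort_has_zero_flagged(ruleset):
    assignments = [rl.classify(
        _bundle("BCR::ABL1", fusions=[_fusion("BCR::ABL1")]), ruleset)
        for _ in range(5)]
    summary = rl.summarize_cohort(assignments)
    assert "manual_curation" not in summary["status"].index


# --------------------------------------------------------------------------
# evidence collection
# --------------------------------------------------------------------------
def test_collect_evidence_requires_expression():
    with pytest.raises(ValueError, match="mandatory"):
        rl.collect_evidence("S1", None)


def test_collect_evidence_records_missing_layers(ruleset, fusion_catalog,
                                                 hotspot_catalog):
    bundle = rl.collect_evidence(
        "S1", rl.ExpressionPrediction("DUX4"),
        fusion_catalog=fusion_catalog, hotspot_catalog=hotspot_catalog)
    assert set(bundle.missing_inputs) == {"fusion_calls", "pileup",
                                          "karyotype"}
    assert bundle.fusions == [] and bundle.hotspots == []


def test_cohort_truth_crosstab_matches_summary(ruleset):
    """Classify a generated cohort against its own truth table."""
    spec = sim.CohortSpec(n_per_class={"other": 40}, n_genes=30,
                          snvs_per_chrom=5, evidence_completeness=1.0,
                          double_driver_rate=0.0, seed=11)
    cohort = sim.generate_cohort(spec)
    assignments = []
    for s in cohort.samples:
        bundle = rl.collect_evidence(
            s.sample_id, rl.ExpressionPrediction(
                s.gep["Prediction"].iloc[0], s.gep["Confidence"].iloc[0]),
            lk.read_arriba(s.arriba), lk.read_fusioncatcher(s.fusioncatcher),
            s.pileup, KaryotypeCall.certain(s.karyotype_class))
        assignments.append(rl.classify(bundle, ruleset))
    summary = rl.summarize_cohort(assignments)
    # complete concordant evidence, no double drivers: all automatic
    assert summary["status"].loc["automatic", "count"] == 40
    by_subtype = cohort.truth["subtype"].value_counts()
    for subtype, n in by_subtype.items():
        assert summary["icc_label"].loc[subtype, "count"] == n


def test_automatic_fraction_in_observed_band(ruleset):
    """At the default ~80% evidence completeness the automatic fraction
    lands in the observed 74-85% range."""
    spec = sim.CohortSpec(
        n_per_class={"other": 400, "high_hyperdiploid": 40,
                     "low_hypodiploid": 35, "near_haploid": 15,
                     "iamp21_chr21amp": 10},
        n_genes=30, snvs_per_chrom=5, seed=19)
    cohort = sim.generate_cohort(spec)
    assignments = []
    for s in cohort.samples:
        bundle = rl.collect_evidence(
            s.sample_id, rl.ExpressionPrediction(
                s.gep["Prediction"].iloc[0], s.gep["Confidence"].iloc[0]),
            lk.read_arriba(s.arriba), lk.read_fusioncatcher(s.fusioncatcher),
            s.pileup, KaryotypeCall.certain(s.karyotype_class))
        assignments.append(rl.classify(bundle, ruleset))
    frac = np.mean([a.status == "automatic" for a in assignments])
    assert 0.74 <= frac <= 0.85
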