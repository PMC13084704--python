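"""Rule-based WHO-HAEM5/ICC subtype assignment from integrated evidence.

One sample's evidence — an expression-classifier prediction, a virtual
karyotype call, matched driver fusions and hotspot SNVs — is fused by a
deterministic decision procedure into either an automatic subtype assignment
or a manual-curation flag.  Automatic assignment requires concordance between
a subtype-defining genomic driver and the expression-based subtype, and the
absence of any other defining driver; four driver-cryptic subtypes (DUX4,
CEBP, BCR::ABL1-like, PAX5alt) may be assigned from a high-confidence
expression prediction alone.  Flagged samples fall into the curation
categories missed driver, discordant driver, additional driver, or
unclassified.

The bundled rule set (``data/ruleset.synthetic.yaml``) is a synthetic
curation of 26 ICC / 10 WHO-HAEM5 B-ALL entities assembled from public
classification literature (IGH::IL3 is not represented).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .drivers import (FusionCall, FusionCatalog, HotspotCall, HotspotCatalog,
                      load_fusion_catalog, load_hotspot_catalog)
from .karyotype import KaryotypeCall

logger = logging.getLogger(__name__)

DEFAULT_RULESET = Path(str(resources.files("leukotype") / "data"
                           / "ruleset.synthetic.yaml"))

CONFIDENCE_TIERS = ("high_confidence", "candidate", "unclassified")
#: expression labels whose subtypes may be assigned from expression alone
ALLOWANCE_FAMILIES = ("DUX4", "CEBP", "BCR::ABL1-like", "PAX5alt")

KARYOTYPE_SUBTYPE_CLASSES = ("near_haploid", "low_hypodiploid",
                             "high_hyperdiploid", "iamp21_chr21amp")


class RuleSetError(ValueError):
    """Malformed or inconsistent rule set."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass
class ExpressionPrediction:
    """Expression-classifier record: subtype label, tier, clinical covariates."""

    subtype: str
    tier: str = "high_confidence"
    blast_pct: float = float("nan")
    sex: str = ""
    immunophenotype: str = ""

    def __post_init__(self) -> None:
        if self.tier not in CONFIDENCE_TIERS:
            raise ValueError(f"unknown confidence tier {self.tier!r}")


@dataclass
class EvidenceBundle:
    """Per-sample union of all classification evidence layers."""

    sample_id: str
    expression: ExpressionPrediction
    karyotype: KaryotypeCall | None = None
    fusions: list[FusionCall] = field(default_factory=list)
    hotspots: list[HotspotCall] = field(default_factory=list)
    missing_inputs: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SubtypeRule:
    icc_label: str
    who_label: str  # "" = not represented in WHO-HAEM5
    expression: tuple[str, ...]  # concordant expression labels, primary first
    defining_fusions: bool
    defining_snvs: tuple[str, ...]  # "GENE CHANGE" strings
    defining_karyotype: str | None
    allowance: bool

    @property
    def primary_expression(self) -> str:
        return self.expression[0]


@dataclass(frozen=True)
class RuleSet:
    rules: Mapping[str, SubtypeRule]
    version: str

    def __iter__(self):
        return iter(self.rules.values())

    def __getitem__(self, icc_label: str) -> SubtypeRule:
        return self.rules[icc_label]

    def __contains__(self, icc_label: str) -> bool:
        return icc_label in self.rules

    @property
    def icc_labels(self) -> set[str]:
        return set(self.rules)

    @property
    def who_labels(self) -> set[str]:
        return {r.who_label for r in self if r.who_label}

    def karyotype_rule(self, karyotype_class: str) -> SubtypeRule | None:
        for r in self:
            if r.defining_karyotype == karyotype_class:
                return r
        return None

    def allowance_rule_for(self, expression_label: str) -> SubtypeRule | None:
        for r in self:
            if r.allowance and r.primary_expression == expression_label:
                return r
        return None


@dataclass
class SubtypeAssignment:
    sample_id: str
    status: str  # automatic | manual_curation
    icc_label: str = ""
    who_label: str = ""
    basis: str = "none"  # fusion+GEP | karyotype+GEP | SNV+GEP | GEP_only | none
    curation_category: str = "none"  # none | missed_driver | discordant_driver
    #                                  | additional_driver | unclassified
    evidence_summary: str = ""


def load_ruleset(path: str | Path | None = None,
                 fusion_catalog: FusionCatalog | None = None,
                 hotspot_catalog: HotspotCatalog | None = None) -> RuleSet:
    """Load and validate a YAML rule set.

    Validation: unique ICC labels; allowance flags restricted to the four
    driver-cryptic families; every fusion-defined subtype resolvable in the
    fusion catalog and every defining SNV present in the hotspot catalog.
    """
    path = Path(path) if path is not None else DEFAULT_RULESET
    fusion_catalog = fusion_catalog or load_fusion_catalog()
    hotspot_catalog = hotspot_catalog or load_hotspot_catalog()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules: dict[str, SubtypeRule] = {}
    for rec in doc["subtypes"]:
        rule = SubtypeRule(
            icc_label=rec["icc_label"],
            who_label=rec.get("who_label") or "",
            expression=tuple(rec["expression"]),
            defining_fusions=bool(rec.get("defining_fusions")),
            defining_snvs=tuple(rec.get("defining_snvs") or ()),
            defining_karyotype=rec.get("defining_karyotype"),
            allowance=bool(rec.get("allowance")))
        if rule.icc_label in rules:
            raise RuleSetError(f"duplicate subtype {rule.icc_label!r}")
        if rule.allowance and not any(
                fam in rule.icc_label or fam == rule.primary_expression
                for fam in ALLOWANCE_FAMILIES):
            raise RuleSetError(
                f"expression-only allowance not permitted for {rule.icc_label!r}")
        if (rule.defining_karyotype is not None
                and rule.defining_karyotype not in KARYOTYPE_SUBTYPE_CLASSES):
            raise RuleSetError(
                f"unknown karyotype class {rule.defining_karyotype!r}")
        if rule.defining_fusions and rule.icc_label not in fusion_catalog.subtypes:
            raise RuleSetError(
                f"subtype {rule.icc_label!r} has no fusion catalog entries")
        for sv in rule.defining_snvs:
            gene, change = sv.split(" ", 1)
            if hotspot_catalog.defining_subtype_of(gene, change) != rule.icc_label:
                raise RuleSetError(
                    f"defining SNV {sv!r} of {rule.icc_label!r} absent from "
                    "hotspot catalog")
        rules[rule.icc_label] = rule
    unresolvable = fusion_catalog.subtypes - set(rules)
    if unresolvable:
        raise RuleSetError(
            f"fusion catalog names unknown subtypes: {sorted(unresolvable)}")
    return RuleSet(rules=rules, version=str(doc.get("version", "unversioned")))


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------
def _supported_definitions(evidence: EvidenceBundle,
                           rules: RuleSet) -> dict[str, str]:
    """Map supported subtype definition -> evidence kind (fusion/SNV/karyotype).

    A definition is supported by a matched defining fusion, a defining
    hotspot SNV, or a non-"other" karyotype call.  Cooperating (non-defining)
    hotspot SNVs never contribute.  When several evidence kinds support the
    same definition it counts once (kind priority: fusion > karyotype > SNV).
    """
    support: dict[str, str] = {}

    def add(name: str, kind: str) -> None:
        order = {"fusion": 0, "karyotype": 1, "SNV": 2}
        if name not in support or order[kind] < order[support[name]]:
            support[name] = kind

    for call in evidence.fusions:
        if call.defining_subtype and call.defining_subtype in rules:
            add(call.defining_subtype, "fusion")
    if evidence.karyotype is not None and evidence.karyotype.label != "other":
        rule = rules.karyotype_rule(evidence.karyotype.label)
        if rule is not None:
            add(rule.icc_label, "karyotype")
    for hs in evidence.hotspots:
        if hs.defining_subtype and hs.defining_subtype in rules:
            rule = rules[hs.defining_subtype]
            if f"{hs.gene} {hs.codon_change}" in rule.defining_snvs:
                add(rule.icc_label, "SNV")
    return support


def _summarize(evidence: EvidenceBundle) -> str:
    parts = []
    if evidence.fusions:
        parts.append("fusions: " + ", ".join(map(str, evidence.fusions)))
    if evidence.hotspots:
        parts.append("hotspots: " + ", ".join(map(str, evidence.hotspots)))
    if evidence.karyotype is not None:
        parts.append(f"karyotype: {evidence.karyotype.label}")
    parts.append(f"expression: {evidence.expression.subtype or '(none)'} "
                 f"[{evidence.expression.tier}]")
    return "; ".join(parts)


def classify(evidence: EvidenceBundle, rules: RuleSet) -> SubtypeAssignment:
    """Assign a subtype or curation flag to one evidence bundle.

    Decision procedure, in order:

    1. enumerate distinct subtype definitions supported by driver evidence;
    2. exactly one supported definition with a concordant expression label
       (any confidence tier) -> automatic, basis per evidence kind;
    3. no driver, high-confidence expression of an allowance subtype ->
       automatic, basis GEP_only;
    4. two or more supported definitions -> additional driver (even if one
       is concordant);
    5. one supported definition, non-concordant expression -> discordant
       driver;
    6. no driver, expression label present but not qualifying -> missed
       driver;
    7. no driver, unclassified expression -> unclassified.

    Total and pure: every bundle maps to exactly one assignment.
    """
    expr = evidence.expression
    support = _supported_definitions(evidence, rules)
    summary = _summarize(evidence)
    label_present = bool(expr.subtype) and expr.tier != "unclassified"

    if len(support) >= 2:  # additional driver dominates (steps 4 before 2/3)
        return SubtypeAssignment(evidence.sample_id, "manual_curation",
                                 basis="none",
                                 curation_category="additional_driver",
                                 evidence_summary=summary)
    if len(support) == 1:
        (name, kind), = support.items()
        rule = rules[name]
        if expr.subtype in rule.expression:
            basis = {"fusion": "fusion+GEP", "karyotype": "karyotype+GEP",
                     "SNV": "SNV+GEP"}[kind]
            return SubtypeAssignment(evidence.sample_id, "automatic",
                                     icc_label=rule.icc_label,
                                     who_label=rule.who_label, basis=basis,
                                     evidence_summary=summary)
        return SubtypeAssignment(evidence.sample_id, "manual_curation",
                                 basis="none",
                                 curation_category="discordant_driver",
                                 evidence_summary=summary)
    # no driver evidence at all
    if expr.tier == "high_confidence" and expr.subtype:
        rule = rules.allowance_rule_for(expr.subtype)
        if rule is not None:
            return SubtypeAssignment(evidence.sample_id, "automatic",
                                     icc_label=rule.icc_label,
                                     who_label=rule.who_label,
                                     basis="GEP_only",
                                     evidence_summary=summary)
    if label_present:
        return SubtypeAssignment(evidence.sample_id, "manual_curation",
                                 basis="none",
                                 curation_category="missed_driver",
                                 evidence_summary=summary)
    return SubtypeAssignment(evidence.sample_id, "manual_curation",
                             basis="none", curation_category="unclassified",
                             evidence_summary=summary)


def karyotype_concordance(karyotype: KaryotypeCall,
                          expression: ExpressionPrediction,
                          rules: RuleSet) -> bool:
    """Is the expression label concordant with a non-"other" karyotype call?

    Near-haploid and high-hyperdiploid share an expression signature, so each
    accepts the other's label (the karyotype call decides the final subtype);
    iAMP21/chr21-amplification additionally accepts the BCR::ABL1-like label.
    """
    if karyotype.label == "other":
        raise ValueError("concordance is defined for aneuploid calls only")
    rule = rules.karyotype_rule(karyotype.label)
    if rule is None:
        return False
    return expression.subtype in rule.expression


def collect_evidence(sample_id: str,
                     expression: ExpressionPrediction,
                     arriba_rows: pd.DataFrame | None = None,
                     fusioncatcher_rows: pd.DataFrame | None = None,
                     pileup_rows: pd.DataFrame | None = None,
                     karyotype: KaryotypeCall | None = None,
                     fusion_catalog: FusionCatalog | None = None,
                     hotspot_catalog: HotspotCatalog | None = None,
                     thresholds=None) -> EvidenceBundle:
    """Assemble one sample's EvidenceBundle from parsed per-layer inputs.

    The expression prediction is mandatory; fusion tables, pileups and the
    karyotype call are optional and recorded as absent (never defaulted) in
    ``missing_inputs``.
    """
    from .drivers import filter_hotspots, harmonize_fusion_calls, match_fusions

    if expression is None:
        raise ValueError(f"sample {sample_id}: expression prediction is mandatory")
    fusion_catalog = fusion_catalog or load_fusion_catalog()
    hotspot_catalog = hotspot_catalog or load_hotspot_catalog()
    missing = []
    if arriba_rows is None and fusioncatcher_rows is None:
        missing.append("fusion_calls")
    calls = harmonize_fusion_calls(arriba_rows, fusioncatcher_rows)
    fusions = match_fusions(calls, fusion_catalog)
    if pileup_rows is None:
        missing.append("pileup")
        hotspots: list[HotspotCall] = []
    else:
        hotspots = filter_hotspots(pileup_rows, hotspot_catalog, thresholds)
    if karyotype is None:
        missing.append("karyotype")
    return EvidenceBundle(sample_id=sample_id, expression=expression,
                          karyotype=karyotype, fusions=fusions,
                          hotspots=hotspots, missing_inputs=missing)


def summarize_cohort(assignments: Sequence[SubtypeAssignment]) -> dict[str, pd.DataFrame]:
    """Cross-tabulate assignments by status, basis, curation category, subtype."""
    if not assignments:
        raise ValueError("no assignments to summarize")
    df = pd.DataFrame([vars(a) for a in assignments])
    out = {}
    for key in ("status", "basis", "curation_category", "icc_label"):
        counts = df[key].replace("", "(none)").value_counts()
        out[key] = pd.DataFrame({"count": counts,
                                 "percent": 100 * counts / len(df)})
    return out
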