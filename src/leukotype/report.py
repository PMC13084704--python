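"""Per-sample and cohort orchestration plus static report rendering.

Composes the pipeline stages — feature extraction, virtual-karyotype
prediction, driver harmonization/filtering, rule-based classification —
over per-sample input tables, with per-stage error attribution and
per-sample crash isolation in cohort runs.  Reports are emitted as
machine-readable JSON plus a static, dependency-free Markdown document
(sections: classification summary, karyotype, fusions, hotspots,
expression prediction).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import karyotype as kt
from .drivers import (HotspotThresholds, load_fusion_catalog,
                      load_hotspot_catalog, read_arriba, read_fusioncatcher)
from .rules import (EvidenceBundle, ExpressionPrediction, SubtypeAssignment,
                    classify, collect_evidence, load_ruleset,
                    summarize_cohort)

logger = logging.getLogger(__name__)

SAMPLE_INPUT_KEYS = ("dosage", "maf", "arriba", "fusioncatcher", "pileup",
                     "gep")


class StageError(RuntimeError):
    """Pipeline failure attributed to a stage and sample."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration; hashed into every output for reruns."""

    fusion_catalog: str | None = None
    hotspot_catalog: str | None = None
    ruleset: str | None = None
    model: str | None = None
    min_depth: int = 10
    min_alt: int = 3
    min_vaf: float = 0.05
    seed: int = 0
    out_dir: str = "."
    verbosity: str = "INFO"

    def validate(self) -> "RunConfig":
        for name in ("fusion_catalog", "hotspot_catalog", "ruleset", "model"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config {name} points to missing file {path}")
        return self

    @property
    def thresholds(self) -> HotspotThresholds:
        return HotspotThresholds(self.min_depth, self.min_alt, self.min_vaf)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {})).validate()


@dataclass
class SampleReport:
    sample_id: str
    evidence: EvidenceBundle
    karyotype: kt.KaryotypeCall | None
    assignment: SubtypeAssignment
    metadata: dict[str, Any] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        expr = self.evidence.expression
        return {
            "sample_id": self.sample_id,
            "assignment": dataclasses.asdict(self.assignment),
            "karyotype": (None if self.karyotype is None else
                          dataclasses.asdict(self.karyotype)),
            "expression": dataclasses.asdict(expr),
            "fusions": [dict(five_prime_gene=f.five_prime_gene,
                             three_prime_gene=f.three_prime_gene,
                             callers=sorted(f.callers),
                             supporting_reads=f.supporting_reads,
                             defining_subtype=f.defining_subtype)
                        for f in self.evidence.fusions],
            "hotspots": [dataclasses.asdict(h) for h in self.evidence.hotspots],
            "missing_inputs": list(self.evidence.missing_inputs),
            "metadata": self.metadata,
            "input_checksums": self.input_checksums,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_json_default,
                          sort_keys=True, **kwargs)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _read_gep(path: str | Path) -> ExpressionPrediction:
    df = pd.read_csv(path, sep="\t")
    row = df.iloc[0]
    return ExpressionPrediction(
        subtype=str(row.get("Prediction", "") or ""),
        tier=str(row.get("Confidence", "unclassified")),
        blast_pct=float(row.get("blast_pct", float("nan"))),
        sex=str(row.get("sex", "")),
        immunophenotype=str(row.get("immunophenotype", "")))


def run_sample(config: RunConfig, sample_id: str,
               inputs: Mapping[str, str | Path]) -> SampleReport:
    """Run the full per-sample pipeline over a mapping of input paths.

    ``inputs`` maps the keys dosage/maf/arriba/fusioncatcher/pileup/gep to
    file paths; gep is mandatory, other layers optional (recorded absent).
    Any stage failure surfaces as a :class:`StageError` naming the stage.
    """
    config.validate()
    checksums = {k: _md5(p) for k, p in inputs.items()
                 if p is not None and Path(p).exists()}
    fusion_catalog = load_fusion_catalog(config.fusion_catalog)
    hotspot_catalog = load_hotspot_catalog(config.hotspot_catalog)
    ruleset = load_ruleset(config.ruleset, fusion_catalog, hotspot_catalog)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError(name, sample_id, exc) from exc

    if "gep" not in inputs or inputs["gep"] is None:
        raise StageError("inputs", sample_id,
                         ValueError("expression prediction (gep) is mandatory"))
    expression = stage("inputs", _read_gep, inputs["gep"])

    karyotype_call = None
    if config.model and inputs.get("dosage") and inputs.get("maf"):
        def _karyotype():
            dosage = pd.read_csv(inputs["dosage"], sep="\t",
                                 dtype={"chrom": str})
            maf = pd.read_csv(inputs["maf"], sep="\t", dtype={"chrom": str})
            vector = feat.extract_features(dosage, maf)
            model = kt.load_model(config.model,
                                  expected_manifest=feat.FEATURE_NAMES)
            return kt.predict(model, vector)
        # feature extraction errors belong to the features stage
        try:
            karyotype_call = _karyotype()
        except Exception as exc:  # noqa: BLE001
            if isinstance(exc, (kt.ModelError,)):
                raise StageError("karyotype", sample_id, exc) from exc
            raise StageError("features", sample_id, exc) from exc

    def _drivers():
        arriba = (read_arriba(inputs["arriba"])
                  if inputs.get("arriba") else None)
        fc = (read_fusioncatcher(inputs["fusioncatcher"])
              if inputs.get("fusioncatcher") else None)
        pileup = (pd.read_csv(inputs["pileup"], sep="\t",
                              dtype={"chrom": str})
                  if inputs.get("pileup") else None)
        return collect_evidence(sample_id, expression, arriba, fc, pileup,
                                karyotype_call, fusion_catalog,
                                hotspot_catalog, config.thresholds)

    evidence = stage("drivers", _drivers)
    assignment = stage("rules", classify, evidence, ruleset)
    metadata = {"ruleset_version": ruleset.version,
                "config_hash": config.digest(), "seed": config.seed}
    return SampleReport(sample_id=sample_id, evidence=evidence,
                        karyotype=karyotype_call, assignment=assignment,
                        metadata=metadata, input_checksums=checksums)


def run_cohort(config: RunConfig, sample_sheet: pd.DataFrame
               ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run every sample in a sheet; failures are isolated per sample.

    The sheet has a ``sample_id`` column plus per-layer path columns.
    Returns (one row per sample, cohort summary tables).
    """
    if sample_sheet.empty:
        raise ValueError("empty sample sheet")
    rows = []
    assignments = []
    for _, sheet_row in sample_sheet.iterrows():
        sample_id = str(sheet_row["sample_id"])
        inputs = {k: sheet_row.get(k) for k in SAMPLE_INPUT_KEYS
                  if pd.notna(sheet_row.get(k))}
        try:
            report = run_sample(config, sample_id, inputs)
        except Exception as exc:  # noqa: BLE001 - isolation by design
            logger.error("sample %s failed: %s", sample_id, exc)
            rows.append({"sample_id": sample_id, "status": "failed",
                         "error": str(exc)})
            continue
        a = report.assignment
        expr = report.evidence.expression
        rows.append({
            "sample_id": sample_id, "status": a.status,
            "icc_label": a.icc_label, "who_label": a.who_label,
            "basis": a.basis, "curation_category": a.curation_category,
            "karyotype": ("" if report.karyotype is None
                          else report.karyotype.label),
            "drivers": "; ".join(
                [str(f) for f in report.evidence.fusions]
                + [str(h) for h in report.evidence.hotspots
                   if h.defining_subtype]),
            "expression": expr.subtype, "tier": expr.tier,
            "blast_pct": expr.blast_pct, "sex": expr.sex,
            "config_hash": report.metadata["config_hash"],
            "seed": config.seed, "error": ""})
        assignments.append(a)
    table = pd.DataFrame(rows)
    summary = summarize_cohort(assignments) if assignments else {}
    return table, summary


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------
def render_report(report: SampleReport) -> str:
    """Static Markdown document for one sample (no external resources)."""
    a = report.assignment
    expr = report.evidence.expression
    lines = [f"# Sample {report.sample_id}", "",
             "## Classification summary", ""]
    if a.status == "automatic":
        lines += [f"- Status: **automatic**",
                  f"- ICC label: {a.icc_label}",
                  f"- WHO-HAEM5 label: {a.who_label or 'not represented'}",
                  f"- Basis: {a.basis}"]
    else:
        lines += [f"- Status: **manual curation**",
                  f"- Curation category: {a.curation_category}"]
    lines += ["", f"- Evidence: {a.evidence_summary}", "", "## Karyotype", ""]
    if report.karyotype is None:
        lines.append("No virtual karyotype call (model or dosage/MAF input absent).")
    else:
        lines.append(f"Predicted class: **{report.karyotype.label}**")
        lines += ["", "| class | probability |", "| --- | --- |"]
        for cls, p in sorted(report.karyotype.probabilities.items()):
            lines.append(f"| {cls} | {p:.4f} |")
    lines += ["", "## Gene fusions", ""]
    if report.evidence.fusions:
        lines += ["| fusion | callers | reads | subtype |", "| --- | --- | --- | --- |"]
        for f in report.evidence.fusions:
            lines.append(f"| {f} | {','.join(sorted(f.callers))} | "
                         f"{f.supporting_reads} | {f.defining_subtype or ''} |")
    else:
        lines.append("No catalog-matched fusion calls.")
    lines += ["", "## Hotspot SNVs", ""]
    if report.evidence.hotspots:
        lines += ["| hotspot | VAF | depth | role |", "| --- | --- | --- | --- |"]
        for h in report.evidence.hotspots:
            role = h.defining_subtype or "cooperating"
            lines.append(f"| {h} | {h.vaf:.3f} | {h.depth} | {role} |")
    else:
        lines.append("No high-confidence hotspot calls.")
    lines += ["", "## Expression prediction", "",
              f"- Subtype: {expr.subtype or '(unclassified)'}",
              f"- Confidence tier: {expr.tier}",
              f"- Blast proportion: {expr.blast_pct}%",
              f"- Sex: {expr.sex}",
              f"- Immunophenotype: {expr.immunophenotype}", "",
              "## Run metadata", ""]
    for k, v in sorted(report.metadata.items()):
        lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"


def render_cohort_summary(table: pd.DataFrame,
                          summary: dict[str, pd.DataFrame]) -> str:
    lines = ["# Cohort summary", "", f"Samples: {len(table)}", ""]
    for key, df in summary.items():
        lines += [f"## By {key}", "", "| value | count | percent |",
                  "| --- | --- | --- |"]
        for value, row in df.iterrows():
            lines.append(f"| {value} | {int(row['count'])} | "
                         f"{row['percent']:.1f} |")
        lines.append("")
    return "\n".join(lines) + "\n"
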