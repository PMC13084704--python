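"""Seeded synthetic B-ALL cohort generator.

Emulates the tables an RNA-seq subtyping pipeline consumes — per-gene
dosage (log2 fold-change vs a diploid reference with expression weights),
per-SNV minor-allele fractions, fusion calls in two caller dialects,
hotspot pileups and expression-classifier prediction records — with the
statistical structure the downstream classifier and rule engine assume:

* five karyotype classes: near-haploid (modal 23-29 chromosomes, chr21/X
  preferentially retained disomic, and with probability 0.5 "masked", i.e.
  whole-genome doubled so dosage looks disomic while MAF shows
  genome-wide loss of heterozygosity), low-hypodiploid (33-39),
  high-hyperdiploid (52-67, gains favouring chromosomes 4/6/10/14/17/18/21/X),
  iAMP21/chr21-amplification (near-diploid with a focal
  chr21:25,772,460-39,428,528 gain at copy number >= 5), and diploid "other";
* per-gene log2FC ~ Normal(log2(effective_cn / 2), sd) with gene counts
  proportional to GRCh38 chromosome lengths;
* folded MAF from binomial read sampling at Poisson depth: 0.5 for balanced
  disomy, 1/3 for trisomy, near 0 under LOH;
* driver evidence (fusions, hotspot SNVs, expression predictions)
  consistent with a chosen molecular subtype, including double-driver
  constellations and degraded-evidence scenarios that exercise every manual
  curation category.

Chromosome Y is excluded throughout: expression-based copy-number inference
on Y is unreliable.  The generator does not model raw reads, subclonality,
contamination or realistic gene-level expression programs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .drivers import (BASES, FusionCatalog, HotspotCatalog,
                      load_fusion_catalog, load_hotspot_catalog)
from .features import (CHROMOSOMES, IAMP21_REGION_END, IAMP21_REGION_START)
from .karyotype import KARYOTYPE_CLASSES, KaryotypeCall
from .rules import RuleSet, SubtypeRule, load_ruleset

logger = logging.getLogger(__name__)

#: GRCh38 chromosome lengths (bp), chromosomes 1-22 and X
CHROM_LENGTHS: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895,
}

#: chromosomes preferentially gained in high-hyperdiploid B-ALL
HYPERDIPLOID_PREFERRED = ("4", "6", "10", "14", "17", "18", "21", "X")
#: chromosomes preferentially retained disomic in near-haploid B-ALL
NEAR_HAPLOID_RETAINED = ("21", "X")

MODAL_RANGES = {"near_haploid": (23, 29), "low_hypodiploid": (33, 39),
                "high_hyperdiploid": (52, 67)}

DEFAULT_MASK_PROB = 0.5
#: log2FC floor for genes on zero-copy chromosomes (ratio floor 0.1/2)
ZERO_COPY_RATIO_FLOOR = 0.1
#: background non-reference read rate at homozygous sites
SEQ_ERROR_RATE = 0.005

EVIDENCE_SCENARIOS = ("full", "missed", "discordant", "unclassified")


class SimulationError(ValueError):
    """Invalid simulation request."""


# --------------------------------------------------------------------------
# karyotype states
# --------------------------------------------------------------------------
@dataclass
class ChromosomeCopyState:
    """Ground-truth per-chromosome copy number and LOH for one genome.

    ``masked`` marks chromosomes of a whole-genome-doubled near-haploid:
    copy number 2 with LOH, dosage-indistinguishable from disomy.
    ``modal_chromosome_count`` is recorded pre-doubling for masked genomes.
    """

    copy_number: dict[str, int]
    loh: dict[str, bool]
    masked: dict[str, bool]
    iamp21_flag: bool = False
    iamp21_region_cn: int = 2
    modal_chromosome_count: int = 46

    def __post_init__(self) -> None:
        for chrom in CHROMOSOMES:
            cn = self.copy_number[chrom]
            if cn < 0:
                raise SimulationError(f"negative copy number on chr{chrom}")
            if self.masked[chrom] and not (cn == 2 and self.loh[chrom]):
                raise SimulationError(
                    f"masked chr{chrom} must be copy-number 2 with LOH")

    def effective_copy_number(self, chrom: str) -> int:
        """Copy number as seen by expression dosage (masking applied)."""
        return 2 if self.masked[chrom] else self.copy_number[chrom]


def sample_karyotype(class_label: str, rng: np.random.Generator,
                     mask_prob: float = DEFAULT_MASK_PROB) -> ChromosomeCopyState:
    """Draw a ground-truth copy-number state for one karyotype class."""
    if class_label not in KARYOTYPE_CLASSES:
        raise SimulationError(f"unknown karyotype class {class_label!r}")
    cn = {c: 2 for c in CHROMOSOMES}
    loh = {c: False for c in CHROMOSOMES}
    masked = {c: False for c in CHROMOSOMES}
    modal = 46
    iamp21 = False
    region_cn = 2

    if class_label == "near_haploid":
        modal = int(rng.integers(23, 30))
        n_disomic = modal - 23
        order = list(NEAR_HAPLOID_RETAINED) + list(
            rng.permutation([c for c in CHROMOSOMES
                             if c not in NEAR_HAPLOID_RETAINED]))
        disomic = set(order[:n_disomic])
        for c in CHROMOSOMES:
            if c not in disomic:
                cn[c], loh[c] = 1, True
        if rng.random() < mask_prob:  # whole-genome doubling
            for c in CHROMOSOMES:
                if cn[c] == 1:
                    cn[c], masked[c] = 2, True
    elif class_label == "low_hypodiploid":
        modal = int(rng.integers(33, 40))
        weights = np.array([1.0 if c in NEAR_HAPLOID_RETAINED else 4.0
                            for c in CHROMOSOMES])
        lost = rng.choice(len(CHROMOSOMES), size=46 - modal, replace=False,
                          p=weights / weights.sum())
        for idx in lost:
            c = CHROMOSOMES[idx]
            cn[c], loh[c] = 1, True
    elif class_label == "high_hyperdiploid":
        modal = int(rng.integers(52, 68))
        weights = np.array([5.0 if c in HYPERDIPLOID_PREFERRED else 1.0
                            for c in CHROMOSOMES])
        for _ in range(modal - 46):
            open_idx = [i for i, c in enumerate(CHROMOSOMES) if cn[c] < 4]
            w = weights[open_idx]
            pick = rng.choice(open_idx, p=w / w.sum())
            cn[CHROMOSOMES[pick]] += 1
    elif class_label == "iamp21_chr21amp":
        iamp21 = True
        region_cn = int(rng.integers(5, 9))
    return ChromosomeCopyState(copy_number=cn, loh=loh, masked=masked,
                               iamp21_flag=iamp21, iamp21_region_cn=region_cn,
                               modal_chromosome_count=modal)


def truth_karyotype_call(state: ChromosomeCopyState,
                         class_label: str) -> KaryotypeCall:
    """Certain KaryotypeCall from generator ground truth (bypasses the model)."""
    return KaryotypeCall.certain(class_label)


# --------------------------------------------------------------------------
# dosage and MAF tables
# --------------------------------------------------------------------------
def _genes_per_chromosome(n_genes: int) -> dict[str, int]:
    """Largest-remainder allocation proportional to chromosome length."""
    lengths = np.array([CHROM_LENGTHS[c] for c in CHROMOSOMES], dtype=float)
    quota = n_genes * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    rest = n_genes - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rest]] += 1
    return dict(zip(CHROMOSOMES, base.tolist()))


def simulate_dosage(state: ChromosomeCopyState, n_genes: int = 15_000,
                    log2fc_sd: float = 0.25,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-gene dosage table: log2FC ~ Normal(log2(effective_cn/2), sd).

    Genes are placed uniformly along chromosomes, counts proportional to
    GRCh38 lengths.  Masked chromosomes emit effective copy number 2; genes
    on zero-copy chromosomes are drawn at a floor ratio rather than raising.
    For iAMP21 states the diagnostic chr21 region is topped up to >= 200
    genes and emits the amplified region copy number.
    """
    if n_genes < len(CHROMOSOMES):
        raise SimulationError("need at least one gene per chromosome")
    if log2fc_sd <= 0:
        raise SimulationError("log2fc_sd must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    alloc = _genes_per_chromosome(n_genes)
    chroms, starts = [], []
    for c in CHROMOSOMES:
        pos = np.sort(rng.integers(1, CHROM_LENGTHS[c] + 1, size=alloc[c]))
        chroms += [c] * alloc[c]
        starts.append(pos)
    starts = np.concatenate(starts)
    chrom_arr = np.array(chroms)
    if state.iamp21_flag:
        in_region = ((chrom_arr == "21") & (starts >= IAMP21_REGION_START)
                     & (starts <= IAMP21_REGION_END))
        deficit = 200 - int(in_region.sum())
        if deficit > 0:
            extra = np.sort(rng.integers(IAMP21_REGION_START,
                                         IAMP21_REGION_END + 1, size=deficit))
            chrom_arr = np.concatenate([chrom_arr, np.array(["21"] * deficit)])
            starts = np.concatenate([starts, extra])
    eff = np.array([state.effective_copy_number(c) for c in chrom_arr], float)
    if state.iamp21_flag:
        region = ((chrom_arr == "21") & (starts >= IAMP21_REGION_START)
                  & (starts <= IAMP21_REGION_END))
        eff[region] = state.iamp21_region_cn
    ratio = np.maximum(eff, ZERO_COPY_RATIO_FLOOR) / 2.0
    log2fc = rng.normal(np.log2(ratio), log2fc_sd)
    weight = np.log1p(rng.lognormal(mean=1.5, sigma=1.0, size=len(chrom_arr)))
    return pd.DataFrame({
        "gene_id": [f"G{i + 1:06d}" for i in range(len(chrom_arr))],
        "chrom": chrom_arr, "start": starts.astype(int),
        "log2fc": log2fc, "weight": weight})


def simulate_maf(state: ChromosomeCopyState, snvs_per_chrom: int = 30,
                 depth_mean: float = 80.0,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-SNV folded minor-allele-fraction table.

    Heterozygous sites on a chromosome with copy number c carry k of c
    allele copies (k uniform on 1..c-1), read-sampled binomially at
    Poisson(depth_mean) depth and folded to [0, 0.5]: balanced disomy
    centres at 0.5, trisomy at 1/3.  LOH chromosomes (including masked
    ones) are homozygous and emit only sequencing-error minor reads.
    """
    if snvs_per_chrom < 5:
        raise SimulationError("need at least 5 SNVs per chromosome")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for c in CHROMOSOMES:
        pos = np.sort(rng.integers(1, CHROM_LENGTHS[c] + 1,
                                   size=snvs_per_chrom))
        depth = np.maximum(1, rng.poisson(depth_mean, size=snvs_per_chrom))
        cn = state.copy_number[c]
        if state.loh[c] or cn < 2:
            f = np.full(snvs_per_chrom, SEQ_ERROR_RATE)
        else:
            k = rng.integers(1, cn, size=snvs_per_chrom)
            f = k / cn
        alt = rng.binomial(depth, f)
        raw = alt / depth
        rows.append(pd.DataFrame({"chrom": c, "pos": pos.astype(int),
                                  "depth": depth.astype(int),
                                  "maf": np.minimum(raw, 1.0 - raw)}))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# driver evidence
# --------------------------------------------------------------------------
def _detectable_fusions(rule: SubtypeRule,
                        catalog: FusionCatalog) -> pd.DataFrame:
    if not rule.defining_fusions:
        return catalog.entries.iloc[0:0]
    entries = catalog.entries_for(rule.icc_label)
    return entries[~entries["rna_insensitive"]]


def driver_generable(subtype: str, rules: RuleSet,
                     fusion_catalog: FusionCatalog) -> bool:
    """Can this subtype contribute RNA-seq-visible driver evidence?"""
    rule = rules[subtype]
    if rule.defining_karyotype is not None or rule.defining_snvs:
        return True
    return len(_detectable_fusions(rule, fusion_catalog)) > 0


def _fusion_rows(g5: str, g3: str, rng: np.random.Generator
                 ) -> tuple[dict, dict]:
    arriba = {"#gene1": g5, "gene2": g3, "confidence": "high",
              "split_reads1": int(rng.integers(5, 40)),
              "split_reads2": int(rng.integers(5, 40)),
              "discordant_mates": int(rng.integers(0, 20))}
    fc = {"Gene_1_symbol(5end_fusion_partner)": g5,
          "Gene_2_symbol(3end_fusion_partner)": g3,
          "Spanning_unique_reads": int(rng.integers(5, 40)),
          "Spanning_pairs": int(rng.integers(3, 25)),
          "Predicted_effect": "in-frame"}
    return arriba, fc


def _pileup_rows(snv: str, catalog: HotspotCatalog,
                 rng: np.random.Generator) -> list[dict]:
    gene, change = snv.split(" ", 1)
    entry = catalog.entries[(catalog.entries["gene"] == gene)
                            & (catalog.entries["codon_change"] == change)].iloc[0]
    depth = int(rng.integers(60, 121))
    vaf = float(rng.uniform(0.35, 0.5))
    alt = max(int(round(depth * vaf)), 1)
    row = {"chrom": str(entry.chrom), "pos": int(entry.pos),
           "ref": entry.ref_base, "depth": depth,
           **{b: 0 for b in BASES}}
    row[entry.alt_base] = alt
    row[entry.ref_base] = depth - alt
    return [row]


def simulate_evidence(subtype: str, secondary_subtype: str | None = None,
                      rng: np.random.Generator | None = None,
                      tier: str = "high_confidence",
                      expression_label: str | None = None,
                      rules: RuleSet | None = None,
                      fusion_catalog: FusionCatalog | None = None,
                      hotspot_catalog: HotspotCatalog | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Driver evidence and expression prediction for a molecular subtype.

    Returns (arriba_rows, fusioncatcher_rows, pileup_rows, gep_record).  The
    subtype's defining fusion (if RNA-seq-detectable) is emitted in both
    caller dialects; a defining SNV as pileup rows clearing the default
    filter thresholds; karyotype-defined and expression-only subtypes emit
    no fusion/SNV evidence (their driver lives in the copy-number state or
    nowhere, respectively).  The expression prediction is drawn from the
    primary subtype only — in double-driver samples a single expression
    program predominates.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rules = rules or load_ruleset()
    fusion_catalog = fusion_catalog or load_fusion_catalog()
    hotspot_catalog = hotspot_catalog or load_hotspot_catalog()
    if subtype not in rules:
        raise SimulationError(f"unknown subtype {subtype!r}")
    arriba_rows, fc_rows, pileup = [], [], []
    for name in filter(None, (subtype, secondary_subtype)):
        rule = rules[name]
        detectable = _detectable_fusions(rule, fusion_catalog)
        if len(detectable):
            entry = detectable.iloc[int(rng.integers(len(detectable)))]
            a, f = _fusion_rows(entry.five_prime_gene, entry.three_prime_gene,
                                rng)
            arriba_rows.append(a)
            fc_rows.append(f)
        elif rule.defining_snvs:
            pileup += _pileup_rows(rule.defining_snvs[0], hotspot_catalog, rng)
        # karyotype-defined / expression-only: nothing to emit here
    if not pileup:  # a background reference-only position
        pileup.append({"chrom": "1", "pos": 1_000_000, "ref": "A",
                       "depth": int(rng.integers(40, 100)),
                       "A": 0, "C": 0, "G": 0, "T": 0})
        pileup[-1]["A"] = pileup[-1]["depth"]
    label = (expression_label if expression_label is not None
             else rules[subtype].primary_expression)
    if tier == "unclassified":
        label = ""
    gep = pd.DataFrame([{
        "Prediction": label, "Confidence": tier,
        "blast_pct": round(float(rng.uniform(50, 95)), 1),
        "sex": str(rng.choice(["female", "male"])),
        "immunophenotype": str(rng.choice(["pre-B", "common", "pro-B"],
                                          p=[0.45, 0.4, 0.15]))}])
    arriba_cols = ["#gene1", "gene2", "confidence", "split_reads1",
                   "split_reads2", "discordant_mates"]
    fc_cols = list(_fusion_rows("A", "B", np.random.default_rng(0))[1])
    return (pd.DataFrame(arriba_rows, columns=arriba_cols),
            pd.DataFrame(fc_rows, columns=fc_cols),
            pd.DataFrame(pileup,
                         columns=["chrom", "pos", "ref", "depth", *BASES]),
            gep)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------
@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_per_class: Mapping[str, int]
    subtype_mix: Mapping[str, float] | None = None  # None = uniform
    double_driver_rate: float = 0.026
    evidence_completeness: float = 0.8
    n_genes: int = 15_000
    log2fc_sd: float = 0.25
    snvs_per_chrom: int = 30
    maf_depth_mean: float = 80.0
    mask_prob: float = DEFAULT_MASK_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in KARYOTYPE_CLASSES:
                raise SimulationError(f"unknown karyotype class {cls!r}")
            if n < 0:
                raise SimulationError("negative class count")
        if self.subtype_mix is not None:
            total = sum(self.subtype_mix.values())
            if abs(total - 1.0) > 1e-6:
                raise SimulationError(f"subtype_mix sums to {total}, not 1")
        if not 0 <= self.double_driver_rate <= 1:
            raise SimulationError("double_driver_rate must be in [0, 1]")


@dataclass
class SyntheticSample:
    sample_id: str
    karyotype_class: str
    state: ChromosomeCopyState
    dosage: pd.DataFrame
    maf: pd.DataFrame
    arriba: pd.DataFrame
    fusioncatcher: pd.DataFrame
    pileup: pd.DataFrame
    gep: pd.DataFrame
    subtype: str
    secondary_subtype: str = ""
    scenario: str = "full"


@dataclass
class SyntheticCohort:
    samples: list[SyntheticSample]
    truth: pd.DataFrame
    spec: CohortSpec

    def write(self, out_dir: str | Path) -> None:
        """Write the per-sample TSVs and the ground-truth table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            for name, df in (("dosage", s.dosage), ("maf", s.maf),
                             ("arriba", s.arriba),
                             ("fusioncatcher", s.fusioncatcher),
                             ("pileup", s.pileup), ("gep", s.gep)):
                df.to_csv(out / f"{s.sample_id}.{name}.tsv", sep="\t",
                          index=False, float_format="%.6g")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                          float_format="%.6g")


_KARYOTYPE_SUBTYPE = {"near_haploid": "Near haploid",
                      "low_hypodiploid": "Low hypodiploid",
                      "high_hyperdiploid": "Hyperdiploid",
                      "iamp21_chr21amp": "iAMP21/chr21-amplification"}


def _degrade(scenario: str, rule: SubtypeRule, rules: RuleSet,
             rng: np.random.Generator) -> tuple[str, str, bool]:
    """(tier, expression_label, emit_driver) for an evidence scenario."""
    if scenario == "full":
        return "high_confidence", rule.primary_expression, True
    if scenario == "missed":
        return "candidate", rule.primary_expression, False
    if scenario == "discordant":
        others = sorted({r.primary_expression for r in rules}
                        - set(rule.expression))
        return ("high_confidence", others[int(rng.integers(len(others)))],
                True)
    return "unclassified", "", False


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Deterministic cohort bundle: per-sample tables plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    rules = load_ruleset()
    fusion_catalog = load_fusion_catalog()
    hotspot_catalog = load_hotspot_catalog()
    driver_subtypes = sorted(
        r.icc_label for r in rules
        if r.defining_karyotype is None
        and driver_generable(r.icc_label, rules, fusion_catalog))
    # default mix: subtypes with RNA-seq-visible drivers or an
    # expression-only allowance (IG-only fusion entities are too rare to
    # seed by default; pass subtype_mix to include them)
    other_subtypes = sorted(
        r.icc_label for r in rules
        if r.defining_karyotype is None
        and (r.allowance or driver_generable(r.icc_label, rules,
                                             fusion_catalog)))
    if spec.subtype_mix is not None:
        other_subtypes = sorted(spec.subtype_mix)
        mix_p = np.array([spec.subtype_mix[s] for s in other_subtypes])
    else:
        mix_p = np.full(len(other_subtypes), 1.0 / len(other_subtypes))

    samples: list[SyntheticSample] = []
    truth_rows = []
    i = 0
    for cls in sorted(spec.n_per_class):
        for _ in range(spec.n_per_class[cls]):
            i += 1
            sample_id = f"S{i:04d}"
            state = sample_karyotype(cls, rng, mask_prob=spec.mask_prob)
            dosage = simulate_dosage(state, spec.n_genes, spec.log2fc_sd, rng)
            maf = simulate_maf(state, spec.snvs_per_chrom,
                               spec.maf_depth_mean, rng)
            if cls == "other":
                subtype = other_subtypes[int(rng.choice(len(other_subtypes),
                                                        p=mix_p))]
            else:
                subtype = _KARYOTYPE_SUBTYPE[cls]
            rule = rules[subtype]
            scenario = "full"
            if rng.random() >= spec.evidence_completeness:
                choices = ["missed", "discordant", "unclassified"]
                if rule.defining_karyotype is not None:
                    choices = ["discordant", "unclassified"]
                scenario = choices[int(rng.integers(len(choices)))]
            secondary = ""
            primary_has_driver = (rule.defining_karyotype is not None
                                  or driver_generable(subtype, rules,
                                                      fusion_catalog))
            if (scenario == "full" and primary_has_driver
                    and rng.random() < spec.double_driver_rate):
                pool = [s for s in driver_subtypes if s != subtype]
                secondary = pool[int(rng.integers(len(pool)))]
            tier, label, emit = _degrade(scenario, rule, rules, rng)
            arriba, fc, pileup, gep = simulate_evidence(
                subtype, secondary or None, rng, tier=tier,
                expression_label=label, rules=rules,
                fusion_catalog=fusion_catalog,
                hotspot_catalog=hotspot_catalog)
            if not emit:  # missed/unclassified: drop the driver evidence
                arriba, fc = arriba.iloc[0:0], fc.iloc[0:0]
                ref_reads = pileup.apply(lambda r: r[r["ref"]], axis=1)
                pileup = pileup[ref_reads == pileup["depth"]]
            samples.append(SyntheticSample(
                sample_id=sample_id, karyotype_class=cls, state=state,
                dosage=dosage, maf=maf, arriba=arriba, fusioncatcher=fc,
                pileup=pileup, gep=gep, subtype=subtype,
                secondary_subtype=secondary, scenario=scenario))
            truth_rows.append({
                "sample_id": sample_id, "karyotype_class": cls,
                "modal_chromosome_count": state.modal_chromosome_count,
                "masked": any(state.masked.values()),
                "subtype": subtype, "secondary_subtype": secondary,
                "scenario": scenario,
                "expression_label": gep["Prediction"].iloc[0],
                "tier": gep["Confidence"].iloc[0]})
    return SyntheticCohort(samples=samples,
                           truth=pd.DataFrame(truth_rows), spec=spec)
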