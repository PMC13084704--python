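"""Driver catalogs, fusion-call harmonization and hotspot-SNV filtering.

B-ALL molecular subtypes are largely defined by driver lesions: gene fusions
(e.g. ``BCR::ABL1``, ``ETV6::RUNX1``), recurrent hotspot SNVs (e.g. PAX5
p.P80R, IKZF1 p.N159Y) or aneuploid karyotypes.  This module houses the
subtype-defining fusion and hotspot catalogs, merges fusion calls produced by
two RNA-seq fusion callers (ARRIBA-style and FusionCatcher-style TSV
dialects) into caller-agnostic :class:`FusionCall` records, and filters raw
per-position pileup rows into high-confidence :class:`HotspotCall` records.

The bundled catalogs (``data/fusion_catalog.synthetic.tsv``,
``data/hotspot_catalog.synthetic.tsv``) are synthetic curations assembled
from public B-ALL literature; they carry a source tag so users can substitute
their own files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DATA = resources.files("leukotype") / "data"
DEFAULT_FUSION_CATALOG = Path(str(_DATA / "fusion_catalog.synthetic.tsv"))
DEFAULT_HOTSPOT_CATALOG = Path(str(_DATA / "hotspot_catalog.synthetic.tsv"))

BASES = ("A", "C", "G", "T")


class CatalogError(ValueError):
    """Malformed or inconsistent driver catalog."""


# --------------------------------------------------------------------------
# catalogs
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class FusionCatalog:
    """Catalog of subtype-defining gene fusions.

    ``entries`` has columns ``five_prime_gene``, ``three_prime_gene``,
    ``defining_subtype``, ``orientation_specific`` and (optionally)
    ``rna_insensitive`` marking IG-partner fusions that RNA-seq callers
    routinely miss.
    """

    entries: pd.DataFrame
    source: str = "unknown"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subtypes(self) -> set[str]:
        return set(self.entries["defining_subtype"])

    def entries_for(self, subtype: str) -> pd.DataFrame:
        return self.entries[self.entries["defining_subtype"] == subtype]


@dataclass(frozen=True)
class HotspotCatalog:
    """Curated hotspot SNV positions (defining or cooperating lesions)."""

    entries: pd.DataFrame
    source: str = "unknown"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self.entries["gene"])

    def defining_subtype_of(self, gene: str, codon_change: str) -> str:
        m = self.entries[(self.entries["gene"] == gene)
                         & (self.entries["codon_change"] == codon_change)]
        if m.empty:
            return ""
        return str(m["defining_subtype"].iloc[0])


def _canonical_pair(g1: str, g2: str) -> tuple[str, str]:
    return tuple(sorted((g1, g2)))  # type: ignore[return-value]


def load_fusion_catalog(path: str | Path | None = None) -> FusionCatalog:
    """Load a fusion catalog TSV, rejecting duplicate unordered gene pairs."""
    path = Path(path) if path is not None else DEFAULT_FUSION_CATALOG
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"five_prime_gene", "three_prime_gene", "defining_subtype"}
    if missing := required - set(df.columns):
        raise CatalogError(f"fusion catalog {path} lacks columns {sorted(missing)}")
    if df.empty:
        logger.warning("fusion catalog %s is empty", path)
    for col, default in (("orientation_specific", "False"),
                         ("rna_insensitive", "False")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
    bad = df["five_prime_gene"].isna() | df["three_prime_gene"].isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # header + 1-based
        raise CatalogError(f"fusion catalog {path}: malformed row at line {lineno}")
    for g in ("five_prime_gene", "three_prime_gene"):
        df[g] = df[g].str.strip().str.upper()
    keys = [_canonical_pair(a, b) for a, b in
            zip(df["five_prime_gene"], df["three_prime_gene"])]
    dup_mask = pd.Series(keys).duplicated(keep=False) & ~df["orientation_specific"].values
    if dup_mask.any():
        lines = [str(i + 2) for i in np.flatnonzero(dup_mask.values)]
        raise CatalogError(
            f"fusion catalog {path}: duplicate unordered gene pair at lines "
            + ", ".join(lines))
    source = df["source"].iloc[0] if "source" in df.columns and len(df) else "unknown"
    return FusionCatalog(entries=df.reset_index(drop=True), source=str(source))


def load_hotspot_catalog(path: str | Path | None = None) -> HotspotCatalog:
    """Load a hotspot catalog TSV (chrom/pos/ref/alt plus codon-change label)."""
    path = Path(path) if path is not None else DEFAULT_HOTSPOT_CATALOG
    df = pd.read_csv(path, sep="\t",
                     dtype={"chrom": str, "gene": str, "ref_base": str,
                            "alt_base": str, "codon_change": str})
    required = {"gene", "chrom", "pos", "ref_base", "alt_base", "codon_change"}
    if missing := required - set(df.columns):
        raise CatalogError(f"hotspot catalog {path} lacks columns {sorted(missing)}")
    if "defining_subtype" not in df.columns:
        df["defining_subtype"] = ""
    df["defining_subtype"] = df["defining_subtype"].fillna("")
    df["pos"] = df["pos"].astype(int)
    if df.duplicated(["chrom", "pos", "alt_base"]).any():
        raise CatalogError(f"hotspot catalog {path}: duplicate position/alt entries")
    source = df["source"].iloc[0] if "source" in df.columns and len(df) else "unknown"
    return HotspotCatalog(entries=df.reset_index(drop=True), source=str(source))


# --------------------------------------------------------------------------
# fusion calls
# --------------------------------------------------------------------------
@dataclass
class FusionCall:
    five_prime_gene: str
    three_prime_gene: str
    callers: set[str] = field(default_factory=set)
    supporting_reads: int = 0
    caller_confidence: str = ""
    defining_subtype: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return _canonical_pair(self.five_prime_gene, self.three_prime_gene)

    def __str__(self) -> str:  # "BCR::ABL1"
        return f"{self.five_prime_gene}::{self.three_prime_gene}"


ARRIBA_GENE_COLS = ("gene1", "gene2")
FUSIONCATCHER_GENE_COLS = ("Gene_1_symbol(5end_fusion_partner)",
                           "Gene_2_symbol(3end_fusion_partner)")


def read_arriba(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Parse an ARRIBA-style TSV into (gene1, gene2, reads, confidence) rows.

    Requires the two gene-symbol columns (``#gene1``/``gene1`` and ``gene2``),
    ``confidence`` and the split/spanning read counts; extra columns are
    ignored.  Rows without both gene symbols are skipped with a warning.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if not set(ARRIBA_GENE_COLS) <= set(df.columns):
        raise CatalogError("ARRIBA table lacks gene1/gene2 columns")
    out = []
    for idx, row in df.iterrows():
        g1, g2 = row.get("gene1"), row.get("gene2")
        if pd.isna(g1) or pd.isna(g2) or not str(g1).strip() or not str(g2).strip():
            logger.warning("skipping unparseable ARRIBA row %s", idx)
            continue
        reads = sum(int(row.get(c, 0) or 0)
                    for c in ("split_reads1", "split_reads2", "discordant_mates"))
        out.append(dict(five_prime_gene=str(g1).strip().upper(),
                        three_prime_gene=str(g2).strip().upper(),
                        supporting_reads=reads,
                        caller_confidence=str(row.get("confidence", "")),
                        caller="arriba"))
    return pd.DataFrame(out, columns=["five_prime_gene", "three_prime_gene",
                                      "supporting_reads", "caller_confidence",
                                      "caller"])


def read_fusioncatcher(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Parse a FusionCatcher-style TSV; analogous to :func:`read_arriba`."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    c5, c3 = FUSIONCATCHER_GENE_COLS
    if not {c5, c3} <= set(df.columns):
        raise CatalogError("FusionCatcher table lacks gene symbol columns")
    out = []
    for idx, row in df.iterrows():
        g1, g2 = row.get(c5), row.get(c3)
        if pd.isna(g1) or pd.isna(g2) or not str(g1).strip() or not str(g2).strip():
            logger.warning("skipping unparseable FusionCatcher row %s", idx)
            continue
        reads = sum(int(row.get(c, 0) or 0)
                    for c in ("Spanning_unique_reads", "Spanning_pairs"))
        out.append(dict(five_prime_gene=str(g1).strip().upper(),
                        three_prime_gene=str(g2).strip().upper(),
                        supporting_reads=reads,
                        caller_confidence=str(row.get("Predicted_effect", "")),
                        caller="fusioncatcher"))
    return pd.DataFrame(out, columns=["five_prime_gene", "three_prime_gene",
                                      "supporting_reads", "caller_confidence",
                                      "caller"])


def harmonize_fusion_calls(arriba_rows: pd.DataFrame | None,
                           fusioncatcher_rows: pd.DataFrame | None,
                           ) -> list[FusionCall]:
    """Merge parsed caller rows into one :class:`FusionCall` per gene pair.

    Merging is orientation-insensitive: ``ABL1::BCR`` and ``BCR::ABL1`` meet
    in one call (callers unioned).  Per caller, supporting reads of repeated
    rows are summed; across callers the maximum is retained.  The reported
    orientation is the first seen (ARRIBA first).  Output is sorted by
    canonical gene pair.
    """
    frames = [f for f in (arriba_rows, fusioncatcher_rows)
              if f is not None and len(f)]
    if not frames:
        return []
    rows = pd.concat(frames, ignore_index=True)
    calls: dict[tuple[str, str], FusionCall] = {}
    per_caller: dict[tuple[str, str], dict[str, int]] = {}
    for _, row in rows.iterrows():
        key = _canonical_pair(row.five_prime_gene, row.three_prime_gene)
        if key not in calls:
            calls[key] = FusionCall(five_prime_gene=row.five_prime_gene,
                                    three_prime_gene=row.three_prime_gene,
                                    caller_confidence=row.caller_confidence)
            per_caller[key] = {}
        calls[key].callers.add(row.caller)
        per_caller[key][row.caller] = (per_caller[key].get(row.caller, 0)
                                       + int(row.supporting_reads))
    for key, call in calls.items():
        call.supporting_reads = max(per_caller[key].values())
    return [calls[k] for k in sorted(calls)]


def match_fusions(calls: Iterable[FusionCall],
                  catalog: FusionCatalog) -> list[FusionCall]:
    """Return the subset of calls matching catalog entries, subtype attached.

    Matching is on the unordered gene pair unless the catalog entry is
    orientation-specific, in which case the reported 5'/3' order must agree.
    Non-matching calls are simply excluded (callers keep them in raw output).
    """
    by_pair: dict[tuple[str, str], list[pd.Series]] = {}
    for _, entry in catalog.entries.iterrows():
        by_pair.setdefault(
            _canonical_pair(entry.five_prime_gene, entry.three_prime_gene),
            []).append(entry)
    matched = []
    for call in calls:
        for entry in by_pair.get(call.pair, []):
            if entry.orientation_specific and (
                    call.five_prime_gene != entry.five_prime_gene
                    or call.three_prime_gene != entry.three_prime_gene):
                continue
            m = FusionCall(call.five_prime_gene, call.three_prime_gene,
                           set(call.callers), call.supporting_reads,
                           call.caller_confidence,
                           defining_subtype=str(entry.defining_subtype))
            matched.append(m)
            break
    return matched


# --------------------------------------------------------------------------
# hotspot filtering
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class HotspotThresholds:
    """Minimum evidence for a high-confidence hotspot call."""

    min_depth: int = 10
    min_alt: int = 3
    min_vaf: float = 0.05


@dataclass
class HotspotCall:
    gene: str
    codon_change: str
    vaf: float
    depth: int
    alt_reads: int
    defining_subtype: str = ""

    def __str__(self) -> str:
        return f"{self.gene} {self.codon_change}"


def filter_hotspots(pileup_rows: pd.DataFrame,
                    catalog: HotspotCatalog,
                    thresholds: HotspotThresholds | None = None,
                    ) -> list[HotspotCall]:
    """Filter pileup rows (chrom, pos, ref, depth, A/C/G/T) to catalog hits.

    A row is retained iff its position and alt allele are in the catalog and
    depth/alt-read/VAF thresholds are met.  Pure function of rows +
    thresholds: no hidden state.
    """
    thresholds = thresholds or HotspotThresholds()
    if pileup_rows.empty:
        return []
    counts = pileup_rows[list(BASES)].to_numpy()
    if (counts < 0).any() or (pileup_rows["depth"] < 0).any():
        raise ValueError("negative counts in pileup rows")
    idx = {(str(r.chrom), int(r.pos)): i for i, r in
           enumerate(pileup_rows.itertuples())}
    out = []
    for _, entry in catalog.entries.iterrows():
        i = idx.get((str(entry.chrom), int(entry.pos)))
        if i is None:
            continue
        row = pileup_rows.iloc[i]
        depth = int(row["depth"])
        alt_reads = int(row[entry.alt_base])
        if depth < thresholds.min_depth or alt_reads < thresholds.min_alt:
            continue
        vaf = alt_reads / depth if depth else 0.0
        if vaf < thresholds.min_vaf:
            continue
        out.append(HotspotCall(gene=str(entry.gene),
                               codon_change=str(entry.codon_change),
                               vaf=vaf, depth=depth, alt_reads=alt_reads,
                               defining_subtype=str(entry.defining_subtype)))
    return out
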