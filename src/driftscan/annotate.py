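"""Offline region -> gene/QTL annotation and enrichment.

Outlier regions are intersected against user-supplied interval sets (gene
models and QTL tracks as BED, GFF3 or a simple gene-table TSV); category
tallies and a one-sided Fisher-exact (hypergeometric) over-representation
test with Benjamini-Hochberg adjustment replace any live database lookup.

Coordinates are 1-based inclusive internally; BED input/output is converted
at the boundary.  Chromosome names are normalized through a small alias rule
("chr14", "SSC14" and "14" all compare equal) plus an optional user map.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .fst import Region

logger = logging.getLogger(__name__)

_PREFIX_RE = re.compile(r"^(chr|ssc)", re.IGNORECASE)


def normalize_chrom(chrom: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonical chromosome label: strip chr/SSC prefixes, then apply aliases."""
    s = _PREFIX_RE.sub("", str(chrom).strip())
    if aliases and s in aliases:
        s = aliases[s]
    return s


@dataclass
class AnnotationSet:
    """Named genomic intervals (genes or QTLs) with category labels.

    ``records``: DataFrame (name, chrom, start_bp, end_bp, category),
    1-based inclusive, names unique.  Overlap queries go through per-
    chromosome interval trees built lazily.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["name", "chrom", "start_bp", "end_bp", "category"]
        self.records = self.records[req].reset_index(drop=True)
        if (self.records["end_bp"] < self.records["start_bp"]).any():
            bad = self.records[self.records["end_bp"] < self.records["start_bp"]].iloc[0]
            raise ValueError(f"interval {bad['name']!r}: end < start")
        if self.records["name"].duplicated().any():
            dup = self.records.loc[self.records["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate annotation name {dup!r}")
        self.records["chrom"] = [normalize_chrom(c) for c in self.records["chrom"]]
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def _tree(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            self._trees = {}
            for c, sub in self.records.groupby("chrom"):
                # tree coordinates are half-open: [start, end + 1)
                self._trees[str(c)] = IntervalTree.from_tuples(
                    (int(row.start_bp), int(row.end_bp) + 1, idx)
                    for idx, row in sub.iterrows()
                )
        return self._trees.get(chrom)

    def query(self, chrom: str, start_bp: int, end_bp: int) -> pd.DataFrame:
        """Records overlapping [start_bp, end_bp] (1-based inclusive) by >= 1 bp."""
        chrom = normalize_chrom(chrom)
        tree = self._tree(chrom)
        if tree is None:
            return self.records.iloc[0:0]
        hits = sorted(iv.data for iv in tree.overlap(start_bp, end_bp + 1))
        return self.records.loc[hits]


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_annotations(
    path: str | Path,
    format: str = "bed",
    default_category: str = "gene",
) -> AnnotationSet:
    """Load an annotation file as an :class:`AnnotationSet`.

    ``bed``: chrom, start (0-based half-open), end, name[, category];
    ``gff3``: standard 9 columns, name from Name=/ID=, category = feature
    type; ``tsv``: the gene-table layout Symbol / Full Name / SSC /
    Location ("start..end")[, Category].
    """
    path = Path(path)
    if format == "bed":
        rows = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ValueError(f"{path} line {ln}: BED needs >= 3 columns")
            try:
                start0, end0 = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValueError(f"{path} line {ln}: non-integer coordinate") from e
            if end0 < start0:
                raise ValueError(f"{path} line {ln}: end < start")
            rows.append({
                "name": f[3] if len(f) > 3 else f"iv_{ln}",
                "chrom": f[0],
                "start_bp": start0 + 1,   # 0-based half-open -> 1-based inclusive
                "end_bp": end0,
                "category": f[4] if len(f) > 4 else default_category,
            })
        return AnnotationSet(pd.DataFrame(rows, columns=["name", "chrom", "start_bp", "end_bp", "category"]))
    if format == "gff3":
        rows = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path} line {ln}: GFF3 needs 9 tab-separated columns")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"feat_{ln}"
            start, end = int(f[3]), int(f[4])
            if end < start:
                raise ValueError(f"{path} line {ln}: end < start")
            rows.append({"name": name, "chrom": f[0], "start_bp": start,
                         "end_bp": end, "category": f[2]})
        return AnnotationSet(pd.DataFrame(rows, columns=["name", "chrom", "start_bp", "end_bp", "category"]))
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return gene_table_to_annotations(df, default_category=default_category)
    raise ValueError(f"unknown annotation format {format!r}")


def gene_table_to_annotations(df: pd.DataFrame, default_category: str = "gene") -> AnnotationSet:
    """Convert a Symbol / SSC / Location ("start..end") gene table."""
    rows = []
    for _, r in df.iterrows():
        loc = str(r["Location"])
        m = re.match(r"^\s*(\d+)\s*\.\.\s*(\d+)\s*$", loc)
        if not m:
            raise ValueError(f"unparseable Location {loc!r} for {r['Symbol']!r}")
        rows.append({
            "name": str(r["Symbol"]),
            "chrom": str(r["SSC"]),
            "start_bp": int(m.group(1)),
            "end_bp": int(m.group(2)),
            "category": str(r["Category"]) if "Category" in df.columns else default_category,
        })
    return AnnotationSet(pd.DataFrame(rows, columns=["name", "chrom", "start_bp", "end_bp", "category"]))


# ---------------------------------------------------------------------------
# overlap and set operations
# ---------------------------------------------------------------------------

def overlap_regions(
    regions: Sequence[Region],
    ann: AnnotationSet,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """All (region, annotation) pairs intersecting by >= 1 bp.

    Returns a DataFrame (region_index, region_chrom, region_start,
    region_end, name, category, overlap_bp).  Chromosomes present in the
    regions but absent from the annotation produce a warning and no hits.
    """
    ann_chroms = set(ann.records["chrom"])
    rows = []
    missing_chroms = set()
    for ri, reg in enumerate(regions):
        chrom = normalize_chrom(reg.chrom, aliases)
        if chrom not in ann_chroms:
            missing_chroms.add(chrom)
            continue
        hits = ann.query(chrom, reg.start_bp, reg.end_bp)
        for _, h in hits.iterrows():
            ov = min(reg.end_bp, h["end_bp"]) - max(reg.start_bp, h["start_bp"]) + 1
            rows.append({
                "region_index": ri, "region_chrom": chrom,
                "region_start": reg.start_bp, "region_end": reg.end_bp,
                "name": h["name"], "category": h["category"], "overlap_bp": int(ov),
            })
    if missing_chroms:
        logger.warning("region chromosomes absent from annotation: %s",
                       sorted(missing_chroms))
    return pd.DataFrame(
        rows,
        columns=["region_index", "region_chrom", "region_start", "region_end",
                 "name", "category", "overlap_bp"],
    )


def shared_genes(set_a: Iterable[str], set_b: Iterable[str]) -> list[str]:
    """Sorted intersection of two gene-symbol lists (deduplicated)."""
    return sorted(set(set_a) & set(set_b))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment_test(
    hit_genes: Iterable[str],
    category_map: pd.DataFrame | Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation per category, with BH FDR.

    ``category_map`` is either a DataFrame (gene, category) or a mapping
    gene -> categories.  For each category the hypergeometric upper tail
    P(X >= k) is computed on the 2x2 table of hit/background membership;
    q-values are Benjamini-Hochberg across the tested categories.
    """
    background = sorted(set(background))
    N = len(background)
    if N == 0:
        raise ValueError("empty background gene set")
    hits = set(hit_genes)
    stray = hits - set(background)
    if stray:
        raise ValueError(f"hit genes not in background: {sorted(stray)}")
    if isinstance(category_map, pd.DataFrame):
        pairs = list(zip(category_map["gene"].astype(str), category_map["category"].astype(str)))
    else:
        pairs = [(str(g), str(c)) for g, cats in category_map.items() for c in cats]
    bg = set(background)
    by_cat: dict[str, set[str]] = {}
    for gene, cat in pairs:
        if gene in bg:
            by_cat.setdefault(cat, set()).add(gene)
    n = len(hits)
    rows = []
    for cat in sorted(by_cat):
        members = by_cat[cat]
        K = len(members)
        k = len(hits & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": cat, "k_hit": k, "n_hit_genes": n,
                     "K_category": K, "N_background": N, "p_value": min(p, 1.0)})
    result = pd.DataFrame(
        rows, columns=["category", "k_hit", "n_hit_genes", "K_category",
                       "N_background", "p_value"]
    )
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# packaged gene-table fixtures
# ---------------------------------------------------------------------------

def load_gene_table(breed: str) -> pd.DataFrame:
    """Packaged candidate-gene table for ``landrace`` or ``duroc``."""
    from importlib.resources import files

    name = {"landrace": "landrace_genes.tsv", "duroc": "duroc_genes.tsv"}.get(breed.lower())
    if name is None:
        raise ValueError(f"unknown breed table {breed!r}")
    with (files("driftscan.data") / name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)
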