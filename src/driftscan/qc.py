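"""Genotype quality control: missingness, HWE exact test, relatedness, LD.

The filter chain mirrors standard SNP-array practice for selection-signature
scans: per-variant call-rate filter, exact Hardy-Weinberg test, greedy
removal of highly related samples based on the genomic relationship matrix
(GRM), and sliding-window LD pruning.  Every step is implemented from first
principles on the dosage matrix; each returns the filtered matrix plus the
identifiers it removed, and :func:`run_qc` composes them in the fixed order
missingness -> HWE -> relatedness -> monomorphic -> LD with full bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcConfig:
    """Thresholds for the QC chain.

    Defaults are the conventional array-QC settings for this kind of scan:
    drop variants with >2% missing calls, drop variants with HWE exact
    p < 1e-7 (pooled sample), greedily prune samples until no GRM
    off-diagonal exceeds 0.75, and LD-prune with a 50-SNP window sliding
    by 5 SNPs at r^2 > 0.2.
    """

    max_missing_rate: float = 0.02
    hwe_alpha: float = 1e-7
    rel_cutoff: float = 0.75
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_rate <= 1:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0 <= self.hwe_alpha <= 1:
            raise ValueError("hwe_alpha must be in [0, 1]")
        if self.ld_step_snps < 1 or self.ld_window_snps <= self.ld_step_snps:
            raise ValueError("require ld_window_snps > ld_step_snps >= 1")
        if not 0 <= self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must be in [0, 1]")


@dataclass
class QcReport:
    """Bookkeeping of a QC run; counts reconcile exactly per step."""

    n_samples_in: int
    n_variants_in: int
    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, kind: str, removed: list[str]) -> None:
        self.steps.append({"step": step, "kind": kind, "n_removed": len(removed),
                           "removed": list(removed)})

    @property
    def n_variants_out(self) -> int:
        return self.n_variants_in - sum(
            s["n_removed"] for s in self.steps if s["kind"] == "variant"
        )

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - sum(
            s["n_removed"] for s in self.steps if s["kind"] == "sample"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": s["step"], "kind": s["kind"], "n_removed": s["n_removed"]}
             for s in self.steps]
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# samples: {self.n_samples_in} -> {self.n_samples_out}\n")
            fh.write(f"# variants: {self.n_variants_in} -> {self.n_variants_out}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def missingness_filter(
    g: GenotypeMatrix, max_missing_rate: float = 0.02
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants whose missing-call fraction strictly exceeds the threshold."""
    frac = g.missing_fraction()
    drop = frac > max_missing_rate
    removed = g.variants.loc[drop, "id"].tolist()
    logger.info("missingness filter: removed %d/%d variants", len(removed), g.n_variants)
    return g.take_variants(np.flatnonzero(~drop)), removed


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all attainable heterozygote counts whose conditional probability does
    not exceed that of the observed count (no mid-p correction).  The
    p-value lies in (0, 1]; a monomorphic site gives exactly 1.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    rare = min(2 * n_hom_a + n_het, 2 * n_hom_b + n_het)
    if rare == 0:
        return 1.0
    probs = _hwe_het_probs(n, rare)
    obs = probs.get(n_het)
    if obs is None:
        raise ValueError(f"heterozygote count {n_het} unattainable for these allele counts")
    p = sum(q for q in probs.values() if q <= obs * (1 + 1e-12))
    return min(1.0, p)


def _hwe_het_probs(n: int, rare: int) -> dict[int, float]:
    """Conditional P(het = h) for all attainable h given n diploids, ``rare`` minor alleles."""
    common = 2 * n - rare
    # attainable het counts share the parity of the minor-allele count; max is `rare`
    val = 1.0
    out = {rare: 1.0}
    for h in range(rare, 1, -2):
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        val *= h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        out[h - 2] = val
    total = sum(out.values())
    return {h: v / total for h, v in out.items()}


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant HWE exact p-values on all (pooled) samples."""
    d = g.dosage
    n_hom_a = (d == 2).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    n_hom_b = (d == 0).sum(axis=0)
    out = np.empty(g.n_variants)
    for j in range(g.n_variants):
        tot = n_hom_a[j] + n_het[j] + n_hom_b[j]
        out[j] = 1.0 if tot == 0 else hwe_exact_test(int(n_hom_a[j]), int(n_het[j]), int(n_hom_b[j]))
    return out


def hwe_filter(g: GenotypeMatrix, alpha: float = 1e-7) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants with HWE exact p-value below ``alpha`` (pooled samples)."""
    p = hwe_pvalues(g)
    drop = p < alpha
    removed = g.variants.loc[drop, "id"].tolist()
    logger.info("HWE filter (alpha=%g): removed %d/%d variants", alpha, len(removed), g.n_variants)
    return g.take_variants(np.flatnonzero(~drop)), removed


# ---------------------------------------------------------------------------
# GRM and relatedness pruning
# ---------------------------------------------------------------------------

def grm(g: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method-1 form.

    G = Z Z^T / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix centered
    at 2 p_j; allele frequencies are estimated from the data and missing
    dosages are mean-imputed per variant.  The result is symmetric PSD with
    diagonal approximately 1 + inbreeding.
    """
    if g.n_samples < 2:
        raise ValueError("GRM requires at least two samples")
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all variants monomorphic: GRM scale is zero")
    z = d - 2.0 * p
    return (z @ z.T) / denom


def relatedness_prune(
    g: GenotypeMatrix, cutoff: float = 0.75
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedily drop samples until no GRM off-diagonal entry exceeds ``cutoff``.

    At each step the sample participating in the most over-cutoff pairs is
    removed (ties broken by higher missingness, then lexicographically
    smaller sample id).  The GRM is computed once on the input matrix.
    """
    G = grm(g)
    n = g.n_samples
    over = (G > cutoff)
    np.fill_diagonal(over, False)
    active = np.ones(n, dtype=bool)
    miss = g.sample_missing_fraction()
    ids = g.samples["sample_id"].to_numpy()
    removed: list[str] = []
    while True:
        counts = (over & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        if counts.max(initial=0) == 0:
            break
        cand = np.flatnonzero(counts == counts.max())
        cand = sorted(cand, key=lambda i: (-miss[i], ids[i]))
        victim = cand[0]
        active[victim] = False
        removed.append(ids[victim])
    if removed:
        logger.info("relatedness prune (cutoff=%g): removed %d samples", cutoff, len(removed))
    return g.take_samples(np.flatnonzero(active)), removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _standardized(dosage: np.ndarray) -> np.ndarray:
    """Mean-imputed, variance-standardized dosage columns (zero columns for monomorphic)."""
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    d -= mean
    sd = d.std(axis=0)
    sd[sd == 0] = np.inf
    return d / sd


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> tuple[GenotypeMatrix, list[str]]:
    """Sliding-window LD pruning on squared Pearson correlation of dosages.

    Within each window of ``window_snps`` variants, advanced by
    ``step_snps``, any retained pair with r^2 > ``r2_max`` triggers removal
    of the later-positioned variant (tie: lexicographically larger id)
    until the window holds no violating pair.  Windows never span
    chromosomes; r^2 uses mean-imputed, standardized dosages.
    """
    if step_snps < 1 or window_snps <= step_snps:
        raise ValueError("require window_snps > step_snps >= 1")
    z = _standardized(g.dosage)
    n = g.n_samples
    keep = np.ones(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    ids = g.variants["id"].to_numpy()
    pos = g.variants["pos_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = idx.size
        for start in range(0, max(m - 1, 1), step_snps):
            win = idx[start : start + window_snps]
            win = win[keep[win]]
            if win.size < 2:
                continue
            zc = z[:, win]
            r = (zc.T @ zc) / n
            r2 = r**2
            np.fill_diagonal(r2, 0.0)
            while True:
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                # drop the later-positioned member; equal positions fall back to id order
                victim = max(i, j, key=lambda t: (pos[win[t]], ids[win[t]]))
                keep[win[victim]] = False
                r2[victim, :] = 0.0
                r2[:, victim] = 0.0
    removed = [ids[j] for j in np.flatnonzero(~keep)]
    logger.info("LD prune (%d %d %g): removed %d/%d variants",
                window_snps, step_snps, r2_max, len(removed), g.n_variants)
    return g.take_variants(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# monomorphic removal and the composed chain
# ---------------------------------------------------------------------------

def monomorphic_filter(g: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants with no observed polymorphism (FST undefined there)."""
    d = g.dosage
    obs = d != MISSING
    cnt = np.where(obs, d, 0).sum(axis=0)
    tot = 2 * obs.sum(axis=0)
    poly = (cnt > 0) & (cnt < tot)
    removed = g.variants.loc[~poly, "id"].tolist()
    if removed:
        logger.info("monomorphic filter: removed %d variants", len(removed))
    return g.take_variants(np.flatnonzero(poly)), removed


def run_qc(g: GenotypeMatrix, cfg: QcConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Composed QC chain: missingness -> HWE -> relatedness -> monomorphic -> LD."""
    cfg = cfg or QcConfig()
    report = QcReport(n_samples_in=g.n_samples, n_variants_in=g.n_variants)
    g, rem = missingness_filter(g, cfg.max_missing_rate)
    report.add("missingness", "variant", rem)
    g, rem = hwe_filter(g, cfg.hwe_alpha)
    report.add("hwe", "variant", rem)
    g, rem = relatedness_prune(g, cfg.rel_cutoff)
    report.add("relatedness", "sample", rem)
    g, rem = monomorphic_filter(g)
    report.add("monomorphic", "variant", rem)
    g, rem = ld_prune(g, cfg.ld_window_snps, cfg.ld_step_snps, cfg.ld_r2_max)
    report.add("ld_prune", "variant", rem)
    logger.info("QC: %d/%d variants, %d/%d samples retained",
                report.n_variants_out, report.n_variants_in,
                report.n_samples_out, report.n_samples_in)
    return g, report
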