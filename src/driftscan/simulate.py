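"""Synthetic two-group genotype data under a pure-drift frequency model.

The generator realizes exactly the model the scan assumes: per SNP an
ancestral frequency pi ~ Uniform(maf range), per group a descendant
frequency drawn Beta(pi (1-c)/c, (1-pi)(1-c)/c) — the Balding-Nichols
parameterization with mean pi and variance c pi(1-pi) — then diploid
genotypes Binomial(2, p) per sample.  Planted windows add an extra
frequency shift of +/- delta/2 with opposite signs in the two groups,
giving a directly controllable effect size; SNPs are independent given
their frequencies (no LD), which is the main idealization relative to
real chip data.

Genotype draws are coupled through per-cell uniforms so that, for a fixed
seed, increasing delta moves every planted genotype monotonically — useful
for power curves with common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .annotate import AnnotationSet
from .fst import Region
from .genotypes import GROUP_CASE, GROUP_CONTROL, MISSING, GenotypeMatrix


@dataclass
class PlantedWindow:
    """A run of consecutive SNPs with extra between-group differentiation.

    ``chrom`` is the 1-based simulated chromosome number; ``start_snp`` the
    0-based index of the first SNP within that chromosome.  Either
    ``delta`` (frequency shift, the default mechanism) or ``c_planted``
    (locally elevated drift) must be set.
    """

    chrom: int
    start_snp: int
    n_snps: int
    delta: float = 0.0
    c_planted: float | None = None


@dataclass
class SimConfig:
    """Study conditions of one simulated breed dataset.

    Defaults echo the real cohorts this emulates: ~30-40 pigs per
    phenotype group, markers at ~25 kb mean spacing, and weak background
    drift between the two groups (c = 0.01, i.e. FST-scale differentiation
    of about 1% genome-wide).
    """

    n_samples_per_group: int = 40
    n_snps: int = 5000
    n_chromosomes: int = 5
    spacing_bp: float = 25_000.0
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    background_c: float = 0.01
    planted_windows: list[PlantedWindow] = dc_field(default_factory=list)
    missing_rate: float = 0.01
    seed: int | None = None
    breed: str = "SIM"

    def __post_init__(self) -> None:
        if not 0 <= self.background_c < 1:
            raise ValueError("background_c must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.seed is None:
            raise ValueError("seed is mandatory: every simulation must be reproducible")


@dataclass
class SimTruth:
    """Planted intervals plus the latent per-group frequencies of a run."""

    windows: pd.DataFrame  # chrom, start_bp, end_bp, delta
    freq_group1: np.ndarray
    freq_group2: np.ndarray


@dataclass
class RecoveryMetrics:
    sensitivity: float
    n_false_regions: int
    n_planted: int
    n_recovered: int


def _chrom_sizes(n_snps: int, n_chromosomes: int) -> list[int]:
    base, extra = divmod(n_snps, n_chromosomes)
    return [base + (1 if i < extra else 0) for i in range(n_chromosomes)]


def _draw_group_freqs(rng: np.random.Generator, pi: np.ndarray, c: float) -> np.ndarray:
    if c == 0:
        return pi.copy()
    a = pi * (1 - c) / c
    b = (1 - pi) * (1 - c) / c
    return rng.beta(a, b)


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth, AnnotationSet]:
    """Generate one breed dataset, its ground truth, and a toy gene set.

    The gene set places one named gene inside each planted window and two
    decoy genes per chromosome elsewhere, so the annotation stage is
    exercised end to end on synthetic runs.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps
    sizes = _chrom_sizes(m, cfg.n_chromosomes)

    # marker map: cumulative Exponential(spacing) positions per chromosome
    chroms: list[str] = []
    pos = np.empty(m, dtype=np.int64)
    offset = 0
    chrom_bounds: dict[int, tuple[int, int]] = {}
    for ci, size in enumerate(sizes, start=1):
        gaps = np.maximum(1, np.round(rng.exponential(cfg.spacing_bp, size=size))).astype(np.int64)
        pos[offset : offset + size] = np.cumsum(gaps)
        chroms += [str(ci)] * size
        chrom_bounds[ci] = (offset, offset + size)
        offset += size

    lo, hi = cfg.ancestral_maf_range
    pi = rng.uniform(lo, hi, size=m)
    p1 = _draw_group_freqs(rng, pi, cfg.background_c)
    p2 = _draw_group_freqs(rng, pi, cfg.background_c)

    truth_rows = []
    for w in cfg.planted_windows:
        if w.chrom not in chrom_bounds:
            raise ValueError(f"planted window on chromosome {w.chrom} outside the map")
        c0, c1 = chrom_bounds[w.chrom]
        j0 = c0 + w.start_snp
        j1 = j0 + w.n_snps
        if w.start_snp < 0 or j1 > c1:
            raise ValueError(
                f"planted window [{w.start_snp}, {w.start_snp + w.n_snps}) exceeds "
                f"chromosome {w.chrom} ({c1 - c0} SNPs)"
            )
        sl = slice(j0, j1)
        if w.c_planted is not None:
            p1[sl] = _draw_group_freqs(rng, pi[sl], w.c_planted)
            p2[sl] = _draw_group_freqs(rng, pi[sl], w.c_planted)
        p1[sl] = np.clip(p1[sl] + w.delta / 2.0, 0.01, 0.99)
        p2[sl] = np.clip(p2[sl] - w.delta / 2.0, 0.01, 0.99)
        truth_rows.append({"chrom": str(w.chrom), "start_bp": int(pos[j0]),
                           "end_bp": int(pos[j1 - 1]), "delta": float(w.delta)})

    n = cfg.n_samples_per_group
    # Binomial(2, p) via two per-cell uniforms: monotone in p under a fixed seed
    u = rng.random(size=(2 * n, m, 2))
    freqs = np.vstack([np.tile(p1, (n, 1)), np.tile(p2, (n, 1))])
    dosage = ((u[:, :, 0] < freqs).astype(np.int8) + (u[:, :, 1] < freqs).astype(np.int8))
    if cfg.missing_rate > 0:
        dosage[rng.random(size=dosage.shape) < cfg.missing_rate] = MISSING

    samples = pd.DataFrame({
        "sample_id": [f"{cfg.breed}_{g}_{i:03d}" for g in ("I", "II") for i in range(n)],
        "breed": cfg.breed,
        "group": [GROUP_CASE] * n + [GROUP_CONTROL] * n,
    })
    variants = pd.DataFrame({
        "id": [f"snp{j:06d}" for j in range(m)],
        "chrom": chroms,
        "pos_bp": pos,
        "allele_a": "A",
        "allele_b": "B",
    })
    g = GenotypeMatrix(dosage, samples, variants)

    truth = SimTruth(
        windows=pd.DataFrame(truth_rows, columns=["chrom", "start_bp", "end_bp", "delta"]),
        freq_group1=p1,
        freq_group2=p2,
    )
    genes = _toy_genes(truth, chroms, pos, chrom_bounds, rng)
    return g, truth, genes


def _toy_genes(
    truth: SimTruth,
    chroms: list[str],
    pos: np.ndarray,
    chrom_bounds: dict[int, tuple[int, int]],
    rng: np.random.Generator,
) -> AnnotationSet:
    """One gene inside each planted window, two decoys per chromosome."""
    rows = []
    for k, w in truth.windows.iterrows():
        rows.append({"name": f"PLANT{k + 1}", "chrom": w["chrom"],
                     "start_bp": int(w["start_bp"]), "end_bp": int(w["end_bp"]),
                     "category": "planted"})
    for ci, (c0, c1) in chrom_bounds.items():
        span = int(pos[c1 - 1])
        for d in range(2):
            start = int(rng.integers(1, max(span - 50_000, 2)))
            rows.append({"name": f"DECOY{ci}_{d + 1}", "chrom": str(ci),
                         "start_bp": start, "end_bp": start + 50_000,
                         "category": "background"})
    return AnnotationSet(pd.DataFrame(rows, columns=["name", "chrom", "start_bp", "end_bp", "category"]))


def simulate_two_breeds(
    cfg: SimConfig, c_breed: float = 0.1, breeds: tuple[str, str] = ("LR", "DU")
) -> GenotypeMatrix:
    """Two breeds on a shared marker map, with breed-level drift.

    Breed frequencies drift from a common ancestral frequency with
    ``c_breed`` (strong; produces the well-separated breed clusters a
    structure plot should show), and within each breed the two phenotype
    groups drift with ``cfg.background_c`` (so case/control labels show no
    stratification).  No windows are planted; this feeds the structure
    diagnostic, not the scan.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps
    sizes = _chrom_sizes(m, cfg.n_chromosomes)
    chroms: list[str] = []
    pos = np.empty(m, dtype=np.int64)
    offset = 0
    for ci, size in enumerate(sizes, start=1):
        gaps = np.maximum(1, np.round(rng.exponential(cfg.spacing_bp, size=size))).astype(np.int64)
        pos[offset : offset + size] = np.cumsum(gaps)
        chroms += [str(ci)] * size
        offset += size
    lo, hi = cfg.ancestral_maf_range
    pi = rng.uniform(lo, hi, size=m)
    n = cfg.n_samples_per_group
    dosages = []
    sample_frames = []
    for breed in breeds:
        q = np.clip(_draw_group_freqs(rng, pi, c_breed), 0.01, 0.99)
        p1 = _draw_group_freqs(rng, q, cfg.background_c)
        p2 = _draw_group_freqs(rng, q, cfg.background_c)
        u = rng.random(size=(2 * n, m, 2))
        freqs = np.vstack([np.tile(p1, (n, 1)), np.tile(p2, (n, 1))])
        d = (u[:, :, 0] < freqs).astype(np.int8) + (u[:, :, 1] < freqs).astype(np.int8)
        if cfg.missing_rate > 0:
            d[rng.random(size=d.shape) < cfg.missing_rate] = MISSING
        dosages.append(d)
        sample_frames.append(pd.DataFrame({
            "sample_id": [f"{breed}_{g}_{i:03d}" for g in ("I", "II") for i in range(n)],
            "breed": breed,
            "group": [GROUP_CASE] * n + [GROUP_CONTROL] * n,
        }))
    variants = pd.DataFrame({
        "id": [f"snp{j:06d}" for j in range(m)],
        "chrom": chroms,
        "pos_bp": pos,
        "allele_a": "A",
        "allele_b": "B",
    })
    return GenotypeMatrix(
        np.vstack(dosages), pd.concat(sample_frames, ignore_index=True), variants
    )


def evaluate_recovery(regions: list[Region], truth: SimTruth) -> RecoveryMetrics:
    """Score a region call set against the planted truth.

    A planted window counts as recovered iff some region overlaps it by at
    least 1 bp; a region overlapping no planted window is a false region.
    """
    windows = truth.windows
    recovered = np.zeros(len(windows), dtype=bool)
    n_false = 0
    for reg in regions:
        hit_any = False
        for k, w in windows.iterrows():
            if str(reg.chrom) == str(w["chrom"]) and not (
                reg.end_bp < w["start_bp"] or reg.start_bp > w["end_bp"]
            ):
                recovered[k] = True
                hit_any = True
        if not hit_any:
            n_false += 1
    n_planted = len(windows)
    sens = float(recovered.sum() / n_planted) if n_planted else float("nan")
    return RecoveryMetrics(
        sensitivity=sens,
        n_false_regions=n_false,
        n_planted=n_planted,
        n_recovered=int(recovered.sum()),
    )
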