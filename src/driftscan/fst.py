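"""Per-SNP FST between two groups, window smoothing, and outlier regions.

The scan compares the two phenotype groups of one breed dataset.  Two
estimators of per-SNP differentiation are available:

``weir_cockerham``
    The two-population variance-components point estimate theta-hat from
    observed diploid genotype counts, with the heterozygosity correction
    terms (a / (a + b + c) in the usual component notation).

``pure_drift_moment``
    A moment estimate of the drift parameter c under the pure-drift model
    in which group allele frequencies scatter around the pooled frequency
    with variance c * p(1-p): the sample variance of the two group
    frequencies, bias-corrected for binomial sampling of 2n alleles per
    group, divided by p-bar(1 - p-bar).

Raw values are clamped to [0, 1] (configurable), smoothed over a centered
window of SNPs, thresholded at a genome-wide empirical quantile, and the
flagged SNPs merged into regions for annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GROUP_CASE, GROUP_CONTROL, MISSING, GenotypeMatrix, chrom_sort_key

logger = logging.getLogger(__name__)


@dataclass
class FstConfig:
    """Scan parameters.

    ``smooth_window_snps`` must be odd; ``outlier_quantile`` is the
    genome-wide empirical quantile (linear interpolation) above which a
    smoothed value is flagged, strictly.  ``region_merge_gap_bp`` is the
    largest gap between consecutive flagged SNPs kept in one region.
    """

    estimator: str = "weir_cockerham"
    smooth_window_snps: int = 9
    smooth_kernel: str = "uniform_mean"
    outlier_quantile: float = 0.99
    region_merge_gap_bp: int = 1_000_000
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.estimator not in ("weir_cockerham", "pure_drift_moment"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.smooth_kernel not in ("uniform_mean", "triangular"):
            raise ValueError(f"unknown kernel {self.smooth_kernel!r}")
        if self.smooth_window_snps < 1 or self.smooth_window_snps % 2 == 0:
            raise ValueError("smooth_window_snps must be odd and >= 1")
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier_quantile must be in (0, 1)")
        if self.region_merge_gap_bp < 0:
            raise ValueError("region_merge_gap_bp must be >= 0")


@dataclass
class Region:
    """A merged run of flagged SNPs; 1-based inclusive bounds."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_fst_smooth: float
    member_ids: list[str] = field(default_factory=list)


def _group_stats(g: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    """Per-variant (n, p, het-frequency) for groups I and II."""
    groups = g.samples["group"].to_numpy()
    out = []
    for label in (GROUP_CASE, GROUP_CONTROL):
        d = g.dosage[groups == label, :]
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, d, 0).sum(axis=0) / (2.0 * n)
            h = np.where(obs & (d == 1), 1, 0).sum(axis=0) / n
        out += [n, p, h]
    return tuple(out)


def weir_cockerham_fst(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> np.ndarray:
    """Two-population variance-components theta-hat from per-group summaries.

    ``n``: diploid sample counts; ``p``: A1 allele frequencies; ``h``:
    observed heterozygote frequencies.  Vectorized over variants; returns
    NaN where the denominator vanishes (monomorphic overall).
    """
    r = 2.0
    nbar = (n1 + n2) / r
    S = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (S - (n1**2 + n2**2) / S) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta


def pure_drift_moment_fst(
    n1: np.ndarray, p1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray,
) -> np.ndarray:
    """Moment estimate of the drift parameter c from two group frequencies.

    c-tilde = (s^2 - v-bar) / (p-bar (1 - p-bar)) where s^2 is the
    two-group sample variance of frequencies (unweighted), and v-bar the
    mean estimated binomial sampling variance p_i(1-p_i)/(2 n_i - 1) of
    each group frequency.  c is a proportion-of-variance parameter, so the
    estimate is truncated at its upper parameter bound 1 (a fixed
    difference yields exactly 1); finite-sample negative values are kept
    for audit.  Returns NaN where p-bar(1-p-bar) = 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (p1 + p2) / 2.0
        s2 = (p1 - p2) ** 2 / 2.0
        v1 = p1 * (1 - p1) / (2 * n1 - 1)
        v2 = p2 * (1 - p2) / (2 * n2 - 1)
        denom = pbar * (1 - pbar)
        c = np.where(denom > 0, (s2 - (v1 + v2) / 2.0) / denom, np.nan)
    return np.minimum(c, 1.0)


def estimate_drift_c(g: GenotypeMatrix) -> float:
    """Genome-wide pooled moment estimate of the drift parameter c.

    Ratio of summed moments across variants: sum_j (s2_j - vbar_j) /
    sum_j pbar_j (1 - pbar_j), with the same per-variant components as
    :func:`pure_drift_moment_fst`.  Unlike the per-variant estimate (a
    1-degree-of-freedom quantity with a strongly right-skewed
    distribution), the pooled ratio concentrates tightly around the true
    genome-wide c.
    """
    n1, p1, _, n2, p2, _ = _group_stats(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (p1 + p2) / 2.0
        s2 = (p1 - p2) ** 2 / 2.0
        vbar = (p1 * (1 - p1) / (2 * n1 - 1) + p2 * (1 - p2) / (2 * n2 - 1)) / 2.0
        denom = pbar * (1 - pbar)
    ok = (n1 >= 2) & (n2 >= 2) & (denom > 0) & np.isfinite(s2) & np.isfinite(vbar)
    if not ok.any():
        raise ValueError("no informative variants for drift estimation")
    return float((s2[ok] - vbar[ok]).sum() / denom[ok].sum())


def fst_per_snp(g: GenotypeMatrix, estimator: str = "weir_cockerham") -> pd.DataFrame:
    """Raw per-variant FST track (column ``fst_raw``; NaN where undefined).

    A variant needs >= 2 non-missing calls in each group and overall
    polymorphism; otherwise its FST is missing and it is excluded from
    smoothing.  Both groups must be present in ``g``.
    """
    groups = set(g.samples["group"].dropna())
    if not {GROUP_CASE, GROUP_CONTROL} <= groups:
        raise ValueError(f"both groups I and II required, found {sorted(groups)}")
    n1, p1, h1, n2, p2, h2 = _group_stats(g)
    if estimator == "weir_cockerham":
        raw = weir_cockerham_fst(n1, p1, h1, n2, p2, h2)
    elif estimator == "pure_drift_moment":
        raw = pure_drift_moment_fst(n1, p1, n2, p2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    # preconditions: >=2 called samples per group, polymorphic overall
    tot = 2 * n1 * p1 + 2 * n2 * p2
    alleles = 2 * (n1 + n2)
    ok = (n1 >= 2) & (n2 >= 2) & (tot > 0) & (tot < alleles)
    raw = np.where(ok, raw, np.nan)
    track = g.variants[["id", "chrom", "pos_bp"]].copy()
    track["fst_raw"] = raw
    return track


def smooth_track(
    track: pd.DataFrame,
    window_snps: int = 9,
    kernel: str = "uniform_mean",
    clamp_negative: bool = True,
) -> pd.DataFrame:
    """Fill ``fst_smooth``: kernel-weighted window mean of raw FST per SNP.

    Windows are centered, counted in SNPs, truncated at chromosome ends
    (weights renormalized over the shrunken window); missing raw values are
    excluded with renormalization.  With ``clamp_negative`` the raw values
    are clamped into [0, 1] before smoothing; the unclamped raw column is
    kept for audit.
    """
    if window_snps < 1 or window_snps % 2 == 0:
        raise ValueError("window_snps must be odd and >= 1")
    if kernel == "uniform_mean":
        w = np.ones(window_snps)
    elif kernel == "triangular":
        half = window_snps // 2
        w = np.concatenate([np.arange(1, half + 2), np.arange(half, 0, -1)]).astype(float)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    vals = track["fst_raw"].to_numpy(dtype=float)
    if clamp_negative:
        vals = np.clip(vals, 0.0, 1.0)
    valid = ~np.isnan(vals)
    filled = np.where(valid, vals, 0.0)
    out = np.full(len(track), np.nan)
    chroms = track["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < window_snps:
            # window exceeds chromosome: chromosome-wide mean fallback
            logger.info("chromosome %s has %d < %d SNPs: chromosome-wide mean",
                        chrom, idx.size, window_snps)
            v = valid[idx]
            out[idx] = filled[idx][v].mean() if v.any() else np.nan
            continue
        num = np.convolve(filled[idx] * 1.0, w, mode="same")
        den = np.convolve(valid[idx] * 1.0, w, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out[idx] = np.where(den > 0, num / den, np.nan)
    res = track.copy()
    res["fst_smooth"] = out
    return res


def call_outliers(track: pd.DataFrame, quantile: float = 0.99) -> pd.DataFrame:
    """Flag SNPs strictly above the genome-wide empirical quantile.

    The threshold is the linear-interpolation empirical quantile of all
    smoothed values in the dataset; ``is_outlier`` is strict, so a constant
    track flags nothing.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    sm = track["fst_smooth"].to_numpy(dtype=float)
    if np.all(np.isnan(sm)):
        raise ValueError("no smoothed values present")
    threshold = float(np.nanquantile(sm, quantile))
    res = track.copy()
    res["is_outlier"] = sm > threshold
    res.attrs["outlier_threshold"] = threshold
    return res


def merge_regions(track: pd.DataFrame, merge_gap_bp: int = 1_000_000) -> list[Region]:
    """Merge consecutive flagged SNPs within ``merge_gap_bp`` into regions."""
    flagged = track[track["is_outlier"]]
    regions: list[Region] = []
    for chrom in sorted(pd.unique(flagged["chrom"]), key=chrom_sort_key):
        sub = flagged[flagged["chrom"] == chrom].sort_values("pos_bp", kind="stable")
        pos = sub["pos_bp"].to_numpy()
        ids = sub["id"].to_numpy()
        sm = sub["fst_smooth"].to_numpy()
        start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or pos[i] - pos[i - 1] > merge_gap_bp:
                regions.append(
                    Region(
                        chrom=str(chrom),
                        start_bp=int(pos[start]),
                        end_bp=int(pos[i - 1]),
                        n_snps=i - start,
                        peak_fst_smooth=float(np.nanmax(sm[start:i])),
                        member_ids=list(ids[start:i]),
                    )
                )
                start = i
    return regions


def scan(g: GenotypeMatrix, cfg: FstConfig | None = None) -> tuple[pd.DataFrame, list[Region]]:
    """Full scan: raw FST -> smoothing -> quantile outliers -> merged regions."""
    cfg = cfg or FstConfig()
    track = fst_per_snp(g, cfg.estimator)
    track = smooth_track(track, cfg.smooth_window_snps, cfg.smooth_kernel, cfg.clamp_negative)
    track = call_outliers(track, cfg.outlier_quantile)
    regions = merge_regions(track, cfg.region_merge_gap_bp)
    logger.info("scan: %d/%d SNPs flagged (threshold %.5g), %d regions",
                int(track["is_outlier"].sum()), len(track),
                track.attrs["outlier_threshold"], len(regions))
    return track, regions


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------

def track_to_tsv(track: pd.DataFrame, path, cfg: FstConfig | None = None) -> None:
    """FST track as TSV with a commented header (dosage counts allele_a copies)."""
    with open(path, "w") as fh:
        fh.write("# driftscan FST track; fst_raw is unclamped; dosage counts allele_a copies\n")
        if cfg is not None:
            fh.write(f"# estimator={cfg.estimator} window={cfg.smooth_window_snps} "
                     f"kernel={cfg.smooth_kernel} quantile={cfg.outlier_quantile}\n")
        if "outlier_threshold" in track.attrs:
            fh.write(f"# outlier_threshold={track.attrs['outlier_threshold']!r}\n")
        track.to_csv(fh, sep="\t", index=False)


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
             "n_snps": r.n_snps, "peak_fst_smooth": r.peak_fst_smooth,
             "member_ids": ",".join(r.member_ids)}
            for r in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "peak_fst_smooth", "member_ids"],
    )


def regions_to_bed(regions: list[Region], path, merge_gap_bp: int | None = None) -> None:
    """Regions as BED (0-based half-open conversion happens here)."""
    with open(path, "w") as fh:
        if merge_gap_bp is not None:
            fh.write(f"# driftscan regions; merge_gap_bp={merge_gap_bp}; BED 0-based half-open\n")
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\tregion_{i}\t"
                     f"{r.peak_fst_smooth:.6g}\n")
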