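"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — exact rational enumeration, scalar
formula transcription, O(n*w) loops, all-pairs scans — and shares no code
with the implementation it validates.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact HWE p-value by full rational enumeration of attainable het counts.

    P(h | n, nA) is proportional to 2^h * n! / (hom_a! h! hom_b!); the
    p-value sums P over all h with P(h) <= P(observed), computed in exact
    integer/rational arithmetic before a single final float conversion.
    """
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # multinomial n! / (hom_r! h! hom_c!) via binomials, times 2^h
        weights[h] = comb(n, h) * comb(n - h, hom_r) * (1 << h)
    total = sum(weights.values())
    w_obs = weights[n_het]
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


def wc_theta_oracle(counts1: tuple[int, int, int], counts2: tuple[int, int, int]) -> float:
    """Two-population Weir-Cockerham theta-hat transcribed term by term.

    ``counts`` are (hom_A, het, hom_a) genotype counts for each group.
    """
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (2 * counts1[0] + counts1[1]) / (2 * n1)
    p2 = (2 * counts2[0] + counts2[1]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a / (a + b + c)


def naive_smooth(values, chroms, window: int, kernel: str = "uniform_mean"):
    """O(n * w) windowed mean with truncation, NaN exclusion, renormalization."""
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(chroms)
    half = window // 2
    if kernel == "uniform_mean":
        weight = lambda d: 1.0
    elif kernel == "triangular":
        weight = lambda d: float(half + 1 - abs(d))
    else:
        raise ValueError(kernel)
    out = np.full(values.shape, np.nan)
    for i in range(len(values)):
        num = den = 0.0
        for j in range(i - half, i + half + 1):
            if 0 <= j < len(values) and chroms[j] == chroms[i] and not np.isnan(values[j]):
                w = weight(j - i)
                num += w * values[j]
                den += w
        if den > 0:
            out[i] = num / den
    return out


def brute_force_overlaps(regions, records):
    """All-pairs 1-bp-or-more intersection between region tuples and record rows.

    ``regions``: iterable of (chrom, start, end); ``records``: DataFrame with
    name/chrom/start_bp/end_bp.  Returns a set of (region_index, name).
    """
    hits = set()
    for ri, (chrom, start, end) in enumerate(regions):
        for _, rec in records.iterrows():
            if str(rec["chrom"]) == str(chrom) and not (
                end < rec["start_bp"] or start > rec["end_bp"]
            ):
                hits.add((ri, rec["name"]))
    return hits


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct rational enumeration."""
    total = comb(N, n)
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return float(Fraction(num, total))
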