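"""Method-of-moments pooled F_ST from read counts with pool-size correction.

F_ST is expressed through identity-in-state probabilities: Q1, the
probability that two distinct gene copies drawn within a pool carry the same
allele, and Q2, the same probability for copies drawn from different pools;
F = (Q1 - Q2) / (1 - Q2).  Reads sample the pool's gene copies with
replacement, so the naive read-pair identity overestimates Q1 by the chance
1/n that two reads hit the same copy; :func:`identity_probs` removes that
bias, which is where the assumed pool size (in individuals, times ploidy)
enters.

The multilocus statistic is the ratio of sums sum(Q1bar - Q2) / sum(1 - Q2)
over valid SNPs — weighting informative SNPs more than the mean of per-SNP
ratios would.  Per-SNP values may legitimately be negative (unbiased moment
estimator); they are passed through unclipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_EPS_ONE_MINUS_Q2 = 1e-12


@dataclass
class FstEstimate:
    """Pairwise pooled F_ST summary for one sample pair."""

    pair: tuple[str, str]
    per_snp_fst: np.ndarray            # NaN where a SNP was excluded
    multilocus_fst: float              # ratio of sums
    mean_of_ratios: float              # reported for comparison only
    pool_sizes_used: tuple[int, int]   # gene copies
    n_snps_used: int

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "multilocus_fst": float(self.multilocus_fst),
            "mean_of_ratios": float(self.mean_of_ratios),
            "pool_sizes_used": [int(n) for n in self.pool_sizes_used],
            "n_snps_used": int(self.n_snps_used),
        }


def identity_probs(
    ref: np.ndarray, alt: np.ndarray, n_copies: int
) -> tuple[np.ndarray, np.ndarray]:
    """Within-pool identity Q1 corrected for reads re-sampling gene copies.

    Q1_reads = [alt(alt-1) + ref(ref-1)] / [r(r-1)] with r = ref + alt, then
    Q1 = (Q1_reads - 1/n) / (1 - 1/n) for a pool of ``n_copies`` gene copies.
    Returns ``(Q1, valid)``; entries with r < 2 are invalid (Q1 = NaN).
    Small negative Q1 values are a normal unbiasedness artifact and are kept.
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    r = ref + alt
    valid = r >= 2
    denom = np.where(valid, r * (r - 1.0), 1.0)
    q1_reads = (alt * (alt - 1.0) + ref * (ref - 1.0)) / denom
    q1 = (q1_reads - 1.0 / n_copies) / (1.0 - 1.0 / n_copies)
    q1 = np.where(valid, q1, np.nan)
    return q1, valid


def pairwise_fst(
    ref_a: np.ndarray,
    alt_a: np.ndarray,
    ref_b: np.ndarray,
    alt_b: np.ndarray,
    n_a: int,
    n_b: int,
    ploidy: int = 2,
    pair: tuple[str, str] = ("a", "b"),
) -> FstEstimate:
    """Pairwise pooled F_ST between two count columns on a shared SNP axis.

    ``n_a``/``n_b`` are pool sizes in individuals; gene copies are
    ``ploidy * n``.  Per SNP, Q1bar is the unweighted mean of the two pools'
    within-pool identities and Q2 = p_a p_b + (1-p_a)(1-p_b) with p the read
    frequency.  SNPs are excluded when either pool has depth < 2 or when
    1 - Q2 falls below 1e-12 (monomorphic in both pools).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("pool sizes must be >= 1 individual")
    copies_a, copies_b = ploidy * n_a, ploidy * n_b
    q1_a, valid_a = identity_probs(ref_a, alt_a, copies_a)
    q1_b, valid_b = identity_probs(ref_b, alt_b, copies_b)
    ref_a = np.asarray(ref_a, dtype=float)
    alt_a = np.asarray(alt_a, dtype=float)
    ref_b = np.asarray(ref_b, dtype=float)
    alt_b = np.asarray(alt_b, dtype=float)
    r_a = ref_a + alt_a
    r_b = ref_b + alt_b
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(r_a > 0, alt_a / np.where(r_a > 0, r_a, 1), np.nan)
        p_b = np.where(r_b > 0, alt_b / np.where(r_b > 0, r_b, 1), np.nan)
    q2 = p_a * p_b + (1.0 - p_a) * (1.0 - p_b)
    q1_bar = 0.5 * (q1_a + q1_b)
    one_minus_q2 = 1.0 - q2
    valid = valid_a & valid_b & (one_minus_q2 > _EPS_ONE_MINUS_Q2)
    if not valid.any():
        raise ValueError("no valid SNPs for F_ST (all monomorphic or underdepth)")
    num = q1_bar - q2
    per_snp = np.where(valid, num / np.where(valid, one_minus_q2, 1.0), np.nan)
    multilocus = float(num[valid].sum() / one_minus_q2[valid].sum())
    mean_of_ratios = float(np.nanmean(per_snp))
    return FstEstimate(
        pair=pair,
        per_snp_fst=per_snp,
        multilocus_fst=multilocus,
        mean_of_ratios=mean_of_ratios,
        pool_sizes_used=(copies_a, copies_b),
        n_snps_used=int(valid.sum()),
    )


def fst_between_samples(counts, sample_a: str, sample_b: str, n_a: int, n_b: int,
                        ploidy: int = 2) -> FstEstimate:
    """Convenience wrapper: pairwise F_ST between two samples of a count matrix."""
    ref_a, alt_a = counts.counts_for(sample_a)
    ref_b, alt_b = counts.counts_for(sample_b)
    return pairwise_fst(ref_a, alt_a, ref_b, alt_b, n_a, n_b, ploidy=ploidy,
                        pair=(sample_a, sample_b))


def pool_size_sweep(
    ref_a: np.ndarray,
    alt_a: np.ndarray,
    ref_b: np.ndarray,
    alt_b: np.ndarray,
    size_grid_a,
    size_grid_b,
    ploidy: int = 2,
) -> pd.DataFrame:
    """Multilocus F_ST over a grid of assumed pool sizes (individuals).

    The sensitivity sweep used when the census of a sampling day is only
    known as a range — e.g. 10,000-40,000 individuals on day 6 and 100-400
    settled individuals on day 43.  Returns a table sorted by (n_a, n_b).
    """
    size_grid_a = list(size_grid_a)
    size_grid_b = list(size_grid_b)
    if not size_grid_a or not size_grid_b:
        raise ValueError("pool size grids must be non-empty")
    rows = []
    for na in sorted(size_grid_a):
        for nb in sorted(size_grid_b):
            est = pairwise_fst(ref_a, alt_a, ref_b, alt_b, na, nb, ploidy=ploidy)
            rows.append(
                {
                    "n_a": na,
                    "n_b": nb,
                    "multilocus_fst": est.multilocus_fst,
                    "n_snps_used": est.n_snps_used,
                }
            )
    return pd.DataFrame(rows).sort_values(["n_a", "n_b"], ignore_index=True)


DAY6_POOL_GRID = (10_000, 20_000, 30_000, 40_000)
DAY43_POOL_GRID = (100, 200, 300, 400)


def mortality_from_census(start: int, end_counts) -> tuple[float, float]:
    """Percent mortality from a starting census and per-replicate end counts.

    ``100 * (1 - mean(end_counts) / start)``.  Returns (rounded-to-one-decimal,
    unrounded) so reporting can print e.g. 97.7 while retaining precision.
    """
    if start <= 0:
        raise ValueError("starting census must be positive")
    ends = np.asarray(list(end_counts), dtype=float)
    if (ends < 0).any():
        raise ValueError("end counts must be non-negative")
    if (ends > start).any():
        raise ValueError("end counts cannot exceed the starting census")
    pct = 100.0 * (1.0 - ends.mean() / start)
    return round(pct, 1), float(pct)
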