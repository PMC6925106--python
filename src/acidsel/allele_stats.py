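"""Per-SNP allele-frequency-shift tests and FDR q-values.

Two contingency-table tests drive the evolve-and-resequence scan:

* Fisher's exact test (FET) on a single 2x2 table of read counts, used where
  no replicate cultures exist (the day-6 full-population samples).
* The Cochran-Mantel-Haenszel (CMH) chi-square, which pools evidence for a
  consistent allele-frequency change across K replicate strata.

Tables are built directly from read depths — rows are (baseline sample,
focal sample), columns are (ref reads, alt reads) — with no normalisation or
effective-pool-size rescaling before testing.  P-values are converted to
q-values (Storey or Benjamini-Hochberg) and SNPs are called significant at a
strict ``q < threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import AlleleCountMatrix


# ---------------------------------------------------------------------------
# contrast specification


@dataclass
class ContrastSpec:
    """A named baseline-vs-focal comparison over pooled samples.

    For ``test="FET"`` exactly one baseline and one focal sample are allowed.
    For ``test="CMH"`` the K focal samples define K strata; ``baseline_samples``
    is either a single sample reused in every stratum (the day-0 pool paired
    with each replicate) or a list of K baselines pairing one-to-one.
    """

    name: str
    test: str  # "FET" | "CMH"
    baseline_samples: list[str] = field(default_factory=list)
    focal_samples: list[str] = field(default_factory=list)
    continuity_correction: bool = True

    def __post_init__(self) -> None:
        if self.test not in ("FET", "CMH"):
            raise ValueError(f"unknown test {self.test!r}; expected 'FET' or 'CMH'")
        if not self.baseline_samples or not self.focal_samples:
            raise ValueError("baseline_samples and focal_samples must be non-empty")
        if self.test == "FET":
            if len(self.baseline_samples) != 1 or len(self.focal_samples) != 1:
                raise ValueError("FET requires exactly one baseline and one focal sample")
        else:
            k = len(self.focal_samples)
            if len(self.baseline_samples) not in (1, k):
                raise ValueError(
                    "CMH baseline_samples must be a single sample or one per stratum"
                )

    def strata_pairs(self) -> list[tuple[str, str]]:
        if len(self.baseline_samples) == 1:
            return [(self.baseline_samples[0], f) for f in self.focal_samples]
        return list(zip(self.baseline_samples, self.focal_samples))


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(ref1: int, alt1: int, ref2: int, alt2: int) -> float:
    """Two-sided FET p-value for the table [[ref1, alt1], [ref2, alt2]].

    Two-sidedness follows the point-probability rule: every table with the
    same margins whose hypergeometric probability is at most that of the
    observed table contributes to p.  A monomorphic column pair (both columns
    zero on one side) carries no information and returns p = 1.
    """
    for v in (ref1, alt1, ref2, alt2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if ref1 + alt1 == 0 or ref2 + alt2 == 0:
        raise ValueError("both row totals must be positive")
    if (ref1 + ref2 == 0) or (alt1 + alt2 == 0):
        return 1.0  # monomorphic in both samples
    _, p = stats.fisher_exact([[ref1, alt1], [ref2, alt2]], alternative="two-sided")
    return float(min(p, 1.0))


def fet_scan(counts: AlleleCountMatrix, baseline: str, focal: str) -> np.ndarray:
    """Per-SNP two-sided FET p-values for one sample pair."""
    ref_b, alt_b = counts.counts_for(baseline)
    ref_f, alt_f = counts.counts_for(focal)
    p = np.ones(counts.n_snps)
    for i in range(counts.n_snps):
        p[i] = fisher_exact_2x2(int(ref_b[i]), int(alt_b[i]), int(ref_f[i]), int(alt_f[i]))
    return p


# ---------------------------------------------------------------------------
# CMH


def cmh_test(strata: list[np.ndarray], continuity_correction: bool = True) -> float:
    """CMH chi-square p-value across K stratified 2x2 tables.

    statistic = (|sum_k a_k - sum_k E_k| - c)^2 / sum_k V_k with
    E_k = row1_k * col1_k / T_k and
    V_k = row1_k * row2_k * col1_k * col2_k / (T_k^2 (T_k - 1));
    c = 0.5 with the continuity correction, else 0.  Strata with zero
    marginal variance contribute nothing; if all strata are degenerate the
    test is uninformative and p = 1.
    """
    tables = [np.asarray(t, dtype=float) for t in strata]
    if not tables:
        raise ValueError("at least one stratum required")
    a_sum = e_sum = v_sum = 0.0
    for t in tables:
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        total = t.sum()
        if total < 2:
            raise ValueError("each stratum total must be >= 2")
        r1, r2 = t[0].sum(), t[1].sum()
        c1, c2 = t[:, 0].sum(), t[:, 1].sum()
        v = r1 * r2 * c1 * c2 / (total**2 * (total - 1.0))
        if v <= 0:
            continue
        a_sum += t[0, 0]
        e_sum += r1 * c1 / total
        v_sum += v
    if v_sum <= 0:
        return 1.0
    c = 0.5 if continuity_correction else 0.0
    num = max(abs(a_sum - e_sum) - c, 0.0)
    statistic = num**2 / v_sum
    return float(stats.chi2.sf(statistic, df=1))


def cmh_scan(
    counts: AlleleCountMatrix,
    strata_pairs: list[tuple[str, str]],
    continuity_correction: bool = True,
) -> np.ndarray:
    """Vectorised per-SNP CMH p-values over replicate strata.

    Each stratum k is the 2x2 table
    [[ref_baseline_k, alt_baseline_k], [ref_focal_k, alt_focal_k]].
    """
    n = counts.n_snps
    a_sum = np.zeros(n)
    e_sum = np.zeros(n)
    v_sum = np.zeros(n)
    for baseline, focal in strata_pairs:
        ref_b, alt_b = (x.astype(float) for x in counts.counts_for(baseline))
        ref_f, alt_f = (x.astype(float) for x in counts.counts_for(focal))
        r1 = ref_b + alt_b
        r2 = ref_f + alt_f
        c1 = ref_b + ref_f
        c2 = alt_b + alt_f
        total = r1 + r2
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(
                total > 1, r1 * r2 * c1 * c2 / (total**2 * np.maximum(total - 1.0, 1e-300)), 0.0
            )
        informative = v > 0
        a_sum += np.where(informative, ref_b, 0.0)
        e_sum += np.where(informative, np.where(total > 0, r1 * c1 / np.maximum(total, 1), 0.0), 0.0)
        v_sum += np.where(informative, v, 0.0)
    c = 0.5 if continuity_correction else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        statistic = np.where(v_sum > 0, np.maximum(np.abs(a_sum - e_sum) - c, 0.0) ** 2 / np.where(v_sum > 0, v_sum, 1.0), 0.0)
    p = stats.chi2.sf(statistic, df=1)
    return np.where(v_sum > 0, p, 1.0)


# ---------------------------------------------------------------------------
# q-values


def qvalues(p_values: np.ndarray, method: str = "storey", lam: float = 0.5) -> np.ndarray:
    """Convert p-values to q-values.

    Storey's estimator: ``pi0 = #{p > lam} / (m (1 - lam))`` clipped to
    (0, 1]; the q-value of the i-th order statistic is
    ``min_{j >= i} pi0 * m * p_(j) / j``, clipped at 1.  ``method="BH"`` is
    the same step-up with pi0 = 1 (Benjamini-Hochberg).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if method == "BH":
        pi0 = 1.0
    elif method == "storey":
        if not 0 < lam < 1:
            raise ValueError("lambda must lie in (0, 1)")
        pi0 = np.sum(p > lam) / (m * (1.0 - lam))
        pi0 = min(max(pi0, 1.0 / m), 1.0)  # clip to (0, 1]
    else:
        raise ValueError(f"unknown method {method!r}; expected 'storey' or 'BH'")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significant(q: np.ndarray, q_threshold: float = 0.01) -> np.ndarray:
    """Indices of SNPs with q strictly below the threshold."""
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must lie in (0, 1)")
    return np.flatnonzero(np.asarray(q) < q_threshold)


# ---------------------------------------------------------------------------
# shift-test tables


def shift_test(
    counts: AlleleCountMatrix,
    contrast: ContrastSpec,
    q_threshold: float = 0.01,
    q_method: str = "storey",
) -> pd.DataFrame:
    """Run one contrast and return the per-SNP shift-test table.

    Columns: contig, pos, p_value, q_value, significant.  q ordering
    preserves p ordering, and ``significant`` is the strict ``q < threshold``
    call.
    """
    if contrast.test == "FET":
        (baseline,), (focal,) = contrast.baseline_samples, contrast.focal_samples
        p = fet_scan(counts, baseline, focal)
    else:
        p = cmh_scan(counts, contrast.strata_pairs(), contrast.continuity_correction)
    q = qvalues(p, method=q_method)
    table = pd.DataFrame(
        {
            "contig": counts.snps["contig"].to_numpy(),
            "pos": counts.snps["pos"].to_numpy(),
            "p_value": p,
            "q_value": q,
            "significant": q < q_threshold,
        }
    )
    table.attrs["contrast"] = contrast.name
    table.attrs["test"] = contrast.test
    table.attrs["continuity_correction"] = contrast.continuity_correction
    table.attrs["q_method"] = q_method
    table.attrs["q_threshold"] = q_threshold
    return table
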