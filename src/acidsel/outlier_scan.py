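"""Locus-level outlier calling and the treatment-specific/shared partition.

A "locus" is a reference contig (transcriptome contig) carrying one or more
panel SNPs.  Within a treatment, per-day significant-SNP lists (FET for the
unreplicated day-6 samples, CMH for days 26 and 43) are lifted to locus sets
and intersected across all sampling days: an outlier locus must contain a
significant SNP on every day.  Comparing the two treatments' outlier lists
yields treatment-specific (unique) and shared loci — the shared component is
the expected signature of genetic load and lab-regime selection acting in
both environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allele_stats import ContrastSpec, call_significant, shift_test


@dataclass
class LocusMap:
    """Total mapping from SNP row index to locus (contig) identifier."""

    loci: np.ndarray  # locus id per panel SNP, aligned with the SNP axis

    @classmethod
    def from_counts(cls, counts) -> "LocusMap":
        return cls(loci=counts.snps["contig"].to_numpy())

    @property
    def n_snps(self) -> int:
        return len(self.loci)

    @property
    def all_loci(self) -> set:
        return set(self.loci.tolist())


@dataclass
class OutlierPartition:
    """Shared/unique decomposition of two treatments' outlier locus sets."""

    outliers_a: set
    outliers_b: set
    unique_a: set
    unique_b: set
    shared: set
    percent_unique_a: int
    percent_unique_b: int
    percent_unique_a_raw: float
    percent_unique_b_raw: float

    def to_dict(self) -> dict:
        return {
            "n_outliers_a": len(self.outliers_a),
            "n_outliers_b": len(self.outliers_b),
            "n_unique_a": len(self.unique_a),
            "n_unique_b": len(self.unique_b),
            "n_shared": len(self.shared),
            "percent_unique_a": self.percent_unique_a,
            "percent_unique_b": self.percent_unique_b,
        }


def loci_significant_on_day(snp_indices, locus_map: LocusMap) -> set:
    """Locus set containing at least one significant SNP (indices into the panel)."""
    snp_indices = np.asarray(list(snp_indices), dtype=int)
    if snp_indices.size == 0:
        return set()
    if snp_indices.min() < 0 or snp_indices.max() >= locus_map.n_snps:
        bad = snp_indices[(snp_indices < 0) | (snp_indices >= locus_map.n_snps)]
        raise KeyError(f"SNP indices outside the locus map: {bad[:5].tolist()}")
    return set(locus_map.loci[snp_indices].tolist())


def intersect_days(day_locus_sets: list[set]) -> set:
    """Strict intersection over all provided per-day locus sets."""
    if not day_locus_sets:
        raise ValueError("at least one day's locus set is required")
    out = set(day_locus_sets[0])
    for s in day_locus_sets[1:]:
        out &= set(s)
    return out


def partition_treatments(outliers_a: set, outliers_b: set) -> OutlierPartition:
    """Unique/shared decomposition with percent-unique per treatment.

    Percentages are 100 * |unique| / |outliers|, reported rounded to the
    nearest integer with the unrounded value retained.  Empty treatments
    report 100% unique by convention.
    """
    a, b = set(outliers_a), set(outliers_b)
    shared = a & b
    unique_a = a - b
    unique_b = b - a
    raw_a = 100.0 * len(unique_a) / len(a) if a else 100.0
    raw_b = 100.0 * len(unique_b) / len(b) if b else 100.0
    part = OutlierPartition(
        outliers_a=a,
        outliers_b=b,
        unique_a=unique_a,
        unique_b=unique_b,
        shared=shared,
        percent_unique_a=int(round(raw_a)),
        percent_unique_b=int(round(raw_b)),
        percent_unique_a_raw=raw_a,
        percent_unique_b_raw=raw_b,
    )
    # partition counts must be exactly additive
    assert len(part.unique_a) + len(part.shared) == len(a)
    assert len(part.unique_b) + len(part.shared) == len(b)
    return part


def outliers_for_treatment(
    counts,
    contrasts: list[ContrastSpec],
    locus_map: LocusMap,
    q_threshold: float = 0.01,
    q_method: str = "storey",
    level: str = "locus",
) -> tuple[set, dict[str, set]]:
    """Outlier loci for one treatment: intersection over per-day scans.

    ``contrasts`` holds one contrast per sampling day (mixed FET/CMH as the
    design dictates).  ``level="locus"`` (default) intersects per-day locus
    sets; ``level="snp"`` requires the same SNP to be significant on every
    day before lifting to loci.  Returns (outlier loci, per-day locus sets).
    """
    if level not in ("locus", "snp"):
        raise ValueError("level must be 'locus' or 'snp'")
    day_snp_sets = []
    day_locus_sets: dict[str, set] = {}
    for contrast in contrasts:
        table = shift_test(counts, contrast, q_threshold=q_threshold, q_method=q_method)
        sig = set(call_significant(table["q_value"].to_numpy(), q_threshold).tolist())
        day_snp_sets.append(sig)
        day_locus_sets[contrast.name] = loci_significant_on_day(sig, locus_map)
    if level == "locus":
        outliers = intersect_days(list(day_locus_sets.values()))
    else:
        shared_snps = set.intersection(*day_snp_sets) if day_snp_sets else set()
        outliers = loci_significant_on_day(shared_snps, locus_map)
    return outliers, day_locus_sets


def size_selected_scan(
    counts,
    replicate_pairs_by_treatment: dict[str, list[tuple[str, str]]],
    locus_map: LocusMap,
    q_threshold: float = 0.01,
    q_method: str = "storey",
    continuity_correction: bool = True,
) -> tuple[dict[str, set], dict[str, np.ndarray], OutlierPartition]:
    """Loci under selection for shell growth: fastest vs slowest per treatment.

    ``replicate_pairs_by_treatment`` maps treatment -> [(fastest_id,
    slowest_id), ...] with replicates as CMH strata.  Returns per-treatment
    locus sets, per-treatment significant SNP index arrays, and the
    cross-treatment partition (treatments in sorted key order: a, b).
    """
    locus_sets: dict[str, set] = {}
    snp_sets: dict[str, np.ndarray] = {}
    for treatment, pairs in replicate_pairs_by_treatment.items():
        if not pairs:
            raise ValueError(f"no replicate pairs for treatment {treatment!r}")
        contrast = ContrastSpec(
            name=f"size_{treatment}",
            test="CMH",
            baseline_samples=[p[0] for p in pairs],
            focal_samples=[p[1] for p in pairs],
            continuity_correction=continuity_correction,
        )
        table = shift_test(counts, contrast, q_threshold=q_threshold, q_method=q_method)
        sig = call_significant(table["q_value"].to_numpy(), q_threshold)
        snp_sets[treatment] = sig
        locus_sets[treatment] = loci_significant_on_day(sig, locus_map)
    keys = sorted(locus_sets)
    if len(keys) != 2:
        raise ValueError("size-selected partition requires exactly two treatments")
    partition = partition_treatments(locus_sets[keys[0]], locus_sets[keys[1]])
    return locus_sets, snp_sets, partition


def enrichment_odds_ratio(candidate: set, truth: set, universe: set) -> tuple[float, float]:
    """Fisher enrichment of a truth set within a candidate set over a universe.

    Returns (odds ratio, one-sided p).  Used to check that truly selected
    loci concentrate in the outlier sets recovered from simulated data.
    Haldane-corrected odds ratio (adds 0.5 to each cell) so it is finite for
    clean separations.
    """
    from scipy import stats

    candidate, truth, universe = set(candidate), set(truth), set(universe)
    a = len(candidate & truth)
    b = len(candidate - truth)
    c = len(truth - candidate)
    d = len(universe - candidate - truth)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    or_h = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return float(or_h), float(p)


def venn_summary(partition: OutlierPartition, label_a: str, label_b: str) -> dict:
    return {
        f"unique_{label_a}": len(partition.unique_a),
        f"unique_{label_b}": len(partition.unique_b),
        "shared": len(partition.shared),
        f"total_{label_a}": len(partition.outliers_a),
        f"total_{label_b}": len(partition.outliers_b),
        f"percent_unique_{label_a}": partition.percent_unique_a,
        f"percent_unique_{label_b}": partition.percent_unique_b,
    }
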