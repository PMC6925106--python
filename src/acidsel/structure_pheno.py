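"""Sample-level PCA of allele frequencies and phenotype summaries.

The genetic-structure view of the experiment is a PCA of the sample x SNP
allele-frequency matrix, with SNP columns centered and scaled to unit
variance before singular value decomposition (the standard treatment for
frequency matrices).  Phenotype summaries are descriptive: coefficient of
variation, per-day treatment size deficits, and grouped size-distribution
tables.  Inferential mixed-effects modelling of shell length is deliberately
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    coordinates: pd.DataFrame          # samples x components ("PC1", ...)
    explained_variance_fraction: np.ndarray
    center: np.ndarray                 # per retained SNP column
    scale: np.ndarray
    kept_columns: np.ndarray           # indices of non-zero-variance SNP columns
    scaling: str = "unit_variance"


def pca_samples(
    freqs: np.ndarray,
    n_components: int = 2,
    sample_ids: list[str] | None = None,
) -> PcaResult:
    """PCA of a samples x SNPs frequency matrix.

    Zero-variance SNP columns are dropped (scaling is undefined for them),
    remaining columns are centered and scaled to unit variance (n-1
    denominator, matching R's ``scale``), and scores come from the SVD of
    the standardized matrix.  The sign of each component is fixed by making
    its largest-magnitude loading positive, so results are deterministic.
    """
    x = np.asarray(freqs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    n_samples = x.shape[0]
    max_components = min(n_samples - 1, x.shape[1])
    if n_components > n_samples:
        raise ValueError(f"{n_components} components requested for {n_samples} samples")
    n_components = min(n_components, max_components)
    sd = x.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise ValueError("all SNP columns have zero variance across samples")
    xk = x[:, kept]
    center = xk.mean(axis=0)
    scale = sd[kept]
    z = (xk - center) / scale
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    explained = (s**2) / np.sum(s**2)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n_samples)]
    coords = pd.DataFrame(
        scores,
        index=list(sample_ids),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return PcaResult(
        coordinates=coords,
        explained_variance_fraction=explained[:n_components],
        center=center,
        scale=scale,
        kept_columns=kept,
    )


def coefficient_of_variation(values) -> float:
    """Sample CV as a percent: 100 * SD(n-1) / mean.  Mean must be positive."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def treatment_deficit(ambient: pd.DataFrame, lowph: pd.DataFrame) -> float:
    """Percent size deficit of the low-pH group relative to ambient, same day.

    100 * (mean_ambient - mean_lowph) / mean_ambient over the
    ``shell_length`` column; both slices must be non-empty and share one day.
    """
    if ambient.empty or lowph.empty:
        raise ValueError("both phenotype slices must be non-empty")
    days_a = set(ambient["day"].unique().tolist())
    days_b = set(lowph["day"].unique().tolist())
    if days_a != days_b or len(days_a) != 1:
        raise ValueError(f"day mismatch between slices: {sorted(days_a)} vs {sorted(days_b)}")
    mean_a = float(ambient["shell_length"].mean())
    mean_l = float(lowph["shell_length"].mean())
    return 100.0 * (mean_a - mean_l) / mean_a


def size_distribution_summary(
    table: pd.DataFrame,
    quantiles=(0.05, 0.25, 0.5, 0.75, 0.82, 0.95),
) -> pd.DataFrame:
    """Per (day, treatment) summaries of shell length.

    Returns n, mean, SD, CV (percent), the requested quantiles, and the mean
    and SD of log shell length (parametric tests on these data are run on
    the log scale).  Groups absent from the input are absent from the output.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["day", "treatment", "n", "mean", "sd", "cv_percent"]
        )
    rows = []
    for (day, treatment), grp in table.groupby(["day", "treatment"], sort=True):
        sizes = grp["shell_length"].to_numpy(dtype=float)
        row = {
            "day": day,
            "treatment": treatment,
            "n": sizes.size,
            "mean": sizes.mean(),
            "sd": sizes.std(ddof=1) if sizes.size > 1 else 0.0,
            "log_mean": np.log(sizes).mean(),
            "log_sd": np.log(sizes).std(ddof=1) if sizes.size > 1 else 0.0,
        }
        row["cv_percent"] = (
            coefficient_of_variation(sizes) if sizes.size > 1 and sizes.mean() > 0 else 0.0
        )
        for q in quantiles:
            row[f"q{q:g}"] = float(np.quantile(sizes, q))
        rows.append(row)
    return pd.DataFrame(rows)
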