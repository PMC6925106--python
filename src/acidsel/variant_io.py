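"""Pooled allele-count containers, sync/VCF I/O, and SNP panel filtering.

The central observable throughout the package is an :class:`AlleleCountMatrix`:
per-SNP reference/alternate read depths for a set of samples sharing one SNP
axis.  Counts arrive either as popoolation-style ``.sync`` files or as a
minimal VCF 4.2 with per-sample ``AD`` fields, and leave the same way.

Panel construction (:func:`build_snp_panel`) applies the two-stage filter used
for exome pool-seq panels: a founder-genotype stage (minor allele frequency,
per-founder depth, callable fraction) followed by a per-pooled-sample stage
(read-frequency MAF and depth window), keeping only SNPs that pass in every
pooled sample.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYNC_BASES = ("A", "T", "C", "G", "N", "del")

_TREATMENTS = {"ambient", "low_pH", "founder", "day0"}
_SIZE_CLASSES = {"all", "fastest", "slowest", "none"}


# ---------------------------------------------------------------------------
# containers


@dataclass
class AlleleCountMatrix:
    """Ref/alt read depths over a shared SNP axis.

    Parameters
    ----------
    snps
        DataFrame with columns ``contig``, ``pos`` (1-based), ``ref``, ``alt``;
        one row per SNP.  Rows are the canonical SNP order for ``ref_depth``
        and ``alt_depth`` (0-based internally).
    ref_depth, alt_depth
        Integer arrays of shape ``(n_snps, n_samples)``.
    sample_ids
        Column labels, keys into sample metadata.
    """

    snps: pd.DataFrame
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)
        missing = {"contig", "pos", "ref", "alt"} - set(self.snps.columns)
        if missing:
            raise ValueError(f"snps table missing columns: {sorted(missing)}")
        n_snps = len(self.snps)
        shape = (n_snps, len(self.sample_ids))
        if self.ref_depth.shape != shape or self.alt_depth.shape != shape:
            raise ValueError(
                f"depth arrays must have shape {shape}; got "
                f"{self.ref_depth.shape} and {self.alt_depth.shape}"
            )
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("read depths must be non-negative")
        ids = list(zip(self.snps["contig"], self.snps["pos"]))
        if len(set(ids)) != n_snps:
            raise ValueError("snp identifiers (contig, pos) must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    # -- basic geometry --------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def depth(self) -> np.ndarray:
        """Total read depth, ref + alt, per SNP per sample."""
        return self.ref_depth + self.alt_depth

    def snp_ids(self) -> list[tuple]:
        return list(
            zip(self.snps["contig"], self.snps["pos"], self.snps["ref"], self.snps["alt"])
        )

    # -- subsetting -------------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id: {sample_id!r}") from None

    def counts_for(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(ref_depth, alt_depth) columns for one sample."""
        j = self.sample_index(sample_id)
        return self.ref_depth[:, j], self.alt_depth[:, j]

    def select_samples(self, sample_ids: list[str]) -> "AlleleCountMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return AlleleCountMatrix(
            snps=self.snps.copy(),
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
            sample_ids=list(sample_ids),
        )

    def select_snps(self, mask: np.ndarray) -> "AlleleCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if mask.shape != (self.n_snps,):
                raise ValueError("boolean mask has wrong length")
        return AlleleCountMatrix(
            snps=self.snps.loc[mask].copy(),
            ref_depth=self.ref_depth[mask],
            alt_depth=self.alt_depth[mask],
            sample_ids=list(self.sample_ids),
        )

    def equals(self, other: "AlleleCountMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.snps[["contig", "pos", "ref", "alt"]].equals(
                other.snps[["contig", "pos", "ref", "alt"]]
            )
            and np.array_equal(self.ref_depth, other.ref_depth)
            and np.array_equal(self.alt_depth, other.alt_depth)
        )


@dataclass
class SampleMeta:
    """Per-sample experimental metadata keyed by ``sample_id``.

    ``table`` columns: sample_id, day (0/6/26/43; founders use day 0),
    treatment ({ambient, low_pH, founder, day0}), replicate, size_class
    ({all, fastest, slowest, none}), pool_min, pool_max (census bounds for
    pooled samples, in individuals).
    """

    table: pd.DataFrame

    COLUMNS = ["sample_id", "day", "treatment", "replicate", "size_class", "pool_min", "pool_max"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True)
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad_tr = set(t["treatment"]) - _TREATMENTS
        if bad_tr:
            raise ValueError(f"unknown treatment labels: {sorted(bad_tr)}")
        bad_sc = set(t["size_class"]) - _SIZE_CLASSES
        if bad_sc:
            raise ValueError(f"unknown size_class labels: {sorted(bad_sc)}")
        pooled = t["treatment"] != "founder"
        pmin = t.loc[pooled, "pool_min"].to_numpy(dtype=float)
        pmax = t.loc[pooled, "pool_max"].to_numpy(dtype=float)
        if (pmin < 1).any() or (pmax < 1).any() or (pmin > pmax).any():
            raise ValueError("pool size bounds must satisfy 1 <= pool_min <= pool_max")
        self.table = t

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all equality criteria, e.g. ``day=26, treatment='low_pH'``."""
        mask = pd.Series(True, index=self.table.index)
        for key, value in criteria.items():
            mask &= self.table[key] == value
        return self.table.loc[mask, "sample_id"].tolist()

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(f"unknown sample_id: {sample_id!r}")
        return hit.iloc[0]


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> SampleMeta:
    t = pd.read_csv(path, sep="\t")
    return SampleMeta(table=t)


@dataclass
class FilterSpec:
    """Two-stage SNP panel filter thresholds.

    Founder-stage thresholds follow VCFtools semantics: ``founder_max_missing``
    is the minimum fraction of founders in which the site must be callable
    (depth >= ``founder_depth_min``), i.e. ``--max-missing 0.75`` keeps sites
    called in at least 75% of individuals.  Pool-stage thresholds apply per
    pooled sample; a SNP is kept only if it passes in every pooled sample.
    """

    founder_maf_min: float = 0.05
    founder_depth_min: int = 10
    founder_max_missing: float = 0.75
    pool_maf_min: float = 0.01
    pool_depth_min: int = 50
    pool_depth_max: int = 450

    def __post_init__(self) -> None:
        for name in (
            "founder_maf_min",
            "founder_depth_min",
            "founder_max_missing",
            "pool_maf_min",
            "pool_depth_min",
            "pool_depth_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.pool_depth_min < self.pool_depth_max:
            raise ValueError("pool_depth_min must be < pool_depth_max")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# sync format


def write_sync(counts: AlleleCountMatrix, path) -> None:
    """Write popoolation-style sync: contig, pos, ref, then per-sample A:T:C:G:N:del."""
    base_col = {b: i for i, b in enumerate(SYNC_BASES)}
    contig = counts.snps["contig"].to_numpy()
    pos = counts.snps["pos"].to_numpy()
    ref = counts.snps["ref"].to_numpy()
    alt = counts.snps["alt"].to_numpy()
    with open(path, "w") as fh:
        for i in range(counts.n_snps):
            cols = [str(contig[i]), str(pos[i]), str(ref[i])]
            ri, ai = base_col[ref[i]], base_col[alt[i]]
            for j in range(counts.n_samples):
                cells = [0] * 6
                cells[ri] = int(counts.ref_depth[i, j])
                cells[ai] = int(counts.alt_depth[i, j])
                cols.append(":".join(str(c) for c in cells))
            fh.write("\t".join(cols) + "\n")


def read_sync(
    path,
    sample_ids: list[str] | None = None,
    alleles: dict[tuple, tuple[str, str]] | None = None,
    on_multiallelic: str = "error",
) -> AlleleCountMatrix:
    """Parse a sync file into an :class:`AlleleCountMatrix`.

    The reference base comes from column 3.  The alternate allele is taken
    from ``alleles[(contig, pos)]`` when provided, otherwise inferred as the
    non-reference base with the highest total count across samples (ties
    broken alphabetically).  Reads on bases other than the declared pair are
    ignored but tallied; more than two segregating bases at a SNP is handled
    per ``on_multiallelic``: ``"error"`` raises, ``"drop"`` removes the SNP
    with a warning.
    """
    if on_multiallelic not in ("error", "drop"):
        raise ValueError("on_multiallelic must be 'error' or 'drop'")
    rows, refs, alts, ref_counts, alt_counts = [], [], [], [], []
    n_samples = None
    ignored_reads = 0
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed sync line {lineno}: expected >= 4 columns")
            contig, pos_s, ref = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"malformed sync line {lineno}: bad position {pos_s!r}")
            if ref not in SYNC_BASES[:4]:
                raise ValueError(f"malformed sync line {lineno}: bad reference base {ref!r}")
            if n_samples is None:
                n_samples = len(parts) - 3
            elif len(parts) - 3 != n_samples:
                raise ValueError(f"malformed sync line {lineno}: inconsistent column count")
            cells = np.zeros((n_samples, 6), dtype=np.int64)
            for j, cell in enumerate(parts[3:]):
                vals = cell.split(":")
                if len(vals) != 6:
                    raise ValueError(f"malformed sync line {lineno}: count cell {cell!r}")
                try:
                    cells[j] = [int(v) for v in vals]
                except ValueError:
                    raise ValueError(f"malformed sync line {lineno}: count cell {cell!r}")
            totals = cells[:, :4].sum(axis=0)  # A,T,C,G totals across samples
            ri = SYNC_BASES.index(ref)
            if alleles is not None and (contig, pos) in alleles:
                ref_decl, alt = alleles[(contig, pos)]
                if ref_decl != ref:
                    raise ValueError(
                        f"line {lineno}: declared ref {ref_decl!r} != sync ref {ref!r}"
                    )
            else:
                order = sorted(
                    (b for k, b in enumerate(SYNC_BASES[:4]) if k != ri),
                    key=lambda b: (-totals[SYNC_BASES.index(b)], b),
                )
                alt = order[0]
            ai = SYNC_BASES.index(alt)
            segregating = [k for k in range(4) if totals[k] > 0]
            extra = [k for k in segregating if k not in (ri, ai)]
            if extra:
                if on_multiallelic == "error":
                    raise ValueError(
                        f"line {lineno}: >2 segregating bases at {contig}:{pos}"
                    )
                n_dropped += 1
                continue
            ignored_reads += int(cells[:, [4, 5]].sum())
            rows.append((contig, pos))
            refs.append(ref)
            alts.append(alt)
            ref_counts.append(cells[:, ri])
            alt_counts.append(cells[:, ai])
    if n_samples is None:
        raise ValueError("empty sync file")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} multiallelic sync records", stacklevel=2)
    if sample_ids is None:
        sample_ids = [f"sample_{j}" for j in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise ValueError("sample_ids length does not match sync column count")
    snps = pd.DataFrame(
        {
            "contig": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "ref": refs,
            "alt": alts,
        }
    )
    return AlleleCountMatrix(
        snps=snps,
        ref_depth=np.array(ref_counts, dtype=np.int64).reshape(len(rows), n_samples),
        alt_depth=np.array(alt_counts, dtype=np.int64).reshape(len(rows), n_samples),
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# VCF


def write_vcf(counts: AlleleCountMatrix, path) -> None:
    """Write a minimal VCF 4.2 with per-sample AD and DP FORMAT fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for contig in pd.unique(counts.snps["contig"]):
        max_pos = int(counts.snps.loc[counts.snps["contig"] == contig, "pos"].max())
        header.contigs.add(str(contig), length=max_pos + 1000)
    for sid in counts.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(counts.n_snps):
            rec = out.new_record(
                contig=str(counts.snps["contig"].iat[i]),
                start=int(counts.snps["pos"].iat[i]) - 1,
                alleles=(str(counts.snps["ref"].iat[i]), str(counts.snps["alt"].iat[i])),
            )
            for j, sid in enumerate(counts.sample_ids):
                ref_d = int(counts.ref_depth[i, j])
                alt_d = int(counts.alt_depth[i, j])
                rec.samples[sid]["AD"] = (ref_d, alt_d)
                rec.samples[sid]["DP"] = ref_d + alt_d
            out.write(rec)


def read_vcf_ad(path) -> tuple[AlleleCountMatrix, int]:
    """Read biallelic records with per-sample AD into an AlleleCountMatrix.

    Returns ``(counts, n_multiallelic_skipped)``.  Records with more than one
    ALT allele are skipped and counted; a VCF whose FORMAT lacks AD raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    contigs, positions, refs, alts = [], [], [], []
    ref_rows, alt_rows = [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"record {variant.CHROM}:{variant.POS} has no AD FORMAT field")
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # missing AD encoded negative
        contigs.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        ref_rows.append(ad[:, 0])
        alt_rows.append(ad[:, 1])
    vcf.close()
    snps = pd.DataFrame({"contig": contigs, "pos": positions, "ref": refs, "alt": alts})
    counts = AlleleCountMatrix(
        snps=snps,
        ref_depth=np.array(ref_rows, dtype=np.int64).reshape(len(snps), len(sample_ids)),
        alt_depth=np.array(alt_rows, dtype=np.int64).reshape(len(snps), len(sample_ids)),
        sample_ids=sample_ids,
    )
    return counts, n_skipped


# ---------------------------------------------------------------------------
# frequencies and the panel filter


def allele_frequency(counts: AlleleCountMatrix) -> np.ndarray:
    """Alternate-allele read frequency alt/(ref+alt) per SNP per sample.

    Zero-depth cells are flagged missing (NaN) rather than reported as 0.
    """
    depth = counts.depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, counts.alt_depth / np.where(depth > 0, depth, 1), np.nan)
    return freq


@dataclass
class PanelReport:
    """Attrition bookkeeping for :func:`build_snp_panel`."""

    n_input: int
    n_kept: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def build_snp_panel(
    counts: AlleleCountMatrix,
    founder_counts: AlleleCountMatrix,
    spec: FilterSpec | None = None,
) -> tuple[AlleleCountMatrix, PanelReport]:
    """Two-stage panel filter over a shared SNP coordinate space.

    Stage 1 (founders): a SNP must be callable (depth >= founder_depth_min)
    in at least ``founder_max_missing`` of founders, and its minor allele
    frequency — computed from summed read counts over callable founders —
    must be >= ``founder_maf_min``.

    Stage 2 (pools): in *every* pooled sample the SNP must have depth within
    ``[pool_depth_min, pool_depth_max]`` and read-frequency MAF >=
    ``pool_maf_min``.

    Rules are attributed in order (founder_missing, founder_maf, pool_depth,
    pool_maf); a SNP is charged to the first rule it violates.  An empty
    result raises with the attrition table in the message.
    """
    if spec is None:
        spec = FilterSpec()
    key_cols = ["contig", "pos"]
    pool_key = counts.snps.set_index(key_cols).index
    founder_key = founder_counts.snps.set_index(key_cols).index
    if not pool_key.equals(founder_key):
        # align on the shared coordinates; both matrices must cover the panel space
        shared = pool_key.intersection(founder_key)
        if len(shared) == 0:
            raise ValueError("founder and pooled matrices share no SNP coordinates")
        counts = counts.select_snps(pool_key.isin(shared))
        founder_counts = founder_counts.select_snps(founder_key.isin(shared))

    n_input = counts.n_snps
    removed = {"founder_missing": 0, "founder_maf": 0, "pool_depth": 0, "pool_maf": 0}
    alive = np.ones(n_input, dtype=bool)

    # stage 1: founder callability and MAF
    f_depth = founder_counts.depth
    callable_ = f_depth >= spec.founder_depth_min
    frac_called = callable_.mean(axis=1)
    fail = alive & (frac_called < spec.founder_max_missing)
    removed["founder_missing"] = int(fail.sum())
    alive &= ~fail

    alt_sum = np.where(callable_, founder_counts.alt_depth, 0).sum(axis=1).astype(float)
    tot_sum = np.where(callable_, f_depth, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_freq = np.where(tot_sum > 0, alt_sum / np.where(tot_sum > 0, tot_sum, 1), np.nan)
    f_maf = np.fmin(f_freq, 1.0 - f_freq)
    fail = alive & ~(f_maf >= spec.founder_maf_min)
    removed["founder_maf"] = int(fail.sum())
    alive &= ~fail

    # stage 2: pooled-sample depth window and per-sample MAF
    p_depth = counts.depth
    depth_ok = (p_depth >= spec.pool_depth_min) & (p_depth <= spec.pool_depth_max)
    fail = alive & ~depth_ok.all(axis=1)
    removed["pool_depth"] = int(fail.sum())
    alive &= ~fail

    freq = allele_frequency(counts)
    maf = np.fmin(freq, 1.0 - freq)
    maf_ok = np.where(np.isnan(maf), False, maf >= spec.pool_maf_min)
    fail = alive & ~maf_ok.all(axis=1)
    removed["pool_maf"] = int(fail.sum())
    alive &= ~fail

    report = PanelReport(n_input=n_input, n_kept=int(alive.sum()), removed_by_rule=removed)
    if report.n_kept == 0:
        raise ValueError(f"empty SNP panel after filtering; attrition: {removed}")
    return counts.select_snps(alive), report
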