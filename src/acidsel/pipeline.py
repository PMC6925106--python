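"""End-to-end orchestration: simulate -> panel -> shift tests -> outliers ->
F_ST -> structure/phenotype summaries, as one reproducible, seeded run.

A :class:`RunConfig` fans a single global seed out to per-stage seeds through
``numpy.random.SeedSequence`` spawning in a fixed stage order, so any stage
can be rerun in isolation.  Every artifact is a text file (sync, TSV, JSON)
with floats serialized to 12 significant digits, making digests stable; the
run manifest records the config hash and per-stage output digests, and a
rerun with ``resume=True`` skips stages whose outputs already exist under the
same config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import outlier_scan, pool_fst, structure_pheno
from .allele_stats import ContrastSpec, shift_test
from .simulate import ExperimentConfig, SeqNoiseModel, run_experiment
from .variant_io import (
    AlleleCountMatrix,
    FilterSpec,
    SampleMeta,
    allele_frequency,
    build_snp_panel,
    read_sample_meta,
    read_sync,
    write_sample_meta,
    write_sync,
)

log = logging.getLogger("acidsel")

_FLOAT_FMT = "%.12g"

_STAGES = ("simulate", "panel", "shift", "outliers", "fst", "structure")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 1
    simulator: dict = field(default_factory=dict)     # ExperimentConfig overrides
    filters: dict = field(default_factory=dict)       # FilterSpec overrides
    q_threshold: float = 0.01
    q_method: str = "storey"
    outlier_level: str = "locus"
    continuity_correction: bool = True
    day6_pool_grid: tuple = pool_fst.DAY6_POOL_GRID
    day43_pool_grid: tuple = pool_fst.DAY43_POOL_GRID
    output_dir: str = "acidsel_run"

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.q_method not in ("storey", "BH"):
            raise ValueError("q_method must be 'storey' or 'BH'")
        if self.outlier_level not in ("locus", "snp"):
            raise ValueError("outlier_level must be 'locus' or 'snp'")
        known_sim = {f.name for f in dataclasses.fields(ExperimentConfig)}
        unknown = set(self.simulator) - known_sim
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        known_filt = {f.name for f in dataclasses.fields(FilterSpec)}
        unknown = set(self.filters) - known_filt
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")

    def experiment_config(self) -> ExperimentConfig:
        kwargs = dict(self.simulator)
        for key in ("pool_noise", "founder_noise"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = SeqNoiseModel(**kwargs[key])
        return ExperimentConfig(**kwargs)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(**self.filters)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("day6_pool_grid", "day43_pool_grid"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# contrast topology


def standard_contrasts(
    meta: SampleMeta, continuity_correction: bool = True
) -> dict[str, list[ContrastSpec]]:
    """Per-treatment shift contrasts mirroring the experimental design.

    Day 6 has a single full-population sample per treatment, so the day-0
    pool is compared by FET; days 26 and 43 have replicate buckets and use
    CMH with the day-0 pool as the baseline in each stratum.
    """
    baseline = meta.select(day=0, treatment="day0")
    if len(baseline) != 1:
        raise ValueError("expected exactly one day-0 baseline pool")
    out: dict[str, list[ContrastSpec]] = {}
    treatments = sorted(set(meta.table["treatment"]) - {"founder", "day0"})
    for tr in treatments:
        contrasts = []
        d6 = meta.select(day=6, treatment=tr, size_class="all")
        if len(d6) != 1:
            raise ValueError(f"expected one day-6 full-population sample for {tr!r}")
        contrasts.append(
            ContrastSpec(name=f"{tr}_day6", test="FET",
                         baseline_samples=baseline, focal_samples=d6)
        )
        for day in (26, 43):
            focal = meta.select(day=day, treatment=tr, size_class="all")
            if not focal:
                raise ValueError(f"no day-{day} samples for {tr!r}")
            contrasts.append(
                ContrastSpec(
                    name=f"{tr}_day{day}", test="CMH",
                    baseline_samples=baseline, focal_samples=focal,
                    continuity_correction=continuity_correction,
                )
            )
        out[tr] = contrasts
    return out


def size_split_pairs(meta: SampleMeta) -> dict[str, list[tuple[str, str]]]:
    """(fastest, slowest) sample pairs per treatment, replicates as strata."""
    out: dict[str, list[tuple[str, str]]] = {}
    treatments = sorted(set(meta.table["treatment"]) - {"founder", "day0"})
    for tr in treatments:
        fast = meta.select(day=6, treatment=tr, size_class="fastest")
        pairs = []
        for f in fast:
            rep = meta.row(f)["replicate"]
            slow = meta.select(day=6, treatment=tr, size_class="slowest", replicate=rep)
            if len(slow) != 1:
                raise ValueError(f"missing slowest pool for {tr!r} replicate {rep!r}")
            pairs.append((f, slow[0]))
        out[tr] = pairs
    return out


def outlier_analysis(
    counts: AlleleCountMatrix,
    meta: SampleMeta,
    q_threshold: float = 0.01,
    q_method: str = "storey",
    level: str = "locus",
    continuity_correction: bool = True,
):
    """Run the full per-treatment outlier scan and cross-treatment partition.

    Returns ``(partition, outliers_by_treatment, per_day_locus_sets)`` with
    treatments ordered alphabetically in the partition (a = ambient,
    b = low_pH under the default design).
    """
    locus_map = outlier_scan.LocusMap.from_counts(counts)
    contrasts = standard_contrasts(meta, continuity_correction)
    outliers: dict[str, set] = {}
    per_day: dict[str, dict[str, set]] = {}
    for tr, specs in contrasts.items():
        outliers[tr], per_day[tr] = outlier_scan.outliers_for_treatment(
            counts, specs, locus_map,
            q_threshold=q_threshold, q_method=q_method, level=level,
        )
    keys = sorted(outliers)
    if len(keys) != 2:
        raise ValueError("outlier partition requires exactly two treatments")
    partition = outlier_scan.partition_treatments(outliers[keys[0]], outliers[keys[1]])
    return partition, outliers, per_day


def evaluate_outlier_recovery(sim, q_threshold: float = 0.01) -> dict:
    """Score the outlier scan of a simulated experiment against its truth.

    Builds the filtered panel, runs the per-treatment outlier analysis, and
    returns recovery of environment-specific loci in the correct treatment's
    unique set, the enrichment odds ratio of truly shared loci in the shared
    set, and the false-positive locus rate (non-selected loci called
    outliers, as a fraction of panel loci).
    """
    founder_ids = sim.meta.select(treatment="founder")
    pooled_ids = [s for s in sim.meta.table["sample_id"] if s not in set(founder_ids)]
    panel, _report = build_snp_panel(
        sim.counts.select_samples(pooled_ids), sim.counts.select_samples(founder_ids)
    )
    pooled_meta = SampleMeta(
        table=sim.meta.table[sim.meta.table["sample_id"].isin(pooled_ids)].reset_index(
            drop=True
        )
    )
    partition, outliers, _ = outlier_analysis(panel, pooled_meta, q_threshold=q_threshold)
    truth = sim.truth.selected_contigs
    panel_loci = set(panel.snps["contig"])
    unique = {"ambient": partition.unique_a, "low_pH": partition.unique_b}
    n_env = len(truth["ambient"]) + len(truth["low_pH"])
    n_recovered = len(truth["ambient"] & unique["ambient"]) + len(
        truth["low_pH"] & unique["low_pH"]
    )
    truth_all = truth["shared"] | truth["ambient"] | truth["low_pH"]
    false_pos = (partition.outliers_a | partition.outliers_b) - truth_all
    shared_or, shared_p = outlier_scan.enrichment_odds_ratio(
        partition.shared, truth["shared"], panel_loci
    )
    return {
        "n_env_truth": n_env,
        "n_env_recovered": n_recovered,
        "recovery_fraction": n_recovered / n_env if n_env else float("nan"),
        "shared_enrichment_or": shared_or,
        "shared_enrichment_p": shared_p,
        "n_false_positive_loci": len(false_pos),
        "n_panel_loci": len(panel_loci),
        "false_positive_rate": len(false_pos) / len(panel_loci),
        "n_outliers_ambient": len(partition.outliers_a),
        "n_outliers_lowph": len(partition.outliers_b),
    }


# ---------------------------------------------------------------------------
# run_all


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(payload: dict, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(f"{float(o):.12g}")
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        return str(o)

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n")


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute every stage in dependency order; returns the run manifest.

    Stage outputs are written before the next stage starts; a failure stops
    the run with the failing stage named.  With ``resume=True``, stages whose
    outputs already exist under the same config hash are reloaded from disk
    instead of recomputed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != chash:
            log.warning("config hash changed; ignoring previous manifest")
            previous = {}
    manifest: dict = {"config_hash": chash, "config": config.to_dict(), "stages": {}}

    def stage_done(name: str, files: list[Path]) -> bool:
        prior = previous.get("stages", {}).get(name)
        if not prior:
            return False
        return all(p.exists() and _digest(p) == prior["outputs"].get(p.name) for p in files)

    def record(name: str, files: list[Path], t0: float, recomputed: bool) -> None:
        manifest["stages"][name] = {
            "outputs": {p.name: _digest(p) for p in files},
            "seconds": round(time.time() - t0, 3),
            "recomputed": recomputed,
        }
        _write_json(manifest, manifest_path)

    exp_config = config.experiment_config()

    # ---- stage: simulate -------------------------------------------------
    t0 = time.time()
    sync_path = out / "counts.sync"
    meta_path = out / "samples.tsv"
    pheno_path = out / "phenotypes.tsv"
    truth_path = out / "truth.json"
    truth_freq_path = out / "true_frequencies.tsv"
    sim_files = [sync_path, meta_path, pheno_path, truth_path, truth_freq_path]
    if stage_done("simulate", sim_files):
        log.info("simulate: resuming from existing outputs")
        counts = read_sync(sync_path)
        meta = read_sample_meta(meta_path)
        counts.sample_ids[:] = meta.table["sample_id"].tolist()
        phenotypes = pd.read_csv(pheno_path, sep="\t")
        truth_payload = json.loads(truth_path.read_text())
        census = pd.DataFrame(truth_payload["census"])
        recomputed = False
    else:
        log.info("simulate: n_offspring=%d n_snps=%d seed=%d",
                 exp_config.n_offspring, exp_config.n_snps, config.seed)
        sim = run_experiment(exp_config, seed=config.seed)
        counts, meta, phenotypes = sim.counts, sim.meta, sim.phenotypes
        census = sim.truth.census
        write_sync(counts, sync_path)
        write_sample_meta(meta, meta_path)
        phenotypes.to_csv(pheno_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        freq_df = pd.DataFrame(sim.truth.true_pool_freq)
        freq_df.insert(0, "contig", counts.snps["contig"])
        freq_df.insert(1, "pos", counts.snps["pos"])
        freq_df.to_csv(truth_freq_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        _write_json(
            {
                "selected_contigs": {k: sorted(v) for k, v in sim.truth.selected_contigs.items()},
                "growth_contigs": {k: sorted(v) for k, v in sim.truth.growth_contigs.items()},
                "census": census.to_dict(orient="records"),
            },
            truth_path,
        )
        recomputed = True
    record("simulate", sim_files, t0, recomputed)
    log.info("simulate: %d SNPs x %d samples", counts.n_snps, counts.n_samples)

    # ---- stage: panel ----------------------------------------------------
    t0 = time.time()
    founder_ids = meta.select(treatment="founder")
    pooled_ids = [s for s in meta.table["sample_id"] if s not in set(founder_ids)]
    panel, report = build_snp_panel(
        counts.select_samples(pooled_ids),
        counts.select_samples(founder_ids),
        config.filter_spec(),
    )
    panel_path = out / "panel.sync"
    report_path = out / "panel_report.json"
    write_sync(panel, panel_path)
    _write_json(report.to_dict(), report_path)
    record("panel", [panel_path, report_path], t0, True)
    log.info("panel: kept %d of %d SNPs (%s)", report.n_kept, report.n_input,
             report.removed_by_rule)

    # ---- stage: shift tests ---------------------------------------------
    t0 = time.time()
    pooled_meta = SampleMeta(
        table=meta.table[meta.table["sample_id"].isin(pooled_ids)].reset_index(drop=True)
    )
    contrasts = standard_contrasts(pooled_meta, config.continuity_correction)
    shift_files = []
    for tr, specs in contrasts.items():
        for spec in specs:
            table = shift_test(panel, spec, q_threshold=config.q_threshold,
                               q_method=config.q_method)
            path = out / f"shift_{spec.name}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
            shift_files.append(path)
            log.info("shift %s (%s): %d significant SNPs",
                     spec.name, spec.test, int(table["significant"].sum()))
    record("shift", shift_files, t0, True)

    # ---- stage: outliers -------------------------------------------------
    t0 = time.time()
    partition, outliers, _per_day = outlier_analysis(
        panel, pooled_meta,
        q_threshold=config.q_threshold, q_method=config.q_method,
        level=config.outlier_level,
        continuity_correction=config.continuity_correction,
    )
    keys = sorted(outliers)
    venn = outlier_scan.venn_summary(partition, keys[0], keys[1])
    locus_map = outlier_scan.LocusMap.from_counts(panel)
    size_sets, _size_snps, size_partition = outlier_scan.size_selected_scan(
        panel, size_split_pairs(pooled_meta), locus_map,
        q_threshold=config.q_threshold, q_method=config.q_method,
        continuity_correction=config.continuity_correction,
    )
    size_keys = sorted(size_sets)
    venn_path = out / "outlier_venn.json"
    _write_json(
        {
            "outliers": venn,
            "size_selected": outlier_scan.venn_summary(size_partition, *size_keys),
            "outlier_loci": {k: sorted(v) for k, v in outliers.items()},
            "size_selected_loci": {k: sorted(v) for k, v in size_sets.items()},
        },
        venn_path,
    )
    record("outliers", [venn_path], t0, True)
    log.info("outliers: %s", venn)

    # ---- stage: F_ST -----------------------------------------------------
    t0 = time.time()
    baseline = pooled_meta.select(day=0, treatment="day0")[0]
    n0 = int(pooled_meta.row(baseline)["pool_min"])
    fst_rows = []
    for _, row in pooled_meta.table.iterrows():
        if row["day"] not in (6, 26, 43) or row["size_class"] not in ("all",):
            continue
        est = pool_fst.fst_between_samples(
            panel, baseline, row["sample_id"], n0, int(row["pool_min"])
        )
        fst_rows.append(
            {
                "sample": row["sample_id"],
                "day": row["day"],
                "treatment": row["treatment"],
                **{k: v for k, v in est.to_dict().items() if k != "pair"},
            }
        )
    fst_table = pd.DataFrame(fst_rows)
    fst_path = out / "fst_pairs.tsv"
    fst_table.to_csv(fst_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    # pool-size sensitivity sweeps for the unobserved day-6 and day-43 censuses
    sweep_frames = []
    scale = exp_config.n_offspring / 100_000
    for day, grid in ((6, config.day6_pool_grid), (43, config.day43_pool_grid)):
        grid_scaled = sorted({max(2, int(round(g * scale))) for g in grid})
        for tr in sorted(set(pooled_meta.table["treatment"]) - {"day0"}):
            sids = pooled_meta.select(day=day, treatment=tr, size_class="all")
            for sid in sids:
                ref_a, alt_a = panel.counts_for(baseline)
                ref_b, alt_b = panel.counts_for(sid)
                sweep = pool_fst.pool_size_sweep(
                    ref_a, alt_a, ref_b, alt_b, [n0], grid_scaled
                )
                sweep.insert(0, "sample", sid)
                sweep.insert(1, "day", day)
                sweep_frames.append(sweep)
    sweep_path = out / "fst_pool_size_sweep.tsv"
    pd.concat(sweep_frames, ignore_index=True).to_csv(
        sweep_path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    record("fst", [fst_path, sweep_path], t0, True)
    log.info("fst: %d pairwise estimates", len(fst_table))

    # ---- stage: structure + phenotypes ----------------------------------
    t0 = time.time()
    full_pop_ids = [
        s for s in pooled_ids
        if pooled_meta.row(s)["size_class"] == "all"
    ]
    freqs = allele_frequency(panel.select_samples(full_pop_ids))
    filled = np.where(np.isnan(freqs), 0.5, freqs)  # missing cells are rare post-filter
    pca = structure_pheno.pca_samples(filled.T, n_components=2, sample_ids=full_pop_ids)
    pca_path = out / "pca_scores.tsv"
    coords = pca.coordinates.copy()
    coords["explained_1"] = pca.explained_variance_fraction[0]
    if pca.explained_variance_fraction.size > 1:
        coords["explained_2"] = pca.explained_variance_fraction[1]
    coords.to_csv(pca_path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)
    pheno_summary = structure_pheno.size_distribution_summary(phenotypes)
    pheno_sum_path = out / "phenotype_summary.tsv"
    pheno_summary.to_csv(pheno_sum_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    record("structure", [pca_path, pheno_sum_path], t0, True)

    _write_json(manifest, manifest_path)
    return manifest


def replicate_paper_design(seed: int = 1, output_dir: str = "acidsel_run", **sim_overrides) -> dict:
    """Run the pipeline on the exact published sampling topology.

    Day-43 ambient has 2 sequenced replicates and low pH 3; day 6 sees three
    replicates per treatment destructively sampled, two of them size-split.
    ``sim_overrides`` may rescale ``n_offspring``/``n_snps`` for desk runs.
    """
    config = RunConfig(seed=seed, simulator=dict(sim_overrides), output_dir=output_dir)
    return run_all(config)
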