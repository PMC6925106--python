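"""Forward simulator of the factorial-cross larval selection experiment.

The simulated design mirrors a two-pH mussel larval rearing experiment: a
wild-caught founder panel of 12 dams x 16 sires (192 crosses) seeds a day-0
zygote pool of 100,000 individuals per replicate bucket; six replicate
buckets per pH treatment undergo staged viability selection with ~97.7%
(ambient) / 97.6% (low pH) cumulative mortality by day 26; three replicates
per treatment are destructively sampled on day 6 with a truncation split of
the size distribution (largest 18% in ambient, 21% in low pH); survivors are
pool-sequenced at roughly 100x coverage (40x for founders).

Model choices (see docs/methods.md for rationale):

* Loci are biallelic, unlinked, and act marginally; offspring genotypes are
  Mendelian draws from parental dosages.
* Viability selection is truncation on a latent fitness score: the sum of
  dominance-weighted locus effects plus Gumbel-distributed
  micro-environmental noise.  With unit Gumbel noise, keeping the top K
  individuals is equivalent to sampling K survivors without replacement with
  probability proportional to exp(score), i.e. classic multiplicative
  viability selection; with noise scale 0 it degenerates to deterministic
  rank truncation.  A configurable fraction of deaths is uniformly random
  ("drift deaths"), independent of genotype.
* Selected loci come in three classes: shared "load" loci (deleterious in
  both environments) and environment-specific loci for each pH treatment.
* Shell size is a deterministic day baseline, multiplied by a low-pH deficit
  schedule (8% through day 7, relaxing linearly to 2.5% by day 26), plus
  centered additive effects of growth loci and Gaussian noise.
* Pooled sequencing draws per-SNP coverage from a negative binomial and
  alternate read counts binomially at the pool's true allele frequency
  (reads sample gene copies with replacement; pools are large relative to
  coverage).

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .variant_io import AlleleCountMatrix, SampleMeta

_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# allele-frequency distributions for the founder panel


def _draw_afs(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw founder-population allele frequencies from a parametric spec.

    ``spec`` is a dict with key ``kind``: ``uniform`` (low, high), ``beta``
    (a, b), or ``point`` (value).  Frequencies must be able to fall strictly
    inside (0, 1); degenerate specs raise, naming ``af_distribution``.
    """
    kind = spec.get("kind")
    if kind == "uniform":
        low, high = float(spec.get("low", 0.1)), float(spec.get("high", 0.9))
        if not (0.0 <= low <= high <= 1.0) or (low == high and low in (0.0, 1.0)):
            raise ValueError("degenerate af_distribution: uniform bounds give no interior mass")
        if high <= 0.0 or low >= 1.0:
            raise ValueError("degenerate af_distribution: all mass at 0 or 1")
        return rng.uniform(low, high, size=n)
    if kind == "beta":
        a, b = float(spec["a"]), float(spec["b"])
        if a <= 0 or b <= 0:
            raise ValueError("degenerate af_distribution: beta parameters must be positive")
        return rng.beta(a, b, size=n)
    if kind == "point":
        p = float(spec["value"])
        if not 0.0 < p < 1.0:
            raise ValueError("degenerate af_distribution: point mass must lie in (0, 1)")
        return np.full(n, p)
    raise ValueError(f"unknown af_distribution kind {kind!r}")


# ---------------------------------------------------------------------------
# founders and zygotes


@dataclass
class FounderPanel:
    """Diploid founder genotypes: dams first, then sires; dosages in {0,1,2}."""

    n_dams: int
    n_sires: int
    genotypes: np.ndarray      # (n_dams + n_sires, n_snps) int8 alt-allele dosage
    founder_afs: np.ndarray    # realized alt-allele frequency among founders
    snps: pd.DataFrame         # contig, pos, ref, alt

    @property
    def n_founders(self) -> int:
        return self.n_dams + self.n_sires

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_crosses(self) -> int:
        return self.n_dams * self.n_sires


def _snp_table(n_snps: int, snps_per_contig: int) -> pd.DataFrame:
    idx = np.arange(n_snps)
    contigs = [f"contig_{i:06d}" for i in idx // snps_per_contig]
    pos = ((idx % snps_per_contig) + 1) * 100
    ref = [_BASES[i % 4] for i in idx]
    alt = [_BASES[(i + 1) % 4] for i in idx]
    return pd.DataFrame({"contig": contigs, "pos": pos, "ref": ref, "alt": alt})


def make_founders(
    n_dams: int = 12,
    n_sires: int = 16,
    n_snps: int = 10_000,
    af_distribution: dict | None = None,
    seed: int = 0,
    snps_per_contig: int = 3,
    monomorphic: str = "redraw",
    max_redraws: int = 100,
) -> FounderPanel:
    """Draw the diploid founder panel.

    Each founder's dosage at a SNP is a binomial(2, p) draw — two independent
    alleles at the population frequency p drawn from ``af_distribution``
    (default uniform on [0.1, 0.9]).  SNPs monomorphic across all founders
    are redrawn (``monomorphic="redraw"``) or dropped (``"drop"``).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if monomorphic not in ("redraw", "drop"):
        raise ValueError("monomorphic must be 'redraw' or 'drop'")
    if af_distribution is None:
        af_distribution = {"kind": "uniform", "low": 0.1, "high": 0.9}
    rng = np.random.default_rng(seed)
    n_founders = n_dams + n_sires
    afs = _draw_afs(af_distribution, n_snps, rng)
    geno = rng.binomial(2, afs, size=(n_founders, n_snps)).astype(np.int8)
    if monomorphic == "redraw":
        for _ in range(max_redraws):
            tot = geno.sum(axis=0)
            mono = (tot == 0) | (tot == 2 * n_founders)
            if not mono.any():
                break
            k = int(mono.sum())
            afs[mono] = _draw_afs(af_distribution, k, rng)
            geno[:, mono] = rng.binomial(2, afs[mono], size=(n_founders, k)).astype(np.int8)
        else:
            raise RuntimeError("could not resolve monomorphic SNPs; af_distribution too extreme")
        keep = np.ones(n_snps, dtype=bool)
    else:
        tot = geno.sum(axis=0)
        keep = (tot > 0) & (tot < 2 * n_founders)
        geno = geno[:, keep]
    snps = _snp_table(n_snps, snps_per_contig).loc[keep].reset_index(drop=True)
    founder_afs = geno.sum(axis=0) / (2.0 * n_founders)
    return FounderPanel(
        n_dams=n_dams, n_sires=n_sires, genotypes=geno, founder_afs=founder_afs, snps=snps
    )


@dataclass
class ZygotePool:
    """A collection of diploid offspring with their cross assignments."""

    genotypes: np.ndarray   # (n, n_snps) int8 dosage
    dam_idx: np.ndarray     # (n,) dam index 0..n_dams-1
    sire_idx: np.ndarray    # (n,) sire index 0..n_sires-1
    ids: np.ndarray         # (n,) stable individual identifiers

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def cross_ids(self, n_sires: int) -> np.ndarray:
        return self.dam_idx.astype(np.int64) * n_sires + self.sire_idx

    def allele_frequency(self) -> np.ndarray:
        """True pool alternate-allele frequency per SNP."""
        return self.genotypes.mean(axis=0, dtype=np.float64) / 2.0

    def subset(self, indices: np.ndarray) -> "ZygotePool":
        indices = np.sort(np.asarray(indices))
        return ZygotePool(
            genotypes=self.genotypes[indices],
            dam_idx=self.dam_idx[indices],
            sire_idx=self.sire_idx[indices],
            ids=self.ids[indices],
        )


def make_zygote_pool(
    founders: FounderPanel, n_offspring: int, seed: int = 0, chunk: int = 2048
) -> ZygotePool:
    """Generate offspring from the full factorial cross.

    Offspring are assigned to the ``n_dams x n_sires`` crosses with equal
    expected proportions; each genotype is formed by drawing one allele from
    the dam and one from the sire per SNP, loci independent (no linkage).
    Generation is chunked to bound temporary-array memory.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    n_crosses = founders.n_crosses
    cross = rng.integers(0, n_crosses, size=n_offspring)
    dam_idx = (cross // founders.n_sires).astype(np.int32)
    sire_idx = (cross % founders.n_sires).astype(np.int32)
    dam_geno = founders.genotypes[: founders.n_dams]
    sire_geno = founders.genotypes[founders.n_dams :]
    m = founders.n_snps
    geno = np.empty((n_offspring, m), dtype=np.int8)
    for start in range(0, n_offspring, chunk):
        sl = slice(start, min(start + chunk, n_offspring))
        p_dam = dam_geno[dam_idx[sl]] * 0.5
        p_sire = sire_geno[sire_idx[sl]] * 0.5
        gam_d = rng.random(p_dam.shape) < p_dam
        gam_s = rng.random(p_sire.shape) < p_sire
        geno[sl] = gam_d.astype(np.int8) + gam_s.astype(np.int8)
    return ZygotePool(
        genotypes=geno, dam_idx=dam_idx, sire_idx=sire_idx, ids=np.arange(n_offspring)
    )


# ---------------------------------------------------------------------------
# selection regime and viability episodes


@dataclass
class SelectionRegime:
    """Selected-locus classes with per-locus effects and dominance.

    ``effects`` are selection coefficients on the latent (log-viability)
    fitness scale; negative values are deleterious for the alternate allele.
    Dominance h weights the heterozygote: the locus contribution is
    effect * {0: 0, 1: h, 2: 1}[dosage].  ``episode_schedule`` optionally
    records (day, survivor count or fraction) pairs per treatment.
    """

    loci_shared: np.ndarray
    loci_ambient: np.ndarray
    loci_lowph: np.ndarray
    effects: dict[int, float]
    dominance: dict[int, float]
    episode_schedule: dict | None = None

    def __post_init__(self) -> None:
        sets = [set(np.asarray(s).tolist()) for s in
                (self.loci_shared, self.loci_ambient, self.loci_lowph)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("selected locus classes must be disjoint")
        all_loci = sets[0] | sets[1] | sets[2]
        missing = all_loci - set(self.effects) | all_loci - set(self.dominance)
        if missing:
            raise ValueError(f"effects/dominance missing for loci {sorted(missing)[:5]}")

    def active_loci(self, environment: str) -> np.ndarray:
        env_loci = {"ambient": self.loci_ambient, "low_pH": self.loci_lowph}
        if environment not in env_loci:
            raise ValueError(f"unknown environment {environment!r}")
        return np.concatenate(
            [np.asarray(self.loci_shared, dtype=int), np.asarray(env_loci[environment], dtype=int)]
        )

    def selected_flags(self, environment: str, n_snps: int) -> np.ndarray:
        flags = np.zeros(n_snps, dtype=bool)
        flags[self.active_loci(environment)] = True
        return flags


def neutral_regime() -> SelectionRegime:
    empty = np.array([], dtype=int)
    return SelectionRegime(
        loci_shared=empty, loci_ambient=empty, loci_lowph=empty, effects={}, dominance={}
    )


def fitness_scores(pool: ZygotePool, regime: SelectionRegime, environment: str) -> np.ndarray:
    """Latent additive-with-dominance fitness per individual (no noise)."""
    loci = regime.active_loci(environment)
    if loci.size == 0:
        return np.zeros(pool.n)
    eff = np.array([regime.effects[int(l)] for l in loci])
    dom = np.array([regime.dominance[int(l)] for l in loci])
    g = pool.genotypes[:, loci]
    w = np.where(g == 2, 1.0, np.where(g == 1, dom, 0.0))
    return w @ eff


def apply_selection_episode(
    pool: ZygotePool,
    regime: SelectionRegime,
    environment: str,
    survivors: int,
    drift_fraction: float = 0.0,
    seed: int = 0,
    selection_noise_scale: float = 1.0,
    n_rounds: int = 1,
) -> ZygotePool:
    """One viability-selection episode leaving exactly ``survivors`` alive.

    Within each round, a fraction ``drift_fraction`` of the deaths is
    uniformly random (genotype-independent); the remainder are the
    lowest-ranked individuals by latent fitness + Gumbel(0,
    ``selection_noise_scale``) noise.  Unit noise makes a round equivalent to
    sampling survivors without replacement with probability proportional to
    exp(fitness) — multiplicative viability selection; scale 0 is
    deterministic rank truncation.

    ``n_rounds > 1`` spreads the episode over that many culling rounds with
    geometrically interpolated census targets (continuous mortality, e.g.
    one round per day).  Survival weights multiply across rounds, so the
    cumulative selective pressure per locus is ``n_rounds * effect`` and the
    saturation a single fixed-count cull imposes on per-locus shifts is
    avoided; selection on unlinked loci stays approximately independent.
    """
    if not 0.0 <= drift_fraction <= 1.0:
        raise ValueError("drift_fraction must lie in [0, 1]")
    if survivors > pool.n:
        raise ValueError(f"survivors ({survivors}) exceeds pool size ({pool.n})")
    if survivors < 0:
        raise ValueError("survivors must be >= 0")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    n0 = pool.n
    if survivors == n0:
        return pool
    overall = survivors / n0 if n0 else 0.0
    targets = [int(round(n0 * overall ** (t / n_rounds))) for t in range(1, n_rounds + 1)]
    targets[-1] = survivors
    for target in targets:
        target = min(target, pool.n)
        deaths = pool.n - target
        if deaths <= 0:
            continue
        n_drift = int(round(drift_fraction * deaths))
        alive = rng.permutation(pool.n)[: pool.n - n_drift]
        score = fitness_scores(pool, regime, environment)[alive]
        if selection_noise_scale > 0:
            score = score + rng.gumbel(0.0, selection_noise_scale, size=alive.size)
        order = np.argsort(-score, kind="stable")
        pool = pool.subset(alive[order[:target]])
    return pool


def build_default_regime(
    founders: FounderPanel,
    n_shared_loci: int = 10,
    n_env_loci: int = 2,
    effect: float = -2.0,
    dominance: float = 0.5,
    freq_window: tuple[float, float] = (0.48, 0.60),
    seed: int = 0,
    exclude_contigs: set | None = None,
    snps_per_locus: int = 1,
    shared_effect: float | None = -0.3,
    n_shared_strong: int = 0,
    min_clean_parents: int = 3,
) -> SelectionRegime:
    """Assign selected-locus classes to contigs of the founder panel.

    Candidate contigs are those with at least ``snps_per_locus`` SNPs whose
    founder frequency lies inside ``freq_window`` (mid-range frequencies
    leave room for a large downward shift); each chosen contig contributes
    its ``snps_per_locus`` most window-central SNPs, with a uniform effect
    and dominance.  Contig-level assignment makes the locus-level truth well
    defined for the outlier scan.

    The defaults are deliberately few and strong: total selective mortality
    bounds the summed allele-frequency displacement an episode can produce,
    so a handful of large-effect loci is the regime under which per-locus
    shifts are large enough to be individually detectable at ~100x pooled
    coverage.
    """
    rng = np.random.default_rng(seed)
    contigs = founders.snps["contig"].to_numpy()
    in_window = (founders.founder_afs >= freq_window[0]) & (
        founders.founder_afs <= freq_window[1]
    )
    # a tolerant (homozygous-reference) background must exist on both sides
    # of the cross, otherwise the purge stalls in heterozygous families
    clean_dams = (founders.genotypes[: founders.n_dams] == 0).sum(axis=0)
    clean_sires = (founders.genotypes[founders.n_dams :] == 0).sum(axis=0)
    in_window &= (clean_dams >= min_clean_parents) & (clean_sires >= min_clean_parents)
    center = 0.5 * (freq_window[0] + freq_window[1])
    eligible: dict[str, list[int]] = {}
    for idx in np.flatnonzero(in_window):
        eligible.setdefault(contigs[idx], []).append(int(idx))
    exclude_contigs = exclude_contigs or set()
    candidates = sorted(c for c, snps in eligible.items()
                        if len(snps) >= snps_per_locus and c not in exclude_contigs)
    needed = n_shared_loci + 2 * n_env_loci
    if len(candidates) < needed:
        raise ValueError(
            f"only {len(candidates)} candidate contigs for {needed} selected loci; "
            "increase n_snps or widen freq_window"
        )
    chosen = rng.choice(len(candidates), size=needed, replace=False)
    chosen_contigs = [candidates[i] for i in chosen]
    groups = {
        "shared": chosen_contigs[:n_shared_loci],
        "ambient": chosen_contigs[n_shared_loci : n_shared_loci + n_env_loci],
        "low_pH": chosen_contigs[n_shared_loci + n_env_loci :],
    }

    def pick(contig: str) -> list[int]:
        snps = sorted(
            eligible[contig], key=lambda i: abs(founders.founder_afs[i] - center)
        )
        return snps[:snps_per_locus]

    snp_sets = {k: np.array(sorted(i for c in v for i in pick(c)), dtype=int)
                for k, v in groups.items()}
    if shared_effect is None:
        shared_effect = effect
    strong_shared = {i for c in groups["shared"][:n_shared_strong] for i in pick(c)}
    effects = {
        int(i): float(effect if int(i) in strong_shared else shared_effect)
        for i in snp_sets["shared"]
    }
    effects.update(
        {int(i): float(effect) for k in ("ambient", "low_pH") for i in snp_sets[k]}
    )
    all_snps = np.concatenate(list(snp_sets.values()))
    dom = {int(i): float(dominance) for i in all_snps}
    return SelectionRegime(
        loci_shared=snp_sets["shared"],
        loci_ambient=snp_sets["ambient"],
        loci_lowph=snp_sets["low_pH"],
        effects=effects,
        dominance=dom,
    )


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class GrowthModel:
    """Shell-length model: day baseline x treatment deficit + genetic effects.

    ``loci``/``effects``/``env`` define growth loci with environment labels
    ('shared', 'ambient', 'low_pH'); only loci whose label is 'shared' or
    matches the rearing environment contribute.  Effects are centered at the
    founder mean dosage so the expected genetic contribution is ~0 and the
    configured deficit schedule is expressed in the group means.  Units: µm.
    """

    loci: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    effects: np.ndarray = field(default_factory=lambda: np.array([]))
    env: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    mean_dosage: np.ndarray = field(default_factory=lambda: np.array([]))
    baseline_day0: float = 100.0
    baseline_rate: float = 5.0
    deficit_early: float = 0.08
    deficit_late: float = 0.025
    deficit_break_day: float = 7.0
    deficit_end_day: float = 26.0
    noise_sd: float = 2.5

    def baseline(self, day: float) -> float:
        return self.baseline_day0 + self.baseline_rate * day

    def deficit(self, environment: str, day: float) -> float:
        if environment != "low_pH":
            return 0.0
        if day <= self.deficit_break_day:
            return self.deficit_early
        if day >= self.deficit_end_day:
            return self.deficit_late
        span = self.deficit_end_day - self.deficit_break_day
        frac = (day - self.deficit_break_day) / span
        return self.deficit_early + frac * (self.deficit_late - self.deficit_early)

    def active(self, environment: str) -> np.ndarray:
        return np.flatnonzero((self.env == "shared") | (self.env == environment))


def assign_phenotypes(
    pool: ZygotePool,
    day: float,
    environment: str,
    growth: GrowthModel,
    seed: int = 0,
    treatment_label: str | None = None,
    replicate: str = "r?",
) -> pd.DataFrame:
    """Shell lengths for every individual in the pool on a given day.

    size = baseline(day) * (1 - deficit(environment, day))
           + sum over active growth loci of effect * (dosage - mean_dosage)
           + Normal(0, noise_sd).
    """
    if growth.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = growth.baseline(day) * (1.0 - growth.deficit(environment, day))
    genetic = np.zeros(pool.n)
    act = growth.active(environment)
    if act.size:
        loci = growth.loci[act]
        eff = growth.effects[act]
        centred = pool.genotypes[:, loci] - growth.mean_dosage[act]
        genetic = centred @ eff
    noise = rng.normal(0.0, growth.noise_sd, size=pool.n) if growth.noise_sd > 0 else 0.0
    sizes = base + genetic + noise
    return pd.DataFrame(
        {
            "individual_id": pool.ids,
            "day": day,
            "treatment": treatment_label or environment,
            "replicate": replicate,
            "shell_length": sizes,
        }
    )


def build_default_growth(
    founders: FounderPanel,
    n_shared_contigs: int = 1,
    n_env_contigs: int = 2,
    beta: float = 3.0,
    freq_window: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    exclude_contigs: set | None = None,
    **model_kwargs,
) -> GrowthModel:
    """Growth loci on whole contigs, mirroring :func:`build_default_regime`."""
    rng = np.random.default_rng(seed)
    contigs = founders.snps["contig"].to_numpy()
    in_window = (founders.founder_afs >= freq_window[0]) & (
        founders.founder_afs <= freq_window[1]
    )
    eligible: dict[str, list[int]] = {}
    for idx in np.flatnonzero(in_window):
        eligible.setdefault(contigs[idx], []).append(int(idx))
    exclude_contigs = exclude_contigs or set()
    candidates = sorted(c for c, snps in eligible.items()
                        if len(snps) >= 2 and c not in exclude_contigs)
    needed = n_shared_contigs + 2 * n_env_contigs
    if len(candidates) < needed:
        raise ValueError(f"only {len(candidates)} candidate contigs for {needed} growth loci")
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=needed, replace=False)]
    labels = (
        ["shared"] * n_shared_contigs
        + ["ambient"] * n_env_contigs
        + ["low_pH"] * n_env_contigs
    )
    loci, effs, envs = [], [], []
    for contig, label in zip(chosen, labels):
        for idx in eligible[contig]:
            loci.append(idx)
            effs.append(beta)
            envs.append(label)
    loci = np.array(loci, dtype=int)
    return GrowthModel(
        loci=loci,
        effects=np.array(effs),
        env=np.array(envs, dtype=object),
        mean_dosage=2.0 * founders.founder_afs[loci],
        **model_kwargs,
    )


def truncate_by_size(
    phenos: pd.DataFrame, upper_fraction: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a phenotype table at the (1 - upper_fraction) size quantile.

    Returns (fastest, slowest) growers.  The fastest subset holds
    ``round(upper_fraction * n)`` individuals (clamped so both subsets are
    non-empty); ties are broken by stable ordering of identifiers.
    """
    if not 0.0 < upper_fraction < 1.0:
        raise ValueError("upper_fraction must lie in (0, 1)")
    n = len(phenos)
    if n < 2:
        raise ValueError("need at least two individuals to split by size")
    ordered = phenos.sort_values(
        ["shell_length", "individual_id"], ascending=[False, True], kind="mergesort"
    )
    n_fast = int(round(upper_fraction * n))
    n_fast = min(max(n_fast, 1), n - 1)
    fast = ordered.iloc[:n_fast].reset_index(drop=True)
    slow = ordered.iloc[n_fast:].reset_index(drop=True)
    return fast, slow


# ---------------------------------------------------------------------------
# sequencing


@dataclass
class SeqNoiseModel:
    """Pooled-sequencing noise: per-SNP coverage law + binomial read draws.

    ``dispersion`` is the per-sample negative-binomial size parameter k
    (variance mean + mean^2/k); ``distribution="fixed"`` uses exact
    ``mean_coverage`` at every SNP, for tests that need deterministic depth.
    Locus-to-locus capture-efficiency variation, which is shared across all
    samples of an experiment (a poorly captured SNP is shallow everywhere),
    enters through the ``mean_scale`` argument of the draw.
    """

    mean_coverage: float = 100.0
    dispersion: float = 200.0
    distribution: str = "negative_binomial"

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.distribution not in ("negative_binomial", "fixed"):
            raise ValueError("distribution must be 'negative_binomial' or 'fixed'")
        if self.distribution == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def draw_coverage(
        self, n: int, rng: np.random.Generator, mean_scale: np.ndarray | None = None
    ) -> np.ndarray:
        if self.distribution == "fixed":
            return np.full(n, int(round(self.mean_coverage)), dtype=np.int64)
        k = self.dispersion
        mean = self.mean_coverage * (np.ones(n) if mean_scale is None else mean_scale)
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=n).astype(np.int64)


def sequence_frequencies(
    true_freq: np.ndarray,
    noise: SeqNoiseModel,
    seed: int = 0,
    mean_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ref_depth, alt_depth) at each SNP given true pool frequencies.

    Coverage follows the configured count law, optionally scaled per SNP by
    ``mean_scale`` (capture efficiency); alternate reads are binomial at the
    true frequency, i.e. reads sample gene copies with replacement.
    """
    freq = np.asarray(true_freq, dtype=float)
    if freq.ndim != 1:
        raise ValueError("true_freq must be 1-D")
    if np.any((freq < 0) | (freq > 1)):
        raise ValueError("true frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    coverage = noise.draw_coverage(freq.size, rng, mean_scale=mean_scale)
    alt = rng.binomial(coverage, freq)
    return coverage - alt, alt


def sequence_pool(pool: ZygotePool, noise: SeqNoiseModel, seed: int = 0):
    """Sequence a pooled sample of individuals (wrapper over true frequencies)."""
    if pool.n == 0:
        raise ValueError("cannot sequence an empty pool")
    return sequence_frequencies(pool.allele_frequency(), noise, seed=seed)


def island_model_pools(
    n_snps: int = 10_000,
    fst: float = 0.10,
    n_individuals: int = 50,
    noise: SeqNoiseModel | None = None,
    seed: int = 0,
    ancestral_low: float = 0.1,
    ancestral_high: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-population island-model pools with known differentiation.

    Ancestral frequencies are uniform on [ancestral_low, ancestral_high];
    each subpopulation frequency is a Beta draw with mean p and variance
    p(1-p)*fst; a pool of ``n_individuals`` diploids is binomially sampled
    from each subpopulation and sequenced.  Returns (ref_a, alt_a, ref_b,
    alt_b) read counts — a known-parameter fixture for validating the
    pooled F_ST estimator by recovery rather than by matching another
    implementation.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    if noise is None:
        noise = SeqNoiseModel(100.0, 200.0)
    rng = np.random.default_rng(seed)
    p = rng.uniform(ancestral_low, ancestral_high, size=n_snps)
    # Beta with mean p and variance p(1-p)F  =>  shape sum nu = 1/F - 1
    nu = 1.0 / fst - 1.0
    counts = []
    copies = 2 * n_individuals
    for _ in range(2):
        sub = rng.beta(p * nu, (1.0 - p) * nu)
        pool_freq = rng.binomial(copies, sub) / copies
        ref, alt = sequence_frequencies(pool_freq, noise, seed=rng.integers(2**31))
        counts.extend([ref, alt])
    return tuple(counts)


# ---------------------------------------------------------------------------
# the full experiment


@dataclass
class ExperimentConfig:
    """Full design specification with defaults matching the study layout.

    ``census_fractions`` give survivors on each sampling day as a fraction of
    the day-0 seeding count, per treatment; the day-26 values encode the
    observed ~97.7% / 97.6% cumulative mortality.  The day-6 census is not
    pinned by observation (only a 10,000-40,000 plausible range at the
    100,000 scale); the default uses the bottom of that range, consistent
    with the single intense early selection event the F_ST trajectory
    implies.
    """

    n_dams: int = 12
    n_sires: int = 16
    n_snps: int = 10_000
    snps_per_contig: int = 3
    n_offspring: int = 100_000
    af_distribution: dict = field(
        default_factory=lambda: {"kind": "uniform", "low": 0.1, "high": 0.9}
    )
    treatments: tuple[str, ...] = ("ambient", "low_pH")
    n_replicates: int = 6
    sampling_days: tuple[int, ...] = (6, 26, 43)
    census_fractions: dict = field(
        default_factory=lambda: {
            "ambient": {6: 0.06, 26: 0.0231933, 43: 0.0025},
            "low_pH": {6: 0.06, 26: 0.0237467, 43: 0.0025},
        }
    )
    # per-episode death composition and intensity: selective mortality is
    # front-loaded before day 6; later episodes are dominated by random
    # (drift) deaths, consistent with differentiation accruing mostly early
    episode_drift_fraction: dict = field(
        default_factory=lambda: {6: 0.05, 26: 1.0, 43: 1.0}
    )
    # one culling round per elapsed day within the selective episode
    episode_rounds: dict = field(default_factory=lambda: {6: 6, 26: 1, 43: 1})
    selection_noise_scale: float = 1.0
    # viability regime (None -> neutral)
    with_selection: bool = True
    n_shared_loci: int = 10
    n_env_loci: int = 2
    selection_effect: float = -2.0  # per culling round (per day pre-day-6)
    selection_shared_effect: float = -0.3  # weak, numerous load loci
    selection_dominance: float = 0.5
    selection_freq_window: tuple[float, float] = (0.48, 0.60)
    selection_snps_per_locus: int = 1
    n_shared_strong: int = 0  # optionally promote shared loci to env strength
    capture_efficiency_shape: float | None = 100.0  # gamma shape; None = uniform capture
    # growth loci
    with_growth_loci: bool = True
    n_shared_growth: int = 1
    n_env_growth: int = 2
    growth_beta: float = 3.0
    growth_freq_window: tuple[float, float] = (0.3, 0.7)
    noise_sd: float = 3.0
    # day-6 size split
    upper_fraction: dict = field(default_factory=lambda: {"ambient": 0.18, "low_pH": 0.21})
    # sequencing
    pool_noise: SeqNoiseModel = field(default_factory=lambda: SeqNoiseModel(100.0, 200.0))
    founder_noise: SeqNoiseModel = field(default_factory=lambda: SeqNoiseModel(40.0, 200.0))
    # phenotype sampling
    pheno_days: tuple[int, ...] = (3, 7, 14, 26)
    pheno_sample_n: int = 60

    def census(self, treatment: str, day: int) -> int:
        frac = self.census_fractions[treatment][day]
        return int(round(frac * self.n_offspring))

    def validate(self) -> None:
        if self.n_offspring < 1 or self.n_snps < 1:
            raise ValueError("n_offspring and n_snps must be >= 1")
        for tr in self.treatments:
            if tr not in self.census_fractions:
                raise ValueError(f"census_fractions missing treatment {tr!r}")
            counts = [self.census(tr, d) for d in self.sampling_days]
            if any(b > a for a, b in zip(counts, counts[1:])):
                raise ValueError(f"survivor counts must be non-increasing for {tr!r}")
            if counts[0] > self.n_offspring:
                raise ValueError("day-6 census exceeds seeding count")
        if self.n_replicates < 6:
            raise ValueError("the design needs >= 6 replicates per treatment")


@dataclass
class SimTruth:
    """Ground truth retained from a simulated experiment."""

    true_pool_freq: dict[str, np.ndarray]        # sample_id -> alt frequency per SNP
    census: pd.DataFrame                         # treatment, replicate, day, count
    selected_flags: dict[str, np.ndarray]        # environment -> bool per SNP
    selected_contigs: dict[str, set]             # class -> contig set
    growth_contigs: dict[str, set]
    regime: SelectionRegime
    growth: GrowthModel
    founders: FounderPanel


@dataclass
class SimResult:
    counts: AlleleCountMatrix
    meta: SampleMeta
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: ExperimentConfig


def _contig_sets(snps: pd.DataFrame, idx_sets: dict[str, np.ndarray]) -> dict[str, set]:
    contigs = snps["contig"].to_numpy()
    return {k: set(contigs[np.asarray(v, dtype=int)].tolist()) if len(v) else set()
            for k, v in idx_sets.items()}


def run_experiment(config: ExperimentConfig, seed: int = 0) -> SimResult:
    """Simulate the full design and emit counts, metadata, phenotypes, truth.

    Sampling topology: the day-0 zygote pool and all 28 founders are
    sequenced; replicates 1-3 of each treatment are destructively sampled on
    day 6 (replicates 1-2 yield fastest/slowest pools after the size split,
    replicate 3 a full-population pool); replicates 4-6 continue to day 26
    (all sequenced) and day 43, where the ambient treatment loses replicate 6
    to protocol optimization (2 sequenced pools vs 3 in low pH).
    """
    config.validate()
    ss = np.random.SeedSequence(seed)

    def next_seed() -> np.random.SeedSequence:
        # stages consume child seeds in a fixed execution order
        return ss.spawn(1)[0]

    founders = make_founders(
        n_dams=config.n_dams,
        n_sires=config.n_sires,
        n_snps=config.n_snps,
        af_distribution=config.af_distribution,
        seed=next_seed(),
        snps_per_contig=config.snps_per_contig,
    )
    n_snps = founders.n_snps

    if config.with_selection:
        regime = build_default_regime(
            founders,
            n_shared_loci=config.n_shared_loci,
            n_env_loci=config.n_env_loci,
            effect=config.selection_effect,
            dominance=config.selection_dominance,
            freq_window=config.selection_freq_window,
            seed=next_seed(),
            snps_per_locus=config.selection_snps_per_locus,
            shared_effect=config.selection_shared_effect,
            n_shared_strong=config.n_shared_strong,
        )
    else:
        regime = neutral_regime()
    sel_contigs = _contig_sets(
        founders.snps,
        {
            "shared": regime.loci_shared,
            "ambient": regime.loci_ambient,
            "low_pH": regime.loci_lowph,
        },
    )
    exclude = sel_contigs["shared"] | sel_contigs["ambient"] | sel_contigs["low_pH"]
    if config.with_growth_loci:
        growth = build_default_growth(
            founders,
            n_shared_contigs=config.n_shared_growth,
            n_env_contigs=config.n_env_growth,
            beta=config.growth_beta,
            freq_window=config.growth_freq_window,
            seed=next_seed(),
            exclude_contigs=exclude,
            noise_sd=config.noise_sd,
        )
    else:
        growth = GrowthModel(noise_sd=config.noise_sd)
    growth_contigs = _contig_sets(
        founders.snps,
        {
            lab: growth.loci[growth.env == lab]
            for lab in ("shared", "ambient", "low_pH")
        },
    )

    if config.capture_efficiency_shape:
        eff_rng = np.random.default_rng(next_seed())
        shape = config.capture_efficiency_shape
        capture_eff = eff_rng.gamma(shape, 1.0 / shape, size=n_snps)
    else:
        capture_eff = None

    sample_ids: list[str] = []
    ref_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    true_freq: dict[str, np.ndarray] = {}
    census_rows: list[dict] = []
    pheno_frames: list[pd.DataFrame] = []

    def add_sample(sid, day, treatment, replicate, size_class, pool, noise):
        freq = pool.allele_frequency() if isinstance(pool, ZygotePool) else pool
        ref, alt = sequence_frequencies(freq, noise, seed=next_seed(), mean_scale=capture_eff)
        sample_ids.append(sid)
        ref_cols.append(ref)
        alt_cols.append(alt)
        n_ind = pool.n if isinstance(pool, ZygotePool) else 1
        meta_rows.append(
            {
                "sample_id": sid,
                "day": day,
                "treatment": treatment,
                "replicate": replicate,
                "size_class": size_class,
                "pool_min": n_ind,
                "pool_max": n_ind,
            }
        )
        true_freq[sid] = freq

    # founders, sequenced individually at founder coverage
    for i in range(founders.n_founders):
        kind = "D" if i < config.n_dams else "S"
        num = i + 1 if i < config.n_dams else i - config.n_dams + 1
        sid = f"founder_{kind}{num:02d}"
        add_sample(
            sid, 0, "founder", sid, "none",
            founders.genotypes[i].astype(float) / 2.0, config.founder_noise,
        )

    # day-0 zygote pool
    day0 = make_zygote_pool(founders, config.n_offspring, seed=next_seed())
    add_sample("d0_pool", 0, "day0", "pool", "all", day0, config.pool_noise)
    del day0

    for treatment in config.treatments:
        for rep in range(1, config.n_replicates + 1):
            rep_label = f"r{rep}"
            pool = make_zygote_pool(founders, config.n_offspring, seed=next_seed())
            census_rows.append(
                {"treatment": treatment, "replicate": rep_label, "day": 0, "count": pool.n}
            )
            destructive = rep <= 3
            if not destructive and 3 in config.pheno_days:
                ph3 = assign_phenotypes(
                    pool, 3, treatment, growth, seed=next_seed(), replicate=rep_label
                )
                pheno_frames.append(ph3.sample(
                    n=min(config.pheno_sample_n, len(ph3)),
                    random_state=int(next_seed().generate_state(1)[0] % 2**31),
                ))

            pool = apply_selection_episode(
                pool, regime, treatment,
                survivors=config.census(treatment, 6),
                drift_fraction=config.episode_drift_fraction[6],
                seed=next_seed(),
                selection_noise_scale=config.selection_noise_scale,
                n_rounds=config.episode_rounds[6],
            )
            census_rows.append(
                {"treatment": treatment, "replicate": rep_label, "day": 6, "count": pool.n}
            )

            if destructive:
                ph6 = assign_phenotypes(
                    pool, 6, treatment, growth, seed=next_seed(), replicate=rep_label
                )
                pheno_frames.append(ph6.sample(
                    n=min(120, len(ph6)),
                    random_state=int(next_seed().generate_state(1)[0] % 2**31),
                ))
                if rep <= 2:
                    fast, slow = truncate_by_size(ph6, config.upper_fraction[treatment])
                    id_pos = {int(i): k for k, i in enumerate(pool.ids)}
                    fast_pool = pool.subset(
                        np.array([id_pos[int(i)] for i in fast["individual_id"]])
                    )
                    slow_pool = pool.subset(
                        np.array([id_pos[int(i)] for i in slow["individual_id"]])
                    )
                    add_sample(
                        f"d6_{treatment}_{rep_label}_fast", 6, treatment, rep_label,
                        "fastest", fast_pool, config.pool_noise,
                    )
                    add_sample(
                        f"d6_{treatment}_{rep_label}_slow", 6, treatment, rep_label,
                        "slowest", slow_pool, config.pool_noise,
                    )
                else:
                    add_sample(
                        f"d6_{treatment}_{rep_label}_all", 6, treatment, rep_label,
                        "all", pool, config.pool_noise,
                    )
                continue

            for day in (7, 14):
                if day in config.pheno_days:
                    ph = assign_phenotypes(
                        pool, day, treatment, growth, seed=next_seed(), replicate=rep_label
                    )
                    pheno_frames.append(ph.sample(
                        n=min(config.pheno_sample_n, len(ph)),
                        random_state=int(next_seed().generate_state(1)[0] % 2**31),
                    ))

            pool = apply_selection_episode(
                pool, regime, treatment,
                survivors=config.census(treatment, 26),
                drift_fraction=config.episode_drift_fraction[26],
                seed=next_seed(),
                selection_noise_scale=config.selection_noise_scale,
                n_rounds=config.episode_rounds[26],
            )
            census_rows.append(
                {"treatment": treatment, "replicate": rep_label, "day": 26, "count": pool.n}
            )
            if 26 in config.pheno_days:
                ph26 = assign_phenotypes(
                    pool, 26, treatment, growth, seed=next_seed(), replicate=rep_label
                )
                pheno_frames.append(ph26.sample(
                    n=min(config.pheno_sample_n, len(ph26)),
                    random_state=int(next_seed().generate_state(1)[0] % 2**31),
                ))
            add_sample(
                f"d26_{treatment}_{rep_label}", 26, treatment, rep_label,
                "all", pool, config.pool_noise,
            )

            pool = apply_selection_episode(
                pool, regime, treatment,
                survivors=config.census(treatment, 43),
                drift_fraction=config.episode_drift_fraction[43],
                seed=next_seed(),
                selection_noise_scale=config.selection_noise_scale,
                n_rounds=config.episode_rounds[43],
            )
            census_rows.append(
                {"treatment": treatment, "replicate": rep_label, "day": 43, "count": pool.n}
            )
            # ambient replicate 6 was sacrificed to optimize settled-larvae sampling
            if not (treatment == "ambient" and rep == 6):
                add_sample(
                    f"d43_{treatment}_{rep_label}", 43, treatment, rep_label,
                    "all", pool, config.pool_noise,
                )
            del pool

    counts = AlleleCountMatrix(
        snps=founders.snps.copy(),
        ref_depth=np.column_stack(ref_cols),
        alt_depth=np.column_stack(alt_cols),
        sample_ids=sample_ids,
    )
    meta = SampleMeta(table=pd.DataFrame(meta_rows))
    phenotypes = (
        pd.concat(pheno_frames, ignore_index=True)
        if pheno_frames
        else pd.DataFrame(columns=["individual_id", "day", "treatment", "replicate", "shell_length"])
    )
    truth = SimTruth(
        true_pool_freq=true_freq,
        census=pd.DataFrame(census_rows),
        selected_flags={
            env: regime.selected_flags(env, n_snps) for env in config.treatments
        },
        selected_contigs=sel_contigs,
        growth_contigs=growth_contigs,
        regime=regime,
        growth=growth,
        founders=founders,
    )
    return SimResult(counts=counts, meta=meta, phenotypes=phenotypes, truth=truth, config=config)


def scaled_config(n_offspring: int = 40_000, n_snps: int = 2_001, **overrides) -> ExperimentConfig:
    """A desk-scale configuration preserving the design's ratios.

    Census fractions, mortality, coverage and the sampling topology are kept
    at their defaults; only the seeding count and SNP panel shrink, so the
    same pipeline runs in seconds instead of minutes.
    """
    return replace(ExperimentConfig(), n_offspring=n_offspring, n_snps=n_snps, **overrides)
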