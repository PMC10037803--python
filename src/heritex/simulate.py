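"""Synthetic fixture generator with known ground truth.

Emulates the statistical structure of a replicated RNA-seq diversity panel
of inbred lines drawn from two diverged subpopulations: Balding-Nichols
structured genotypes, planted cis/trans regulatory effects with target
heritabilities, genotype-dependent intron splicing counts, planted
selective-sweep windows, and organismal phenotypes driven by planted loci.

Expression is built on the log scale (where variance components are exact)
and exponentiated onto an FPKM-like nonnegative scale; junction/coverage
counts are Poisson given latent rates, matching the PSI ratio definition.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    MARKER_COLUMNS,
    write_gene_models,
    write_vcf,
)


@dataclass
class SimulationConfig:
    """Design of the simulated genotyping panel."""

    n_genotypes: int = 200
    replicates_per_genotype: int = 2
    n_markers: int = 5000
    n_chromosomes: int = 2
    chromosome_length_bp: int = 10_000_000
    subpop_split: tuple[float, ...] = (0.5, 0.5)
    divergence_F: float = 0.1
    maf_floor: float = 0.05
    ld_scale_bp: float = 150_000.0  # e^-1 decay of haplotype correlation; 0 = no LD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genotypes",
            "replicates_per_genotype",
            "n_markers",
            "n_chromosomes",
            "chromosome_length_bp",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.divergence_F < 1.0:
            raise ValueError("divergence_F must be in (0, 1)")
        if abs(sum(self.subpop_split) - 1.0) > 1e-9:
            raise ValueError("subpop_split must sum to 1")
        if self.maf_floor >= 0.5:
            raise ValueError("maf_floor must be < 0.5")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")


@dataclass
class TruthTable:
    """Ground truth planted into a fixture.

    ``planted_cis``: (gene, marker, effect, target_pve) — effect on the log
    scale per alt allele; pve is the fraction of genotype-mean variance.
    ``planted_trans``: (gene, marker, effect).
    ``planted_modules``: (module_id, member_genes, driver_marker).
    ``planted_sweeps``: (chrom, start, end, target allele-frequency gap).
    ``planted_splice_qtl``: (intron, marker, per-allele PSI shift).
    """

    planted_cis: list[tuple[str, str, float, float]] = field(default_factory=list)
    planted_trans: list[tuple[str, str, float]] = field(default_factory=list)
    planted_modules: list[tuple[str, list[str], str]] = field(default_factory=list)
    planted_sweeps: list[tuple[str, int, int, float]] = field(default_factory=list)
    per_gene_target_H2: dict[str, float] = field(default_factory=dict)
    planted_splice_qtl: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g, h2 in self.per_gene_target_H2.items():
            if not 0.0 <= h2 < 1.0:
                raise ValueError(f"target H2 for {g} must be in [0, 1)")

    def validate_against(self, genes: list[str], markers: list[str]) -> None:
        gset, mset = set(genes), set(markers)
        for g, m, *_ in self.planted_cis + self.planted_trans:
            if g not in gset or m not in mset:
                raise ValueError(f"truth references unknown gene/marker ({g}, {m})")
        for _, members, driver in self.planted_modules:
            if driver not in mset or not set(members) <= gset:
                raise ValueError("module truth references unknown gene/marker")
        for intron, m, _ in self.planted_splice_qtl:
            if m not in mset:
                raise ValueError(f"splice QTL references unknown marker {m}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_cis=[tuple(x) for x in d["planted_cis"]],
            planted_trans=[tuple(x) for x in d["planted_trans"]],
            planted_modules=[
                (m, list(genes), drv) for m, genes, drv in d["planted_modules"]
            ],
            planted_sweeps=[tuple(x) for x in d["planted_sweeps"]],
            per_gene_target_H2=d["per_gene_target_H2"],
            planted_splice_qtl=[tuple(x) for x in d["planted_splice_qtl"]],
        )


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Inbred diploid genotypes ({0,2} dosages) under Balding-Nichols structure.

    Per-subpopulation allele frequencies are Beta-distributed around a shared
    ancestral frequency with parameter ``divergence_F``; each inbred line
    contributes a single allele draw (dosage 0 or 2, no heterozygotes).
    Markers whose realized pooled MAF falls below ``maf_floor`` are
    regenerated (a bounded number of rounds), so the floor holds for >= 99%
    of markers.
    """
    rng = np.random.default_rng(config.seed)
    n_pops = len(config.subpop_split)
    pop_sizes = _split_sizes(config.n_genotypes, config.subpop_split)
    labels = np.repeat([f"pop{i+1}" for i in range(n_pops)], pop_sizes)
    geno_ids = [f"G{i:04d}" for i in range(config.n_genotypes)]

    per_chrom = _split_sizes(config.n_markers, [1 / config.n_chromosomes] * config.n_chromosomes)
    rows = []
    for c, n_c in enumerate(per_chrom, start=1):
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chromosome_length_bp + 1), size=n_c, replace=False
            )
        )
        for p in pos:
            rows.append((f"chr{c}_{p}", f"chr{c}", int(p), "A", "T"))
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)

    F = config.divergence_F
    m = config.n_markers
    n = config.n_genotypes

    from scipy.stats import beta as beta_dist, norm

    # Local LD via Gaussian copulas with correlation exp(-d / ld_scale_bp)
    # between neighboring sites (chains reset at chromosome boundaries),
    # applied to three layers: the per-line haplotype field z, the ancestral
    # frequency field u, and the per-subpopulation Balding-Nichols quantile
    # fields v_k. Site marginals are untouched, so allele-frequency
    # structure (and Fst) is exactly Balding-Nichols; nearby sites share
    # both haplotype background and frequency, giving realistic decaying r^2.
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()

    def ar1_field(n_rows: int) -> np.ndarray:
        f = np.empty((n_rows, m))
        f[:, 0] = rng.standard_normal(n_rows)
        for j in range(1, m):
            if config.ld_scale_bp > 0 and chroms[j] == chroms[j - 1]:
                phi = np.exp(-(pos[j] - pos[j - 1]) / config.ld_scale_bp)
            else:
                phi = 0.0
            f[:, j] = phi * f[:, j - 1] + np.sqrt(1 - phi**2) * rng.standard_normal(
                n_rows
            )
        return f

    z = ar1_field(n)
    u = ar1_field(1)[0]
    v = ar1_field(len(pop_sizes))

    # markers failing the MAF floor get their ancestral frequency pulled
    # toward 0.5 and are redrawn on the SAME latent fields, preserving LD
    thresholds = np.empty((len(pop_sizes), m))
    starts = np.cumsum([0] + pop_sizes)
    todo = np.arange(m)
    lo0 = max(0.1, config.maf_floor + 0.02)
    for round_i in range(25):
        lo = min(0.45, lo0 + 0.08 * round_i)
        anc = lo + (1 - 2 * lo) * norm.cdf(u[todo])
        a, b = anc * (1 - F) / F, (1 - anc) * (1 - F) / F
        for k in range(len(pop_sizes)):
            pk = beta_dist.ppf(norm.cdf(v[k, todo]), a, b)
            thresholds[k, todo] = norm.ppf(np.clip(pk, 1e-12, 1 - 1e-12))
        p_pool = np.zeros(todo.size)
        for k, (s0, s1) in enumerate(zip(starts[:-1], starts[1:])):
            p_pool += (z[s0:s1][:, todo] < thresholds[k, todo]).sum(axis=0)
        p_pool /= n
        maf = np.minimum(p_pool, 1 - p_pool)
        still = maf < config.maf_floor
        if not still.any():
            todo = todo[still]
            break
        todo = todo[still]
        u[todo] = 0.7 * u[todo] + 0.3 * rng.standard_normal(todo.size)
    starts = np.cumsum([0] + pop_sizes)
    dosage = np.empty((n, m))
    for k, (s0, s1) in enumerate(zip(starts[:-1], starts[1:])):
        dosage[s0:s1] = 2.0 * (z[s0:s1] < thresholds[k][None, :])
    g = GenotypeMatrix(dosage, geno_ids, markers)
    return g, pd.Series(labels, index=geno_ids, name="subpop")


def _split_sizes(n: int, fracs) -> list[int]:
    sizes = [int(round(f * n)) for f in fracs]
    sizes[-1] = n - sum(sizes[:-1])
    return sizes


def plant_sweep(
    g: GenotypeMatrix,
    labels: pd.Series,
    region: tuple[str, int, int],
    target_gap: float,
    swept_pop: str | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Force a between-subpopulation allele-frequency gap inside ``region``.

    Markers inside the region are resampled so the swept population is near
    fixation (low diversity, as after a selective sweep) and the frequency
    difference to the other population is >= ``target_gap``. Markers outside
    the region are untouched.
    """
    if target_gap == 0:
        return g
    chrom, start, end = region
    rng = np.random.default_rng(seed)
    inside = (
        (g.markers["chrom"] == chrom)
        & (g.markers["pos"] >= start)
        & (g.markers["pos"] <= end)
    ).to_numpy()
    if not inside.any():
        warnings.warn(f"no markers in sweep region {region}; genotypes unchanged")
        return g
    pops = list(pd.unique(labels))
    if len(pops) != 2:
        raise ValueError("plant_sweep requires exactly two subpopulations")
    swept = swept_pop or pops[1]
    other = pops[0] if swept == pops[1] else pops[1]
    lab = labels.loc[g.sample_ids].to_numpy()
    dosage = g.dosage.copy()
    for j in np.where(inside)[0]:
        hi = rng.random() < 0.5
        q_swept = 1.0 if hi else 0.0  # fixation in the swept population
        q_other = np.clip(q_swept - target_gap if hi else q_swept + target_gap, 0, 1)
        q_other = float(np.clip(q_other + rng.normal(0, 0.02), 0, 1))
        if abs(q_swept - q_other) < target_gap:
            q_other = np.clip(q_swept - target_gap if hi else q_swept + target_gap, 0, 1)
        for pop, q in ((swept, q_swept), (other, q_other)):
            idx = lab == pop
            dosage[idx, j] = 2.0 * (rng.random(idx.sum()) < q)
    return GenotypeMatrix(dosage, g.sample_ids, g.markers)


# ---------------------------------------------------------------------------
# Expression


def replicate_plan(
    genotype_ids: list[str], replicates: int
) -> pd.Series:
    """Sample -> genotype map for a balanced replicated design."""
    samples, genos = [], []
    for gid in genotype_ids:
        for r in range(1, replicates + 1):
            samples.append(f"{gid}_r{r}")
            genos.append(gid)
    return pd.Series(genos, index=samples, name="genotype")


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    replicate_map: pd.Series,
    total_log_variance: float = 0.25,
    baseline_log_fpkm: float = 3.0,
    module_variance_share: float = 0.7,
    seed: int = 0,
) -> ExpressionMatrix:
    """Replicated FPKM matrix with planted genetic architecture.

    Per gene, on the log scale: expression = baseline + planted cis/trans
    marker effects + module factor + genotype random effect + replicate
    noise, with the genotype-level variance fraction equal to the gene's
    target H2 and planted-cis variance equal to ``pve`` x genotype-mean
    variance. The log signal is exponentiated onto the FPKM scale.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.per_gene_target_H2)
    truth.validate_against(genes, list(genotypes.markers["id"]))
    geno_ids = genotypes.sample_ids
    n_g = len(geno_ids)
    samples = list(replicate_map.index)
    geno_of_sample = replicate_map.to_numpy()
    geno_pos = {gid: i for i, gid in enumerate(geno_ids)}
    samp_rows = np.array([geno_pos[g] for g in geno_of_sample])
    reps = replicate_map.value_counts()
    r_mean = float(reps.mean())

    V = total_log_variance
    cis_by_gene: dict[str, list[tuple[str, float, float]]] = {}
    for gene, marker, eff, pve in truth.planted_cis:
        cis_by_gene.setdefault(gene, []).append((marker, eff, pve))
    trans_by_gene: dict[str, list[tuple[str, float]]] = {}
    for gene, marker, eff in truth.planted_trans:
        trans_by_gene.setdefault(gene, []).append((marker, eff))
    module_of_gene: dict[str, tuple[int, float]] = {}
    activations = []
    for mi, (_mid, members, driver) in enumerate(truth.planted_modules):
        x = genotypes.column(driver) / 2.0
        act = x + 0.05 * rng.standard_t(3, size=n_g)
        act = (act - act.mean()) / act.std()
        activations.append(act)
        for gene in members:
            module_of_gene[gene] = (mi, 1.0)

    log_expr = np.empty((len(samples), len(genes)))
    for j, gene in enumerate(genes):
        h2 = truth.per_gene_target_H2[gene]
        sigma_g2 = h2 * V
        sigma_e2 = (1.0 - h2) * V
        v_gm = sigma_g2 + sigma_e2 / r_mean  # genotype-mean-scale variance
        signal = np.zeros(n_g)
        used = 0.0
        for marker, eff, pve in cis_by_gene.get(gene, []):
            x = genotypes.column(marker)
            vx = x.var()
            beta = np.sqrt(pve * v_gm / vx) if eff is None else eff
            if eff is None or eff == 0.0:
                beta = np.sqrt(pve * v_gm / vx)
            signal += beta * (x - x.mean())
            used += beta**2 * vx
        for marker, eff in trans_by_gene.get(gene, []):
            x = genotypes.column(marker)
            signal += eff * (x - x.mean())
            used += eff**2 * x.var()
        if gene in module_of_gene:
            mi, _ = module_of_gene[gene]
            avail = max(sigma_g2 - used, 0.0)
            load = np.sqrt(module_variance_share * avail) * rng.choice([-1.0, 1.0])
            signal += load * activations[mi]
            used += load**2
        resid_g = max(sigma_g2 - used, 0.0)
        if sigma_g2 > 0 and used > sigma_g2 * 1.25:
            warnings.warn(
                f"{gene}: planted effects exceed genotype variance budget"
            )
        signal += np.sqrt(resid_g) * rng.standard_normal(n_g)
        mu = baseline_log_fpkm + rng.normal(0, 0.5)
        y = mu + signal[samp_rows] + np.sqrt(sigma_e2) * rng.standard_normal(
            len(samples)
        )
        log_expr[:, j] = y
    fpkm = pd.DataFrame(np.exp(log_expr), index=samples, columns=genes)
    return ExpressionMatrix(fpkm, replicate_map)


# ---------------------------------------------------------------------------
# Splicing


def simulate_splicing_counts(
    genotypes: GenotypeMatrix,
    introns: pd.DataFrame,
    truth: TruthTable,
    replicate_map: pd.Series,
    base_psi_range: tuple[float, float] = (0.2, 0.8),
    mean_coverage: float = 20.0,
    zero_expression_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample junction counts and intronic coverage sums.

    ``introns`` needs columns intron_id/gene_id/chrom/start/end (1-based
    inclusive). Coverage sums are Poisson(rate x size) and junction counts
    Poisson(psi_target x rate), so expected PSI = ucount/(depth/size) equals
    the genotype-dependent target. Planted splice QTLs shift the PSI target
    by the stated amount per alt allele.

    Returns (ucount, depth) DataFrames, samples x introns.
    """
    rng = np.random.default_rng(seed)
    sizes = (introns["end"] - introns["start"] + 1).to_numpy()
    if (sizes < 1).any():
        raise ValueError("intron sizes must be >= 1")
    samples = list(replicate_map.index)
    geno_pos = {gid: i for i, gid in enumerate(genotypes.sample_ids)}
    samp_rows = np.array([geno_pos[g] for g in replicate_map.to_numpy()])
    n_s, n_i = len(samples), len(introns)
    sqtl = {intron: (marker, shift) for intron, marker, shift in truth.planted_splice_qtl}

    ucount = np.zeros((n_s, n_i), dtype=int)
    depth = np.zeros((n_s, n_i), dtype=int)
    base = rng.uniform(*base_psi_range, size=n_i)
    for j, intron in enumerate(introns["intron_id"]):
        psi = np.full(n_s, base[j])
        if intron in sqtl:
            marker, shift = sqtl[intron]
            if base[j] + 2 * min(shift, 0) < 0 and base[j] + 2 * shift < 0:
                raise ValueError(f"{intron}: negative target PSI")
            psi = base[j] + shift * genotypes.column(marker)[samp_rows]
            if (psi < 0).any():
                raise ValueError(f"{intron}: negative target PSI")
        rate = rng.gamma(4.0, mean_coverage / 4.0, size=n_s)
        if zero_expression_frac > 0:
            rate[rng.random(n_s) < zero_expression_frac] = 0.0
        depth[:, j] = rng.poisson(rate * sizes[j])
        ucount[:, j] = rng.poisson(psi * rate)
    ids = list(introns["intron_id"])
    return (
        pd.DataFrame(ucount, index=samples, columns=ids),
        pd.DataFrame(depth, index=samples, columns=ids),
    )


# ---------------------------------------------------------------------------
# Organismal traits


def simulate_organismal_trait(
    genotypes: GenotypeMatrix,
    effects: list[tuple[str, float]],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Positive-valued phenotype exp(linear predictor + Gaussian noise)."""
    rng = np.random.default_rng(seed)
    lp = np.zeros(genotypes.n_samples)
    for marker, beta in effects:
        x = genotypes.column(marker)
        lp += beta * (x - x.mean())
    trait = np.exp(lp + rng.normal(0, noise_sd, size=genotypes.n_samples))
    return pd.Series(trait, index=genotypes.sample_ids, name="trait")


# ---------------------------------------------------------------------------
# GO annotations


def simulate_go_annotations(
    genes: list[str],
    n_terms: int = 40,
    term_size_range: tuple[int, int] = (25, 120),
    planted_terms: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> GO-term table, with optional planted term memberships."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(*term_size_range))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        term = f"GO:{7000000 + t}"
        rows += [(g, term) for g in members]
    for term, members in (planted_terms or {}).items():
        rows += [(g, term) for g in members]
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates()


# ---------------------------------------------------------------------------
# Gene models / introns for fixtures


def tile_gene_models(
    config: SimulationConfig, n_genes: int, gene_length: int = 5000
) -> list[GeneModel]:
    """Evenly tiled gene models across the simulated chromosomes."""
    per_chrom = _split_sizes(n_genes, [1 / config.n_chromosomes] * config.n_chromosomes)
    genes = []
    i = 0
    for c, n_c in enumerate(per_chrom, start=1):
        spacing = config.chromosome_length_bp // (n_c + 1)
        for k in range(n_c):
            start = (k + 1) * spacing
            genes.append(
                GeneModel(
                    f"gene{i:05d}",
                    f"chr{c}",
                    start,
                    start + gene_length - 1,
                    "+" if i % 2 == 0 else "-",
                )
            )
            i += 1
    return genes


def tile_introns(
    genes: list[GeneModel], n_introns: int, intron_size: int = 500
) -> pd.DataFrame:
    """One intron inside each of the first ``n_introns`` gene models."""
    rows = []
    for g in genes[:n_introns]:
        start = g.start + 100
        rows.append(
            (f"intron_{g.gene_id}", g.gene_id, g.chrom, start, start + intron_size - 1)
        )
    return pd.DataFrame(
        rows, columns=["intron_id", "gene_id", "chrom", "start", "end"]
    )


# ---------------------------------------------------------------------------
# Full fixture


@dataclass
class FixtureSet:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    labels: pd.Series
    expression: ExpressionMatrix
    gene_models: list[GeneModel]
    introns: pd.DataFrame
    ucount: pd.DataFrame
    depth: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: TruthTable
    go_annotations: pd.DataFrame


def _nearest_marker(markers: pd.DataFrame, chrom: str, pos: int) -> str:
    sub = markers[markers["chrom"] == chrom]
    j = (sub["pos"] - pos).abs().idxmin()
    return str(markers.loc[j, "id"])


def build_default_fixture(
    seed: int = 0,
    config: SimulationConfig | None = None,
    n_genes: int = 2000,
    n_introns: int = 500,
    n_cis: int = 40,
    n_trans: int = 10,
    n_modules: int = 3,
    module_size: int = 40,
    n_sqtl: int = 30,
    cis_pve: float = 0.4,
    cis_h2: float = 0.6,
    sqtl_shift: float = 0.15,
    sweep_gap: float = 0.9,
    sweep_width: int = 100_000,
) -> FixtureSet:
    """The default 'small' study fixture: 200 genotypes x 2 replicates,
    5,000 markers on 2 chromosomes, 2,000 genes, 500 introns, with planted
    cis/trans eQTLs, splice QTLs, 3 co-expression modules, one sweep window
    per chromosome and two planted phenotypes."""
    cfg = config or SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed + 1)
    geno, labels = simulate_genotypes(cfg)
    genes = tile_gene_models(cfg, n_genes)
    gene_ids = [g.gene_id for g in genes]
    markers = geno.markers

    h2 = {gid: float(rng.uniform(0.1, 0.8)) for gid in gene_ids}
    pick = rng.choice(n_genes, size=n_cis + n_trans + n_modules * module_size, replace=False)
    cis_genes = [gene_ids[i] for i in pick[:n_cis]]
    trans_genes = [gene_ids[i] for i in pick[n_cis : n_cis + n_trans]]
    module_genes = [gene_ids[i] for i in pick[n_cis + n_trans :]]

    planted_cis = []
    gmodel = {g.gene_id: g for g in genes}
    for gid in cis_genes:
        g = gmodel[gid]
        planted_cis.append((gid, _nearest_marker(markers, g.chrom, g.start), 0.0, cis_pve))
        h2[gid] = cis_h2
    planted_trans = []
    for gid in trans_genes:
        g = gmodel[gid]
        other = markers[markers["chrom"] != g.chrom].sample(1, random_state=int(rng.integers(2**31)))
        planted_trans.append((gid, str(other["id"].iloc[0]), 0.25))
        h2[gid] = cis_h2

    # one sweep window per chromosome, clear of the first Mb; regions chosen
    # up front so planted module drivers can avoid them (sweep resampling
    # would destroy a driver's frequency)
    planted_sweeps = []
    for c in range(1, cfg.n_chromosomes + 1):
        start = int(rng.integers(2_000_000, cfg.chromosome_length_bp - 2_000_000))
        planted_sweeps.append((f"chr{c}", start, start + sweep_width, sweep_gap))
    in_sweep = np.zeros(len(markers), dtype=bool)
    for chrom, start, end, _ in planted_sweeps:
        in_sweep |= (
            (markers["chrom"] == chrom)
            & (markers["pos"] >= start)
            & (markers["pos"] <= end)
        ).to_numpy()

    # heavy-tailed modules need low-frequency driver markers: a standardized
    # Bernoulli(p) activation has kurtosis (1-6pq)/pq + 3, > 6 only for
    # p below ~0.10
    p = geno.allele_freq()
    rare_mask = (p > 0.05) & (p < 0.09) & ~in_sweep
    rare = markers.loc[rare_mask, ["id", "chrom", "pos"]].reset_index(drop=True)
    # distinct modules need distinct drivers: enforce pairwise distance well
    # beyond the LD decay scale so driver activations stay independent
    order = rng.permutation(len(rare))
    picked: list[int] = []
    min_sep = 4 * cfg.ld_scale_bp
    while min_sep >= 1:
        picked = []
        for i in order:
            row = rare.iloc[i]
            if all(
                rare.iloc[j]["chrom"] != row["chrom"]
                or abs(int(rare.iloc[j]["pos"]) - int(row["pos"])) >= min_sep
                for j in picked
            ):
                picked.append(i)
            if len(picked) == n_modules:
                break
        if len(picked) == n_modules:
            break
        min_sep //= 2
    if len(picked) < n_modules:
        raise ValueError("not enough low-frequency driver markers for modules")
    planted_modules = []
    for mi in range(n_modules):
        members = module_genes[mi * module_size : (mi + 1) * module_size]
        driver = str(rare.iloc[picked[mi]]["id"])
        planted_modules.append((f"module{mi+1}", members, driver))
        for gid in members:
            h2[gid] = max(h2[gid], 0.5)

    introns = tile_introns(genes, n_introns)
    # prefer introns of genes that also carry a planted cis-eQTL, so the
    # fixture guarantees genes with both signals for colocalization
    cis_set = set(cis_genes)
    in_cis = [i for i in range(len(introns)) if introns["gene_id"].iloc[i] in cis_set]
    others = [i for i in range(len(introns)) if introns["gene_id"].iloc[i] not in cis_set]
    rng.shuffle(in_cis)
    rng.shuffle(others)
    sq_pick = (in_cis + others)[:n_sqtl]
    planted_sqtl = []
    for i in sq_pick:
        row = introns.iloc[i]
        planted_sqtl.append(
            (str(row["intron_id"]), _nearest_marker(markers, row["chrom"], int(row["start"])), sqtl_shift)
        )

    truth = TruthTable(
        planted_cis=planted_cis,
        planted_trans=planted_trans,
        planted_modules=planted_modules,
        planted_sweeps=planted_sweeps,
        per_gene_target_H2=h2,
        planted_splice_qtl=planted_sqtl,
    )

    for chrom, start, end, gap in planted_sweeps:
        geno = plant_sweep(geno, labels, (chrom, start, end), gap, seed=seed + 7)

    rmap = replicate_plan(geno.sample_ids, cfg.replicates_per_genotype)
    expr = simulate_expression(geno, truth, rmap, seed=seed + 2)
    ucount, depth = simulate_splicing_counts(geno, introns, truth, rmap, seed=seed + 3)

    # two phenotypes: one driven through a planted cis gene's marker, one null
    driven_marker = planted_cis[0][1]
    ph1 = simulate_organismal_trait(geno, [(driven_marker, 0.5)], seed=seed + 4)
    ph0 = simulate_organismal_trait(geno, [], seed=seed + 5)
    phenotypes = pd.DataFrame({"trait_driven": ph1, "trait_null": ph0})

    planted_term_genes = {"GO:1000001": planted_modules[0][1]} if planted_modules else None
    go = simulate_go_annotations(gene_ids, planted_terms=planted_term_genes, seed=seed + 6)

    return FixtureSet(
        cfg, geno, labels, expr, genes, introns, ucount, depth, phenotypes, truth, go
    )


def write_fixture_set(fx: FixtureSet, directory: str | Path) -> dict[str, Path]:
    """Write a fixture as VCF / TSV / BED / JSON files that round-trip
    losslessly through the core readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": d / "genotypes.vcf",
        "labels": d / "subpop_labels.tsv",
        "expression": d / "expression_fpkm.tsv",
        "replicate_map": d / "replicate_map.tsv",
        "genes": d / "gene_models.bed",
        "introns": d / "introns.tsv",
        "ucount": d / "splice_ucount.tsv",
        "depth": d / "splice_depth.tsv",
        "phenotypes": d / "phenotypes.tsv",
        "sweeps": d / "planted_sweeps.bed",
        "truth": d / "truth.json",
        "go": d / "go_annotations.tsv",
    }
    try:
        write_vcf(fx.genotypes, paths["vcf"])
        fx.labels.to_csv(paths["labels"], sep="\t")
        fx.expression.fpkm.to_csv(paths["expression"], sep="\t")
        fx.expression.replicate_map.to_csv(paths["replicate_map"], sep="\t")
        write_gene_models(fx.gene_models, paths["genes"])
        fx.introns.to_csv(paths["introns"], sep="\t", index=False)
        fx.ucount.to_csv(paths["ucount"], sep="\t")
        fx.depth.to_csv(paths["depth"], sep="\t")
        fx.phenotypes.to_csv(paths["phenotypes"], sep="\t")
        with open(paths["sweeps"], "w") as fh:
            for chrom, start, end, gap in fx.truth.planted_sweeps:
                fh.write(f"{chrom}\t{start - 1}\t{end}\tsweep_gap_{gap}\n")
        fx.truth.to_json(paths["truth"])
        fx.go_annotations.to_csv(paths["go"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {d}: {exc}") from exc
    return paths
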