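"""Shared genomic data model: genotypes, gene models, expression, QC and
population-structure utilities.

Conventions
-----------
* Coordinates are 1-based inclusive internally; BED I/O converts explicitly.
* Dosage is the count of alternate alleles (0/1/2), ``nan`` for missing;
  inbred material is therefore {0, 2}.
* Missing dosages are mean-imputed per marker only inside kinship / PC
  computation; association code works on pairwise-complete observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("heritex")

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


def _as_marker_frame(markers: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    m = markers.loc[:, MARKER_COLUMNS].reset_index(drop=True)
    if m["id"].duplicated().any():
        raise ValueError("marker ids are not unique")
    # sortedness check: stable within chromosome
    for _, grp in m.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("markers are not sorted by (chrom, pos)")
    return m


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker coordinates.

    ``dosage`` is float with values in {0, 1, 2} or ``nan`` (missing).
    """

    dosage: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.markers = _as_marker_frame(self.markers)
        if self.dosage.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def column(self, marker_id: str) -> np.ndarray:
        return self.dosage[:, self.marker_index(marker_id)]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, selector) -> "GenotypeMatrix":
        """Subset by marker ids, integer positions, or a boolean mask."""
        arr = np.asarray(selector)
        if arr.dtype.kind in "USO":
            keep = self.markers["id"].isin(list(selector)).to_numpy()
        elif arr.dtype.kind == "b":
            keep = arr
        else:  # integer positions
            keep = np.zeros(self.n_markers, dtype=bool)
            keep[arr] = True
        return GenotypeMatrix(
            self.dosage[:, keep], self.sample_ids, self.markers.loc[keep]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        order = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(self.dosage[order], list(sample_ids), self.markers)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class ExpressionMatrix:
    """FPKM per sample per gene with a sample -> genotype replicate map."""

    fpkm: pd.DataFrame  # samples x genes
    replicate_map: pd.Series  # index = sample id, value = genotype id

    def __post_init__(self) -> None:
        if not isinstance(self.fpkm, pd.DataFrame):
            raise TypeError("fpkm must be a DataFrame (samples x genes)")
        self.replicate_map = pd.Series(self.replicate_map)
        unmapped = self.fpkm.index.difference(self.replicate_map.index)
        if len(unmapped):
            raise ValueError(f"samples without genotype mapping: {list(unmapped)[:5]}")
        vals = self.fpkm.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("FPKM must be finite and nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def genotype_means(self) -> pd.DataFrame:
        """Average across biological replicates -> genotypes x genes."""
        geno = self.replicate_map.loc[self.fpkm.index]
        return self.fpkm.groupby(geno.to_numpy()).mean()


@dataclass(frozen=True)
class TransformSpec:
    lmbda: float
    shift: float = 0.0


@dataclass
class KinshipMatrix:
    values: pd.DataFrame  # genotype x genotype

    def __post_init__(self) -> None:
        a = self.values.to_numpy()
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        w = np.linalg.eigvalsh(a)
        if w.min() < -1e-6 * max(1.0, abs(w.max())):
            raise ValueError("kinship must be positive semi-definite")


@dataclass
class CovariateSet:
    scores: pd.DataFrame  # samples x k PCs
    explained_variance_ratio: np.ndarray | None = None


# ---------------------------------------------------------------------------
# VCF I/O


def load_genotypes(vcf_path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Dosage = alt-allele count; ``./.`` becomes ``nan``. Multi-allelic
    records are skipped (a single warning reports the count). Sample order
    follows the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(
            gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan))
        )
        dosages.append(d)
        rows.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0])
        )
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, vcf_path)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return GenotypeMatrix(np.array(dosages).T, samples, markers)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF 4.2 with a GT field only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(g.markers["chrom"])
        for c in chroms:
            cmax = int(g.markers.loc[g.markers["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={cmax + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in enumerate(g.markers.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else gt_code[d] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / gene model I/O


def read_gene_models(bed_path: str | Path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open -> 1-based inclusive)."""
    genes = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start0, end0, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            genes.append(GeneModel(name, chrom, start0 + 1, end0, strand))
    return genes


def write_gene_models(genes: Sequence[GeneModel], bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Marker / sample QC


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.05, het_max: float = 0.02
) -> GenotypeMatrix:
    """Drop markers with MAF < ``maf_min`` or heterozygote fraction > ``het_max``.

    Both statistics are computed over non-missing calls.
    """
    nonmiss = ~np.isnan(g.dosage)
    n_called = nonmiss.sum(axis=0)
    maf = g.maf()
    with np.errstate(invalid="ignore"):
        het_frac = np.where(
            n_called > 0, np.nansum(g.dosage == 1.0, axis=0) / n_called, 1.0
        )
    keep = (maf >= maf_min) & (het_frac <= het_max) & (n_called > 0)
    if not keep.any():
        raise ValueError("all markers removed by MAF/het filters")
    return g.subset_markers(keep)


def filter_heterozygous_samples(
    g: GenotypeMatrix, het_sample_max: float = 0.20
) -> GenotypeMatrix:
    """Drop samples whose heterozygous-call fraction exceeds the threshold."""
    nonmiss = ~np.isnan(g.dosage)
    with np.errstate(invalid="ignore"):
        het_frac = np.where(
            nonmiss.sum(axis=1) > 0,
            np.nansum(g.dosage == 1.0, axis=1) / np.maximum(nonmiss.sum(axis=1), 1),
            0.0,
        )
    keep = het_frac <= het_sample_max
    dropped = [s for s, k in zip(g.sample_ids, keep) if not k]
    if dropped:
        logger.info("dropped %d high-heterozygosity samples: %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("all samples removed by heterozygosity filter")
    return GenotypeMatrix(
        g.dosage[keep], [s for s, k in zip(g.sample_ids, keep) if k], g.markers
    )


# ---------------------------------------------------------------------------
# LD


def ld_r2(g: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    x = g.column(marker_a)
    y = g.column(marker_b)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise ValueError("need >= 2 samples with complete data")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance marker in ld_r2; returning nan")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of dosage columns (missing mean-imputed for speed)."""
    x = dos.copy()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / x.shape[0]
    r = c / np.outer(sd, sd)
    return r * r


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.2, window: int = 100, step: int = 50
) -> list[str]:
    """Greedy left-to-right LD pruning within sliding marker windows.

    ``window``/``step`` are marker counts. Within each window a marker is
    kept only if its r^2 with every already-kept marker in the window is
    <= ``r2_max``.
    """
    removed: set[int] = set()
    m = g.n_markers
    for start in range(0, max(m - 1, 1), step):
        stop = min(start + window, m)
        cols = [j for j in range(start, stop) if j not in removed]
        if len(cols) < 2:
            continue
        r2 = _r2_matrix(g.dosage[:, cols])
        kept_local: list[int] = []
        for a, j in enumerate(cols):
            if any(r2[a, b] > r2_max for b in kept_local):
                removed.add(j)
            else:
                kept_local.append(a)
        if stop == m:
            break
    return [g.markers["id"].iloc[j] for j in range(m) if j not in removed]


# ---------------------------------------------------------------------------
# Kinship / PCs


def _impute_center(dos: np.ndarray) -> np.ndarray:
    x = dos.copy()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    return x - x.mean(axis=0)


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden-style centered relationship matrix ZZ'/m.

    Zero-variance markers are skipped; missing dosages are mean-imputed.
    """
    if g.n_markers < 2:
        raise ValueError("need >= 2 markers for kinship")
    z = _impute_center(g.dosage)
    var = z.var(axis=0)
    z = z[:, var > 0]
    k = z @ z.T / z.shape[1]
    return KinshipMatrix(pd.DataFrame(k, index=g.sample_ids, columns=g.sample_ids))


def compute_pcs(
    g: GenotypeMatrix,
    k: int = 5,
    marker_subsample: int | None = None,
    seed: int = 0,
) -> CovariateSet:
    """Top-k principal components of the centered genotype matrix.

    Signs are fixed so each component's largest-magnitude loading is
    positive. ``marker_subsample`` draws a random marker subset first.
    """
    if k >= g.n_samples:
        raise ValueError("k must be < number of samples")
    dos = g.dosage
    if marker_subsample is not None and marker_subsample < g.n_markers:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(g.n_markers, marker_subsample, replace=False))
        dos = dos[:, cols]
    z = _impute_center(dos)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1
    evr = (s**2) / (s**2).sum()
    return CovariateSet(
        pd.DataFrame(
            scores, index=g.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=evr[:k],
    )


# ---------------------------------------------------------------------------
# Trait transformation


def boxcox_transform(values: np.ndarray) -> tuple[np.ndarray, TransformSpec]:
    """Box-Cox transform with profile-ML lambda on a grid [-2, 2] step 0.01.

    A shift of ``-min + 1e-6`` is applied when any value is nonpositive.
    Output is standardized to zero mean / unit variance.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if x.size < 10:
        raise ValueError("need >= 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input cannot be Box-Cox transformed")
    shift = 0.0 if x.min() > 0 else float(-x.min() + 1e-6)
    xs = x + shift
    grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    logx = np.log(xs)
    slog = logx.sum()
    n = x.size

    def loglik(lm: float) -> float:
        y = np.log(xs) if abs(lm) < 1e-12 else (xs**lm - 1.0) / lm
        v = y.var()
        if v <= 0:
            return -np.inf
        return -0.5 * n * np.log(v) + (lm - 1.0) * slog

    lls = np.array([loglik(lm) for lm in grid])
    lmbda = float(grid[np.argmax(lls)])
    y = np.log(xs) if abs(lmbda) < 1e-12 else (xs**lmbda - 1.0) / lmbda
    y = (y - y.mean()) / y.std()
    return y, TransformSpec(lmbda, shift)


def filter_expressed_genes(
    e: ExpressionMatrix, fpkm_min: float = 1.0, frac: float = 0.80
) -> list[str]:
    """Genes with FPKM >= ``fpkm_min`` in at least ceil(frac * n_samples) samples."""
    n = len(e.fpkm)
    required = int(np.ceil(frac * n))
    counts = (e.fpkm >= fpkm_min).sum(axis=0)
    return list(counts.index[counts >= required])
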