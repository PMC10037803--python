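"""Latent co-expression modules by independent component analysis.

Pipeline: select heritable, variable genes; choose the component count
explaining a target variance fraction by SVD; run whitened fixed-point ICA
(logcosh contrast); drop components whose per-sample coefficients are
Gaussian-like (kurtosis filter, two-cluster size rule); call module member
genes from robust-standardized loadings; summarize components per genotype
as BLUPs with a heritability; and test GWAS-peak / module enrichment.

Kurtosis here is the standard fourth standardized moment (Gaussian = 3),
so the default retention cut "kurtosis > 6" demands strong
non-Gaussianity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA
from statsmodels.stats.multitest import multipletests

from .core import CovariateSet, GenotypeMatrix
from .heritability import estimate_h2


@dataclass
class ICADecomposition:
    sources: pd.DataFrame  # genes x components (loadings)
    mixing: pd.DataFrame  # samples x components (coefficients)
    kurtosis: pd.Series  # per component, of the sample coefficients
    retained: pd.Series | None = None
    drop_reason: pd.Series | None = None
    converged: bool = True


def select_ica_genes(
    expression: pd.DataFrame, h2: pd.Series, h2_min: float = 0.05, sd_min: float = 1.0
) -> list[str]:
    """Genes with H2 > ``h2_min`` and cross-sample expression sd > ``sd_min``."""
    missing = [g for g in expression.columns if g not in h2.index]
    if missing:
        raise ValueError(f"H2 missing for {len(missing)} genes")
    sd = expression.std(axis=0)
    keep = [
        g for g in expression.columns if h2.loc[g] > h2_min and sd.loc[g] > sd_min
    ]
    if not keep:
        raise ValueError("no genes pass the ICA selection filters")
    return keep


def n_components_for_variance(matrix: np.ndarray | pd.DataFrame, target: float = 0.80) -> int:
    """Smallest k whose top-k squared singular values reach ``target`` of the total."""
    x = np.asarray(matrix, dtype=float)
    x = x - x.mean(axis=0)
    s = np.linalg.svd(x, compute_uv=False)
    frac = np.cumsum(s**2) / (s**2).sum()
    return int(np.searchsorted(frac, target) + 1)


def run_ica(
    matrix: pd.DataFrame,
    n_components: int,
    max_iter: int = 500,
    nonlinearity: str = "logcosh",
    seed: int = 0,
    standardize: bool = True,
) -> ICADecomposition:
    """Whitened fixed-point ICA of a samples x genes expression matrix.

    Components are sign-fixed so each source's largest-magnitude gene
    loading is positive. Per-component kurtosis is computed on the sample
    coefficients (the mixing matrix columns).
    """
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = x / sd
    rank = np.linalg.matrix_rank(x)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    ica = FastICA(
        n_components=n_components,
        fun=nonlinearity,
        max_iter=max_iter,
        whiten="unit-variance",
        random_state=seed,
    )
    # transform genes x samples so "sources" are gene-loading signatures
    s = ica.fit_transform(x.T)  # genes x components
    a = ica.mixing_  # samples x components
    converged = ica.n_iter_ < max_iter
    for j in range(n_components):
        i = np.argmax(np.abs(s[:, j]))
        if s[i, j] < 0:
            s[:, j] *= -1
            a[:, j] *= -1
    comp_ids = [f"IC{j+1}" for j in range(n_components)]
    sources = pd.DataFrame(s, index=matrix.columns, columns=comp_ids)
    mixing = pd.DataFrame(a, index=matrix.index, columns=comp_ids)
    kurt = pd.Series(
        stats.kurtosis(a, axis=0, fisher=False), index=comp_ids, name="kurtosis"
    )
    return ICADecomposition(sources, mixing, kurt, converged=converged)


def filter_components(
    decomp: ICADecomposition,
    kurtosis_min: float = 6.0,
    cluster_min: int = 10,
    seed: int = 0,
) -> ICADecomposition:
    """Retain components with heavy-tailed, well-populated coefficient splits.

    Per component, 2-means clustering of the per-sample coefficients must
    leave more than ``cluster_min`` samples in each cluster, and the
    coefficient kurtosis must exceed ``kurtosis_min``.
    """
    retained, reason = {}, {}
    for comp in decomp.mixing.columns:
        coef = decomp.mixing[comp].to_numpy().reshape(-1, 1)
        km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(coef)
        sizes = np.bincount(km.labels_, minlength=2)
        if sizes.min() <= cluster_min:
            retained[comp], reason[comp] = False, "cluster_size"
        elif decomp.kurtosis[comp] <= kurtosis_min:
            retained[comp], reason[comp] = False, "kurtosis"
        else:
            retained[comp], reason[comp] = True, ""
    decomp.retained = pd.Series(retained)
    decomp.drop_reason = pd.Series(reason)
    return decomp


def assign_module_membership(
    decomp: ICADecomposition, fdr_max: float = 0.01
) -> dict[str, list[str]]:
    """Module member genes per retained component.

    Loadings are robust-standardized (median / MAD); each gene gets a
    two-sided normal p, BH-adjusted within the component; members are the
    genes with FDR <= ``fdr_max``.
    """
    if decomp.retained is None:
        raise ValueError("run filter_components first")
    modules: dict[str, list[str]] = {}
    for comp in decomp.retained.index[decomp.retained]:
        x = decomp.sources[comp].to_numpy()
        med = np.median(x)
        mad = stats.median_abs_deviation(x, scale="normal")
        if mad == 0:
            raise ValueError(f"{comp}: MAD of loadings is zero")
        z = (x - med) / mad
        p = 2.0 * stats.norm.sf(np.abs(z))
        fdr = multipletests(p, method="fdr_bh")[1]
        modules[comp] = list(decomp.sources.index[fdr <= fdr_max])
    return modules


def blup_ic_coefficients(
    coefficients: pd.Series, replicate_map: pd.Series
) -> tuple[pd.Series, float]:
    """Genotype-level BLUPs of a component's sample coefficients, plus H2.

    Random-intercept model: BLUP_g = mu + shrink_g * (mean_g - mu) with
    shrink_g = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_g). Without
    replication the raw genotype means are returned with H2 = nan.
    """
    groups = replicate_map.loc[coefficients.index]
    means = coefficients.groupby(groups.to_numpy()).mean()
    counts = coefficients.groupby(groups.to_numpy()).size()
    if (counts >= 2).sum() < 2:
        return means, float("nan")
    vc = estimate_h2(coefficients, replicate_map)
    mu = float(coefficients.mean())
    denom = vc.sigma_g2 + vc.sigma_e2 / counts.loc[means.index]
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, vc.sigma_g2 / denom, 0.0)
    blup = mu + shrink * (means - mu)
    return pd.Series(blup, index=means.index), vc.h2


def ic_peak_enrichment(
    module_genes: list[str],
    peak_marker_ids: list[str],
    expression_means: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | pd.DataFrame | None = None,
    relaxed_p: float = 1e-5,
) -> tuple[float, pd.DataFrame]:
    """Fisher test: does a GWAS peak regulate a component's module genes?

    Every peak SNP is tested against all genes at the relaxed threshold to
    define the peak's e-traits, then a 2x2 Fisher exact test of
    (gene in module) x (gene is e-trait of the peak). Significant p
    (<= 0.01 by the pipeline's convention) indicates the peak tends to
    regulate the module.
    """
    if not module_genes:
        raise ValueError("empty module")
    from .association import lm_scan_matrix

    sub = genotypes.subset_markers(
        genotypes.markers["id"].isin(peak_marker_ids).to_numpy()
    )
    _, pv = lm_scan_matrix(expression_means, sub, covariates)
    is_etrait = pd.Series(
        np.nanmin(pv, axis=0) <= relaxed_p, index=expression_means.columns
    )
    in_module = expression_means.columns.isin(module_genes)
    table = pd.crosstab(in_module, is_etrait.to_numpy())
    t = np.zeros((2, 2), dtype=int)
    for i, mi in enumerate([True, False]):
        for j, ei in enumerate([True, False]):
            if mi in table.index and ei in table.columns:
                t[i, j] = table.loc[mi, ei]
    _, p = stats.fisher_exact(t, alternative="greater")
    counts = pd.DataFrame(
        t,
        index=["in_module", "not_in_module"],
        columns=["e_trait", "not_e_trait"],
    )
    return float(p), counts
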