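"""Genome-wide association scans, significance thresholds, peak grouping,
cis/trans classification, PVE and permutation nulls.

Scans for expression and splicing traits run on per-genotype averages
(replicates collapsed upstream); expression traits are Box-Cox transformed
and organismal phenotypes log transformed before scanning. Effect signs
are reported per alternate-allele dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CovariateSet, GeneModel, GenotypeMatrix

logger = logging.getLogger("heritex")

MIN_COMPLETE_OBS = 20


@dataclass
class QTLPeak:
    trait: str
    chrom: str
    start: int
    end: int
    lead_id: str
    lead_pos: int
    lead_p: float
    n_snps: int
    cis_trans: str = ""
    pve: float = float("nan")
    lead_maf: float = float("nan")


@dataclass
class PermutationNull:
    min_p: np.ndarray  # genes x permutations
    quantile: float
    threshold_neglog10: float

    @property
    def threshold_p(self) -> float:
        return 10.0 ** (-self.threshold_neglog10)


def _design(covariates: CovariateSet | pd.DataFrame | None, index) -> np.ndarray:
    """Intercept + covariates design matrix; raises on collinearity."""
    n = len(index)
    if covariates is None:
        return np.ones((n, 1))
    cov = covariates.scores if isinstance(covariates, CovariateSet) else covariates
    c = np.column_stack([np.ones(n), cov.loc[index].to_numpy()])
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("collinear covariates")
    return c


def _residualizer(c: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(c)
    return q


def _residualize(q: np.ndarray, x: np.ndarray) -> np.ndarray:
    return x - q @ (q.T @ x)


def lm_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker OLS of a trait on dosage + covariates.

    Returns a marker-indexed frame with beta / se / p (two-sided t-test on
    the dosage coefficient). Markers with zero dosage variance or fewer
    than 20 complete observations are skipped (nan row). Missing dosages
    are handled with pairwise-complete observations.
    """
    trait = trait.loc[genotypes.sample_ids]
    y = trait.to_numpy(dtype=float)
    c = _design(covariates, genotypes.sample_ids)
    n, p_cov = c.shape
    dos = genotypes.dosage
    beta = np.full(genotypes.n_markers, np.nan)
    se = np.full(genotypes.n_markers, np.nan)
    pval = np.full(genotypes.n_markers, np.nan)

    complete_cols = ~np.isnan(dos).any(axis=0)
    if complete_cols.any():
        q = _residualizer(c)
        yt = _residualize(q, y)
        xt = _residualize(q, dos[:, complete_cols])
        sxx = (xt**2).sum(axis=0)
        ok = sxx > 1e-12
        b = np.where(ok, (xt * yt[:, None]).sum(axis=0) / np.where(ok, sxx, 1.0), np.nan)
        df = n - p_cov - 1
        rss = (yt**2).sum() - b**2 * sxx
        sigma2 = rss / df
        s = np.sqrt(np.where(ok, sigma2 / np.where(ok, sxx, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        idx = np.where(complete_cols)[0]
        beta[idx], se[idx], pval[idx] = b, s, pv
        beta[idx[~ok]] = se[idx[~ok]] = pval[idx[~ok]] = np.nan

    for j in np.where(~complete_cols)[0]:
        x = dos[:, j]
        ok_rows = ~np.isnan(x) & ~np.isnan(y)
        if ok_rows.sum() < MIN_COMPLETE_OBS:
            continue
        xs, ys, cs = x[ok_rows], y[ok_rows], c[ok_rows]
        if xs.std() == 0:
            continue
        design = np.column_stack([cs, xs])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        resid = ys - design @ coef
        df = ok_rows.sum() - design.shape[1]
        sigma2 = (resid**2).sum() / df
        xtx_inv = np.linalg.inv(design.T @ design)
        s = np.sqrt(sigma2 * xtx_inv[-1, -1])
        t = coef[-1] / s
        beta[j], se[j] = coef[-1], s
        pval[j] = 2.0 * stats.t.sf(abs(t), df)

    out = genotypes.markers[["id", "chrom", "pos"]].copy()
    out["beta"], out["se"], out["p"] = beta, se, pval
    return out.set_index("id")


def lm_scan_matrix(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All-traits x all-markers OLS scan (complete data fast path).

    Returns (beta, p), each markers x traits. Requires a complete dosage
    matrix; use :func:`lm_scan` per trait when missingness is present.
    """
    if np.isnan(genotypes.dosage).any():
        raise ValueError("lm_scan_matrix requires complete dosages")
    y = traits.loc[genotypes.sample_ids].to_numpy(dtype=float)
    c = _design(covariates, genotypes.sample_ids)
    n, p_cov = c.shape
    q = _residualizer(c)
    yt = _residualize(q, y)
    xt = _residualize(q, genotypes.dosage)
    sxx = (xt**2).sum(axis=0)
    syy = (yt**2).sum(axis=0)
    sxy = xt.T @ yt  # markers x traits
    ok = sxx > 1e-12
    beta = sxy / np.where(ok, sxx, np.nan)[:, None]
    df = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx[:, None] * syy[None, :])
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        t2 = df * r2 / (1.0 - r2)
    pval = 2.0 * stats.t.sf(np.sqrt(t2), df)
    pval[~ok] = np.nan
    return beta, pval


def lmm_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    kinship,
    covariates: CovariateSet | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-random-effect mixed-model scan (EMMA-style).

    The variance ratio delta = sigma_e^2/sigma_g^2 is estimated once per
    trait under the null by REML on the kinship spectrum; each marker then
    gets a generalized-least-squares Wald test with delta fixed.
    """
    from .core import KinshipMatrix

    k = kinship.values if isinstance(kinship, KinshipMatrix) else pd.DataFrame(
        kinship, index=genotypes.sample_ids, columns=genotypes.sample_ids
    )
    kmat = k.loc[genotypes.sample_ids, genotypes.sample_ids].to_numpy()
    w, u = np.linalg.eigh(kmat)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValueError("kinship is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    y = trait.loc[genotypes.sample_ids].to_numpy(dtype=float)
    c = _design(covariates, genotypes.sample_ids)
    ys = u.T @ y
    cs = u.T @ c
    n, p_cov = c.shape

    def reml_neg2ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = w + delta
        wi = 1.0 / d
        xtx = cs.T @ (cs * wi[:, None])
        xty = cs.T @ (ys * wi)
        bhat = np.linalg.solve(xtx, xty)
        r = ys - cs @ bhat
        q_form = (r**2 * wi).sum()
        df = n - p_cov
        sg2 = q_form / df
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        return (
            df * np.log(sg2)
            + np.log(d).sum()
            + logdet_xtx
            + q_form / sg2
        )

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(reml_neg2ll, bounds=(-12.0, 12.0), method="bounded")
    delta = float(np.exp(res.x))
    wi = 1.0 / (w + delta)

    dos = genotypes.dosage
    m = genotypes.n_markers
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    xs_all = u.T @ np.nan_to_num(dos)
    has_missing = np.isnan(dos).any(axis=0)
    for j in range(m):
        if has_missing[j]:
            continue  # mixed model requires complete rows; scan skips
        xj = xs_all[:, j]
        if dos[:, j].std() == 0:
            continue
        design = np.column_stack([cs, xj])
        xtx = design.T @ (design * wi[:, None])
        xty = design.T @ (ys * wi)
        try:
            coef = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            continue
        r = ys - design @ coef
        df = n - design.shape[1]
        sg2 = (r**2 * wi).sum() / df
        cov_b = sg2 * np.linalg.inv(xtx)
        s = np.sqrt(cov_b[-1, -1])
        t = coef[-1] / s
        beta[j], se[j] = coef[-1], s
        pval[j] = 2.0 * stats.t.sf(abs(t), df)
    out = genotypes.markers[["id", "chrom", "pos"]].copy()
    out["beta"], out["se"], out["p"] = beta, se, pval
    return out.set_index("id")


# ---------------------------------------------------------------------------
# Thresholds


@dataclass(frozen=True)
class Threshold:
    p: float
    neg_log10: float


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> Threshold:
    """Per-test threshold alpha / n_tests, also on the -log10 scale."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    t = alpha / n_tests
    return Threshold(t, float(-np.log10(t)))


def permutation_threshold(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | pd.DataFrame | None = None,
    n_perm: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> PermutationNull:
    """Permutation null for genome-wide scans.

    Each permutation shuffles the genotype sample labels (trait and
    covariate labels stay fixed), reruns the full scan, and records each
    trait's minimum p. The threshold is the ``quantile`` of -log10(min p)
    pooled over traits and permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    mins = np.empty((traits.shape[1], n_perm))
    for b in range(n_perm):
        perm = rng.permutation(n)
        gperm = GenotypeMatrix(
            genotypes.dosage[perm], genotypes.sample_ids, genotypes.markers
        )
        _, pv = lm_scan_matrix(traits, gperm, covariates)
        mins[:, b] = np.nanmin(pv, axis=0)
    pooled = -np.log10(mins.ravel())
    thr = float(np.quantile(pooled, quantile))
    return PermutationNull(mins, quantile, thr)


# ---------------------------------------------------------------------------
# Peaks


def group_peaks(
    significant: pd.DataFrame,
    trait: str = "",
    gap_max: int = 1_000_000,
    min_snps: int = 3,
) -> list[QTLPeak]:
    """Merge consecutive significant markers < ``gap_max`` apart into peaks.

    ``significant`` needs columns chrom/pos/p indexed by marker id. Peaks
    with fewer than ``min_snps`` member SNPs are discarded; the lead is the
    member with minimum p (ties broken toward the smaller position).
    """
    peaks: list[QTLPeak] = []
    if significant.empty:
        return peaks
    df = significant.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) >= gap_max)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            member = grp.iloc[a:b]
            if len(member) < min_snps:
                continue
            lead = member.sort_values(["p", "pos"], kind="mergesort").iloc[0]
            peaks.append(
                QTLPeak(
                    trait=trait,
                    chrom=str(chrom),
                    start=int(member["pos"].min()),
                    end=int(member["pos"].max()),
                    lead_id=str(lead.name),
                    lead_pos=int(lead["pos"]),
                    lead_p=float(lead["p"]),
                    n_snps=int(len(member)),
                )
            )
    return peaks


def classify_cis_trans(
    peaks: list[QTLPeak], gene: GeneModel, window: int = 1_000_000
) -> list[QTLPeak]:
    """Label peaks cis/trans relative to a gene's TSS/TES +- ``window``.

    At most one peak per trait keeps the cis label: when several fall in
    the cis window, only the one with the smallest lead p stays cis and the
    rest are relabeled trans.
    """
    if gene is None:
        raise ValueError("unknown gene for cis/trans classification")
    lo = min(gene.tss, gene.tes) - window
    hi = max(gene.tss, gene.tes) + window
    cis_idx = [
        i
        for i, pk in enumerate(peaks)
        if pk.chrom == gene.chrom and lo <= pk.lead_pos <= hi
    ]
    for i, pk in enumerate(peaks):
        pk.cis_trans = "cis" if i in cis_idx else "trans"
    if len(cis_idx) > 1:
        best = min(cis_idx, key=lambda i: (peaks[i].lead_p, peaks[i].lead_pos))
        for i in cis_idx:
            if i != best:
                peaks[i].cis_trans = "trans"
    return peaks


def compute_pve(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    peaks: list[QTLPeak],
) -> tuple[float, dict[str, float]]:
    """Joint and per-peak variance explained by peak lead SNPs.

    Cumulative PVE is the R^2 of a joint OLS of the (transformed) trait on
    all lead dosages; per-peak PVE is each lead's marginal R^2. In-sample
    values are upwardly biased. Collinear leads are greedily dropped.
    """
    if not peaks:
        raise ValueError("need >= 1 peak")
    y = trait.loc[genotypes.sample_ids].to_numpy(dtype=float)
    y = y - y.mean()
    cols, kept = [], []
    for pk in peaks:
        x = genotypes.column(pk.lead_id)
        x = np.nan_to_num(x - np.nanmean(x))
        trial = np.column_stack(cols + [x]) if cols else x[:, None]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            cols.append(x)
            kept.append(pk)
        else:
            logger.info("dropping collinear lead %s from PVE fit", pk.lead_id)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = (y**2).sum()
    cumulative = float(1.0 - (resid**2).sum() / tss) if tss > 0 else 0.0
    per_peak = {}
    for pk, x in zip(kept, cols):
        b = (x @ y) / (x @ x)
        per_peak[pk.lead_id] = float(b**2 * (x @ x) / tss) if tss > 0 else 0.0
        pk.pve = per_peak[pk.lead_id]
    return cumulative, per_peak


# ---------------------------------------------------------------------------
# Trait mapping driver


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in peaks])


def map_qtl(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | pd.DataFrame | None,
    threshold: float,
    gene_models: dict[str, GeneModel] | None = None,
    gap_max: int = 1_000_000,
    min_snps: int = 3,
    max_peaks: int = 10,
    min_beta: float | None = None,
    compute_pve_per_trait: bool = True,
) -> pd.DataFrame:
    """Full QTL mapping for a matrix of (pre-transformed) traits.

    Runs the linear scan, applies the significance ``threshold`` (p-value
    scale) and optional |beta| >= ``min_beta`` filter (splicing-QTL mode),
    groups significant SNPs into peaks, classifies cis/trans against
    ``gene_models`` when the trait maps to a gene, and drops traits with
    more than ``max_peaks`` peaks. Returns one row per retained peak.
    """
    beta, pval = lm_scan_matrix(traits, genotypes, covariates)
    marker_info = genotypes.markers.set_index("id")[["chrom", "pos"]]
    maf = pd.Series(genotypes.maf(), index=genotypes.markers["id"])
    all_peaks: list[QTLPeak] = []
    excluded: list[str] = []
    for t_idx, trait_name in enumerate(traits.columns):
        pv = pval[:, t_idx]
        bv = beta[:, t_idx]
        sig = (pv <= threshold) & ~np.isnan(pv)
        if min_beta is not None:
            sig &= np.abs(bv) >= min_beta
        if not sig.any():
            continue
        sub = marker_info.iloc[np.where(sig)[0]].copy()
        sub["p"] = pv[sig]
        peaks = group_peaks(sub, trait=str(trait_name), gap_max=gap_max, min_snps=min_snps)
        if not peaks:
            continue
        if len(peaks) > max_peaks:
            excluded.append(str(trait_name))
            continue
        gene = (gene_models or {}).get(str(trait_name))
        if gene is not None:
            peaks = classify_cis_trans(peaks, gene, window=gap_max)
        if compute_pve_per_trait:
            cumulative, _ = compute_pve(traits[trait_name], genotypes, peaks)
        for pk in peaks:
            pk.lead_maf = float(maf.loc[pk.lead_id])
        all_peaks.extend(peaks)
    if excluded:
        logger.info("excluded %d traits with > %d peaks: %s", len(excluded), max_peaks, excluded[:10])
    frame = peaks_to_frame(all_peaks)
    frame.attrs["excluded_traits"] = excluded
    return frame


def candidate_genes_for_trait(
    trait_sig_markers: list[str],
    gene_models: list[GeneModel],
    eqtl_peaks: pd.DataFrame,
    genotypes: GenotypeMatrix,
    dist: int = 50_000,
    ld_min: float = 0.8,
) -> pd.DataFrame:
    """Candidate genes for an organismal trait with evidence classes.

    A gene qualifies by (a) proximity: a trait-associated SNP within
    ``dist`` of the gene span; (b) LD: a SNP in r^2 > ``ld_min`` with a
    trait SNP within ``dist``; or (c) eQTL overlap: the gene's cis-eQTL
    lead SNP is itself trait-associated.
    """
    from .core import _r2_matrix

    sig = set(trait_sig_markers)
    markers = genotypes.markers
    sig_cols = [genotypes.marker_index(m) for m in trait_sig_markers]
    rows = []
    eqtl_lead = {}
    if eqtl_peaks is not None and len(eqtl_peaks):
        cis = eqtl_peaks[eqtl_peaks["cis_trans"] == "cis"]
        eqtl_lead = dict(zip(cis["trait"], cis["lead_id"]))
    for gene in gene_models:
        near = markers[
            (markers["chrom"] == gene.chrom)
            & (markers["pos"] >= gene.start - dist)
            & (markers["pos"] <= gene.end + dist)
        ]
        evidence = None
        if any(m in sig for m in near["id"]):
            evidence = "proximity"
        elif len(near) and sig_cols:
            near_cols = [genotypes.marker_index(m) for m in near["id"]]
            dos = genotypes.dosage[:, near_cols + sig_cols]
            r2 = _r2_matrix(dos)
            block = r2[: len(near_cols), len(near_cols):]
            if np.nanmax(block) > ld_min:
                evidence = "LD"
        lead = eqtl_lead.get(gene.gene_id)
        if lead is not None and lead in sig:
            evidence = "eQTL-overlap"
        if evidence:
            rows.append((gene.gene_id, evidence))
    return pd.DataFrame(rows, columns=["gene", "evidence"])
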