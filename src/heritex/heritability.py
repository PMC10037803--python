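"""Broad-sense heritability of expression and GO-level distribution tests.

H2 = sigma_G^2 / (sigma_G^2 + sigma_E^2) from a one-way random-intercept
model (genotype as random effect) fit by restricted maximum likelihood.
Only replicated genotypes contribute to the fit. For the unbalanced case
the REML criterion is profiled analytically over the residual variance and
optimized over the variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class VarianceComponents:
    gene_id: str
    sigma_g2: float
    sigma_e2: float
    h2: float
    n_genotypes: int
    n_samples: int
    constant: bool = False


def _group_stats(values: np.ndarray, groups: np.ndarray):
    """Per-group n, mean and within-group SS, restricted to groups with n >= 2."""
    df = pd.DataFrame({"y": values, "g": groups})
    agg = df.groupby("g")["y"].agg(["count", "mean", "var"])
    agg = agg[agg["count"] >= 2]
    n_i = agg["count"].to_numpy(dtype=float)
    ybar = agg["mean"].to_numpy()
    ssw = (agg["var"].to_numpy() * (n_i - 1)).sum()
    ssw_i = agg["var"].to_numpy() * (n_i - 1)
    return n_i, ybar, ssw_i, float(ssw)


def _reml_neg2ll(log_gamma: float, n_i: np.ndarray, ybar: np.ndarray, ssw: float):
    gamma = np.exp(log_gamma)
    w = n_i / (1.0 + n_i * gamma)
    mu = (w * ybar).sum() / w.sum()
    q = ssw + (w * (ybar - mu) ** 2).sum()
    n = n_i.sum()
    sigma_e2 = q / (n - 1.0)
    neg2 = (
        (n - 1.0) * np.log(sigma_e2)
        + np.log1p(n_i * gamma).sum()
        + np.log(w.sum())
        + q / sigma_e2
    )
    return neg2, sigma_e2, gamma


def estimate_h2(
    values: np.ndarray | pd.Series,
    replicate_map: pd.Series,
    gene_id: str = "",
) -> VarianceComponents:
    """REML fit of the one-way random-intercept model for one gene.

    ``values`` are expression measurements indexed like ``replicate_map``
    (sample -> genotype). Genotypes with a single replicate are excluded.
    Negative component estimates are clamped to zero.
    """
    if isinstance(values, pd.Series):
        groups = replicate_map.loc[values.index].to_numpy()
        y = values.to_numpy(dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        groups = replicate_map.to_numpy()
    n_i, ybar, _, ssw = _group_stats(y, groups)
    if len(n_i) < 2:
        raise ValueError("need >= 2 genotypes with >= 2 replicates")
    n = int(n_i.sum())
    if np.ptp(y) == 0:
        return VarianceComponents(gene_id, 0.0, 0.0, 0.0, len(n_i), n, constant=True)

    def objective(lg: float) -> float:
        return _reml_neg2ll(lg, n_i, ybar, ssw)[0]

    res = optimize.minimize_scalar(objective, bounds=(-14.0, 14.0), method="bounded")
    neg2, sigma_e2, gamma = _reml_neg2ll(res.x, n_i, ybar, ssw)
    # compare against the boundary gamma -> 0 (no genotype variance)
    neg2_zero, sigma_e2_zero, _ = _reml_neg2ll(-30.0, n_i, ybar, ssw)
    if neg2_zero <= neg2 + 1e-10:
        sigma_g2, sigma_e2 = 0.0, sigma_e2_zero
    else:
        sigma_g2 = gamma * sigma_e2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if (sigma_g2 + sigma_e2) > 0 else 0.0
    return VarianceComponents(gene_id, float(sigma_g2), float(sigma_e2), float(h2), len(n_i), n)


def h2_table(
    expression: pd.DataFrame, replicate_map: pd.Series
) -> pd.DataFrame:
    """estimate_h2 across all genes of a samples x genes matrix."""
    rows = []
    groups = replicate_map.loc[expression.index]
    for gene in expression.columns:
        vc = estimate_h2(expression[gene], groups, gene_id=gene)
        rows.append((gene, vc.sigma_g2, vc.sigma_e2, vc.h2, vc.n_genotypes, vc.n_samples))
    return pd.DataFrame(
        rows, columns=["gene", "sigma_g2", "sigma_e2", "h2", "n_genotypes", "n_samples"]
    ).set_index("gene")


def compare_subpopulation_h2(
    expression: pd.DataFrame,
    replicate_map: pd.Series,
    labels: pd.Series,
    pop_ref: str,
    pop_alt: str,
    reduction_fraction: float = 0.80,
    secondary_reduction: float = 0.20,
) -> pd.DataFrame:
    """Per-gene H2 in each subpopulation with reduced-heritability flags.

    ``reduced`` is set when H2 in ``pop_alt`` is below
    ``(1 - reduction_fraction)`` x H2 in ``pop_ref`` (the strong, >=80%
    criterion); ``reduced_secondary`` uses the milder ``secondary_reduction``
    (default 20%) threshold. Flags are missing where the reference H2 is 0
    or either estimate is unavailable.
    """
    out = {}
    for pop in (pop_ref, pop_alt):
        genos = labels.index[labels == pop]
        samples = replicate_map.index[replicate_map.isin(genos)]
        sub = expression.loc[expression.index.intersection(samples)]
        try:
            out[pop] = h2_table(sub, replicate_map)["h2"]
        except ValueError:
            out[pop] = pd.Series(np.nan, index=expression.columns)
    df = pd.DataFrame({"h2_ref": out[pop_ref], "h2_alt": out[pop_alt]})
    with np.errstate(invalid="ignore"):
        valid = df["h2_ref"].notna() & df["h2_alt"].notna() & (df["h2_ref"] > 0)
        df["reduced"] = pd.Series(np.nan, index=df.index, dtype=object)
        df.loc[valid, "reduced"] = (
            df.loc[valid, "h2_alt"] < (1.0 - reduction_fraction) * df.loc[valid, "h2_ref"]
        )
        df["reduced_secondary"] = pd.Series(np.nan, index=df.index, dtype=object)
        df.loc[valid, "reduced_secondary"] = (
            df.loc[valid, "h2_alt"] < (1.0 - secondary_reduction) * df.loc[valid, "h2_ref"]
        )
    return df


def go_heritability_shift(
    h2: pd.Series,
    go_annotations: pd.DataFrame,
    size_min: int = 25,
    size_max: int = 499,
    fdr_max: float = 0.05,
    median_shift_min: float = 0.20,
) -> pd.DataFrame:
    """Two-sample KS test of per-term H2 against all remaining tested genes.

    A term is significant when its BH-adjusted p is <= ``fdr_max`` AND its
    median H2 differs from the background median by at least
    ``median_shift_min`` x background median.
    """
    tested = set(h2.index)
    ann = go_annotations[go_annotations["gene"].isin(tested)]
    rows = []
    for term, grp in ann.groupby("term"):
        genes = list(set(grp["gene"]))
        if not size_min <= len(genes) <= size_max:
            continue
        term_h2 = h2.loc[genes]
        bg_h2 = h2.loc[list(tested - set(genes))]
        if len(bg_h2) < 2:
            continue
        ks = stats.ks_2samp(term_h2, bg_h2)
        if not np.isfinite(ks.pvalue):
            continue
        med_t, med_b = float(term_h2.median()), float(bg_h2.median())
        rows.append((term, len(genes), med_t, med_b, ks.statistic, ks.pvalue))
    df = pd.DataFrame(
        rows,
        columns=["term", "n_genes", "median_term", "median_background", "ks_statistic", "p"],
    )
    if df.empty:
        df["fdr"] = df["direction"] = df["significant"] = []
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(df["median_term"] >= df["median_background"], "higher", "lower")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_shift = np.abs(df["median_term"] - df["median_background"]) / df["median_background"]
    df["significant"] = (df["fdr"] <= fdr_max) & (rel_shift >= median_shift_min)
    return df.sort_values("p").reset_index(drop=True)


def go_enrichment(
    study: set[str] | list[str],
    background: set[str] | list[str],
    go_annotations: pd.DataFrame,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of GO terms in a study set."""
    study, background = set(study), set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    ann = go_annotations[go_annotations["gene"].isin(background)]
    N, n = len(background), len(study)
    rows = []
    for term, grp in ann.groupby("term"):
        members = set(grp["gene"])
        K = len(members)
        k = len(members & study)
        p = stats.hypergeom.sf(k - 1, N, K, n)
        expected = n * K / N
        fold = k / expected if expected > 0 else np.nan
        rows.append((term, K, k, fold, p))
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "fold", "p"])
    if not df.empty:
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["fdr"] <= fdr_max
    return df.sort_values("p").reset_index(drop=True)
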