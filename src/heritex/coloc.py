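"""Colocalization of cis-eQTLs and cis-sQTLs and expression-splicing coupling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenotypeMatrix, ld_r2


def coloc_lead_snps(
    eqtl_peaks: pd.DataFrame,
    sqtl_peaks: pd.DataFrame,
    intron_to_gene: pd.Series,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.6,
) -> pd.DataFrame:
    """LD between cis-eQTL and cis-sQTL lead SNPs of the same gene.

    Both peak tables come from :func:`heritex.association.map_qtl`; sQTL
    traits (introns) are mapped to genes via ``intron_to_gene``. A pair is
    colocalized when lead-SNP r^2 >= ``r2_min``.
    """
    e_cis = eqtl_peaks[eqtl_peaks["cis_trans"] == "cis"]
    s_cis = sqtl_peaks[sqtl_peaks["cis_trans"] == "cis"].copy()
    s_cis["gene"] = intron_to_gene.loc[s_cis["trait"]].to_numpy()
    e_lead = dict(zip(e_cis["trait"], e_cis["lead_id"]))
    rows = []
    for _, row in s_cis.iterrows():
        gene = row["gene"]
        if gene not in e_lead:
            continue
        try:
            if e_lead[gene] == row["lead_id"]:
                r2 = 1.0
            else:
                r2 = ld_r2(genotypes, e_lead[gene], row["lead_id"])
        except (KeyError, ValueError) as exc:
            warnings.warn(f"skipping pair for {gene}: {exc}")
            continue
        if np.isnan(r2):
            warnings.warn(f"skipping pair for {gene}: undefined r^2")
            continue
        rows.append((gene, row["trait"], e_lead[gene], row["lead_id"], r2, r2 >= r2_min))
    return pd.DataFrame(
        rows,
        columns=["gene", "intron", "eqtl_lead", "sqtl_lead", "r2", "colocalized"],
    )


def expr_psi_correlation(
    expression_means: pd.DataFrame,
    psi_means: pd.DataFrame,
    pairs: list[tuple[str, str]],
    fdr_max: float = 0.05,
    method: str = "spearman",
    min_overlap: int = 20,
) -> pd.DataFrame:
    """Per gene-intron correlation between expression and PSI.

    Computed across genotype means (matching the QTL-scan substrate) with
    Spearman rank correlation by default; pairs with fewer than
    ``min_overlap`` jointly non-missing genotypes are skipped.
    """
    rows = []
    for gene, intron in pairs:
        if gene not in expression_means.columns or intron not in psi_means.columns:
            continue
        x = expression_means[gene]
        y = psi_means.loc[expression_means.index.intersection(psi_means.index), intron]
        joined = pd.concat([x, y], axis=1, join="inner").dropna()
        if len(joined) < min_overlap:
            continue
        a, b = joined.iloc[:, 0], joined.iloc[:, 1]
        if method == "spearman":
            r, p = stats.spearmanr(a, b)
        else:
            r, p = stats.pearsonr(a, b)
        rows.append((gene, intron, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["gene", "intron", "correlation", "p"])
    if df.empty:
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_max
    df["sign"] = np.where(df["correlation"] >= 0, "positive", "negative")
    return df


def direction_imbalance_test(n_positive: int, n_negative: int) -> float:
    """Chi-square goodness-of-fit of two counts against equal proportions.

    One degree of freedom, two-sided p; symmetric in its arguments.
    """
    if n_positive + n_negative < 1:
        raise ValueError("need at least one observation")
    res = stats.chisquare([n_positive, n_negative])
    return float(res.pvalue)
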