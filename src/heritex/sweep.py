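"""Two-population selective-sweep scan: windowed Weir-Cockerham Fst,
nucleotide diversity (pi) QC, and a cross-population composite likelihood
ratio (XP-CLR) scan.

Inbred lines are counted as single haploid alleles throughout (their two
chromosomes are effectively identical), so allele frequencies, Fst and pi
are computed on one allele per line.

XP-CLR model (Chen-Patterson-Reich class): the reference-population
frequency p1 is observed; under neutrality the object-population frequency
q drifts around p1 as a Gaussian with variance omega * p1 * (1 - p1),
truncated to [0, 1] with the tail mass placed as point masses on the
boundaries. Under a sweep at map distance r with selection coefficient s,
a lineage escapes the sweep with probability c = 1 - exp(-r / s); the
post-sweep frequency is c*q + (1-c) with probability q and c*q with
probability 1 - q, compounded over the neutral drift density. The observed
alt-allele count in the object population is binomial given the frequency.
CLR = 2 * (max_s composite log-likelihood - neutral log-likelihood),
maximized over a log-spaced s grid that includes the neutral limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import GenotypeMatrix


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map anchors: columns chrom, bp, cM."""

    anchors: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.anchors.sort_values(["chrom", "bp"]).reset_index(drop=True)
        for _, grp in a.groupby("chrom"):
            if not grp["cM"].is_monotonic_increasing:
                raise ValueError("cM must be nondecreasing with bp")
        self.anchors = a

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        rows = []
        for chrom, length in chrom_lengths.items():
            rows.append((chrom, 1, 0.0))
            rows.append((chrom, length, (length - 1) / 1e6 * cm_per_mb))
        return cls(pd.DataFrame(rows, columns=["chrom", "bp", "cM"]))


def interpolate_genetic_map(gmap: GeneticMap, chrom: str, bp) -> np.ndarray | float:
    """cM position(s) by linear interpolation between flanking anchors.

    Queries outside the anchor range extrapolate at the nearest segment's
    recombination rate.
    """
    sub = gmap.anchors[gmap.anchors["chrom"] == chrom]
    if sub.empty:
        raise KeyError(f"chromosome {chrom!r} absent from genetic map")
    xp = sub["bp"].to_numpy(dtype=float)
    fp = sub["cM"].to_numpy(dtype=float)
    q = np.atleast_1d(np.asarray(bp, dtype=float))
    if len(xp) == 1:
        out = np.full(q.shape, fp[0])
    else:
        out = np.interp(q, xp, fp)
        lo_rate = (fp[1] - fp[0]) / (xp[1] - xp[0])
        hi_rate = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        below, above = q < xp[0], q > xp[-1]
        out[below] = fp[0] + (q[below] - xp[0]) * lo_rate
        out[above] = fp[-1] + (q[above] - xp[-1]) * hi_rate
    return out if np.ndim(bp) else float(out[0])


# ---------------------------------------------------------------------------
# Allele counts


def _haploid_counts(g: GenotypeMatrix, labels: pd.Series):
    """Per-site haploid allele counts (n, k) per population."""
    lab = labels.loc[g.sample_ids].to_numpy()
    pops = list(pd.unique(lab))
    if len(pops) < 2:
        raise ValueError("need two populations")
    out = {}
    alleles = g.dosage / 2.0  # inbred: one allele per line; 0, 0.5 (het) or 1
    for pop in pops:
        sub = alleles[lab == pop]
        n = (~np.isnan(sub)).sum(axis=0).astype(float)
        k = np.nansum(sub, axis=0)
        out[pop] = (n, k)
    return pops, out


def per_site_fst_components(
    g: GenotypeMatrix, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-site numerator / denominator (haploid, 2 pops).

    Window Fst is the ratio-of-sums of these components over member sites.
    """
    pops, counts = _haploid_counts(g, labels)
    (n1, k1), (n2, k2) = counts[pops[0]], counts[pops[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = k1 / n1, k2 / n2
        nt = n1 + n2
        pbar = (k1 + k2) / nt
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
        nc = nt - (n1**2 + n2**2) / nt
        num = msp - msg
        den = msp + (nc - 1) * msg
    bad = (n1 < 2) | (n2 < 2)
    num[bad] = den[bad] = np.nan
    return num, den


def make_windows(
    chrom_lengths: dict[str, int], window: int = 100_000, step: int = 10_000
) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            rows.append((chrom, start, start + window - 1))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def chrom_lengths_from_markers(markers: pd.DataFrame) -> dict[str, int]:
    return {c: int(grp["pos"].max()) for c, grp in markers.groupby("chrom")}


def windowed_fst(
    g: GenotypeMatrix,
    labels: pd.Series,
    window: int = 100_000,
    step: int = 10_000,
    windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Weighted (ratio-of-sums) Weir-Cockerham Fst in sliding windows.

    Windows containing no polymorphic site are omitted.
    """
    num, den = per_site_fst_components(g, labels)
    if windows is None:
        windows = make_windows(chrom_lengths_from_markers(g.markers), window, step)
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        mask = (g.markers["chrom"] == chrom).to_numpy()
        pos = g.markers["pos"].to_numpy()[mask]
        nn, dd = num[mask], den[mask]
        order = np.argsort(pos)
        pos, nn, dd = pos[order], nn[order], dd[order]
        cum_n = np.concatenate([[0.0], np.nancumsum(nn)])
        cum_d = np.concatenate([[0.0], np.nancumsum(dd)])
        cum_ct = np.concatenate([[0], np.cumsum(~np.isnan(dd))])
        lo = np.searchsorted(pos, grp["start"].to_numpy())
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="right")
        for (_, w), a, b in zip(grp.iterrows(), lo, hi):
            n_snps = int(cum_ct[b] - cum_ct[a])
            if n_snps == 0:
                continue
            d = cum_d[b] - cum_d[a]
            fst = (cum_n[b] - cum_n[a]) / d if d != 0 else np.nan
            rows.append((w["chrom"], int(w["start"]), int(w["end"]), n_snps, fst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])


def window_pi(
    g: GenotypeMatrix,
    labels: pd.Series,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Nucleotide diversity per window per population.

    Per SNP site: unbiased expected heterozygosity 2*p*(1-p)*n/(n-1) on the
    haploid allele sample; window pi = sum over member sites divided by the
    window length in bp (monomorphic sites contribute zero, so absolute pi
    underestimates sequence diversity; the pi ratio uses the same
    convention in numerator and denominator).
    """
    pops, counts = _haploid_counts(g, labels)
    site_pi = {}
    for pop in pops[:2]:
        n, k = counts[pop]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = k / n
            site_pi[pop] = np.where(n > 1, 2 * p * (1 - p) * n / (n - 1), np.nan)
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        mask = (g.markers["chrom"] == chrom).to_numpy()
        pos = g.markers["pos"].to_numpy()[mask]
        order = np.argsort(pos)
        pos = pos[order]
        cums = {
            pop: np.concatenate([[0.0], np.nancumsum(site_pi[pop][mask][order])])
            for pop in pops[:2]
        }
        lo = np.searchsorted(pos, grp["start"].to_numpy())
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="right")
        for (_, w), a, b in zip(grp.iterrows(), lo, hi):
            length = w["end"] - w["start"] + 1
            vals = [float(cums[pop][b] - cums[pop][a]) / length for pop in pops[:2]]
            rows.append((w["chrom"], int(w["start"]), int(w["end"]), *vals))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pi_pop1", "pi_pop2"]
    )


# ---------------------------------------------------------------------------
# XP-CLR


def estimate_omega(p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> float:
    """Genome-wide drift scale by method of moments.

    E[(p1_hat - p2_hat)^2] = omega * p1(1-p1) + sampling noise; the
    binomial sampling terms are subtracted before the ratio of means.
    """
    ok = (p1 > 0) & (p1 < 1)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / n1 - p2 * (1 - p2) / n2
    omega = np.nanmean(np.clip(num[ok], 0, None)) / np.nanmean((p1 * (1 - p1))[ok])
    return float(max(omega, 1e-4))


def _site_likelihood_tables(
    p1: np.ndarray,
    k2: np.ndarray,
    n2: np.ndarray,
    omega: float,
    c_grid: np.ndarray,
    n_nodes: int = 60,
):
    """Per-site neutral log-likelihood and log-likelihood on a grid of
    escape probabilities c (c = 1 reproduces the neutral model)."""
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    q = 0.5 * (nodes + 1.0)  # [0, 1]
    wq = 0.5 * weights
    sigma = np.sqrt(omega * p1 * (1 - p1))  # per site
    # drift density at interior nodes, with boundary point masses
    zq = (q[None, :] - p1[:, None]) / sigma[:, None]
    fq = stats.norm.pdf(zq) / sigma[:, None]  # sites x nodes
    m0 = stats.norm.cdf((0.0 - p1) / sigma)
    m1 = stats.norm.sf((1.0 - p1) / sigma)

    def binom_pmf(k, n, p):
        p = np.clip(p, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logpmf = (
                special.gammaln(n + 1)
                - special.gammaln(k + 1)
                - special.gammaln(n - k + 1)
                + special.xlogy(k, p)
                + special.xlog1py(n - k, -p)
            )
        return np.exp(logpmf)

    # neutral: integral + boundary masses
    bq = binom_pmf(k2[:, None], n2[:, None], q[None, :])  # sites x nodes
    l_neutral = (fq * bq * wq[None, :]).sum(axis=1)
    l_neutral += m0 * (k2 == 0) + m1 * (k2 == n2)

    # sweep: g(q) = q*B(cq + 1 - c) + (1-q)*B(cq), for each c
    n_c = len(c_grid)
    l_sweep = np.empty((len(p1), n_c))
    for ci, c in enumerate(c_grid):
        b_hi = binom_pmf(k2[:, None], n2[:, None], c * q[None, :] + (1.0 - c))
        b_lo = binom_pmf(k2[:, None], n2[:, None], c * q[None, :])
        gq = q[None, :] * b_hi + (1.0 - q[None, :]) * b_lo
        val = (fq * gq * wq[None, :]).sum(axis=1)
        val += m0 * (k2 == 0) + m1 * (k2 == n2)  # g(0)=[k2=0], g(1)=[k2=n2]
        l_sweep[:, ci] = val
    eps = 1e-300
    return np.log(l_neutral + eps), np.log(l_sweep + eps)


def single_site_sweep_likelihood(
    p1: float, k2: int, n2: int, omega: float, c: float, n_nodes: int = 60
) -> float:
    """Likelihood of one object-population count under the sweep model
    (escape probability c); c = 1 gives the neutral likelihood."""
    logl0, logl1 = _site_likelihood_tables(
        np.array([p1]), np.array([float(k2)]), np.array([float(n2)]),
        omega, np.array([c]), n_nodes,
    )
    return float(np.exp(logl1[0, 0]))


def xpclr_scan(
    g: GenotypeMatrix,
    labels: pd.Series,
    gmap: GeneticMap,
    grid_spacing: int = 10_000,
    window_cM: float = 0.0005,
    max_snps: int = 100,
    s_grid_size: int = 100,
    corr_cutoff: float = 0.95,
    ref_pop: str | None = None,
    omega: float | None = None,
) -> pd.DataFrame:
    """Cross-population CLR at grid points spaced ``grid_spacing`` bp.

    ``window_cM`` is the site-inclusion radius in Morgans; at most
    ``max_snps`` nearest sites are used per grid point, with sites in
    pairwise dosage correlation > ``corr_cutoff`` down-weighted by
    1/group-size. Selection coefficients are maximized over a log-spaced
    grid of ``s_grid_size`` values (plus the neutral limit), so CLR >= 0.
    """
    pops, counts = _haploid_counts(g, labels)
    ref = ref_pop or pops[0]
    obj = [p for p in pops if p != ref][0]
    (nr, kr), (no, ko) = counts[ref], counts[obj]
    with np.errstate(divide="ignore", invalid="ignore"):
        p1_raw = kr / nr
        p2 = ko / no
    # shrink reference frequencies off the boundary (degenerate drift there)
    p1 = (kr + 0.5) / (nr + 1.0)
    if omega is None:
        omega = estimate_omega(p1_raw, p2, nr, no)
    s_grid = np.geomspace(1e-4, 0.5, s_grid_size)
    c_grid = np.linspace(0.0, 1.0, 41)

    rows = []
    for chrom, grp in g.markers.groupby("chrom", sort=False):
        mask = (g.markers["chrom"] == chrom).to_numpy()
        pos = g.markers["pos"].to_numpy()[mask]
        cm = np.asarray(interpolate_genetic_map(gmap, str(chrom), pos)) / 100.0  # Morgans
        usable = (no[mask] >= 2) & (nr[mask] >= 2)
        logl0, logl1 = _site_likelihood_tables(
            p1[mask], ko[mask], no[mask], omega, c_grid
        )
        dos = g.dosage[:, mask]
        length = int(pos.max())
        for gp in range(1, length + 1, grid_spacing):
            gp_cm = float(interpolate_genetic_map(gmap, str(chrom), gp)) / 100.0
            d = np.abs(cm - gp_cm)
            sel = np.where((d <= window_cM) & usable)[0]
            if sel.size == 0:
                rows.append((chrom, gp, np.nan, 0))
                continue
            if sel.size > max_snps:
                sel = sel[np.argsort(d[sel])[:max_snps]]
                sel = np.sort(sel)
            w = _corr_group_weights(dos[:, sel], corr_cutoff)
            r = np.maximum(d[sel], 1e-8)  # Morgans to the grid point
            # escape probabilities per (site, s)
            c = 1.0 - np.exp(-r[:, None] / s_grid[None, :])
            ll1 = _interp_rows(logl1[sel], c_grid, c)  # sites x s
            score_s = (w[:, None] * ll1).sum(axis=0)
            score_0 = (w * logl0[sel]).sum()
            clr = 2.0 * max(float(score_s.max() - score_0), 0.0)
            rows.append((chrom, gp, clr, int(sel.size)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "clr", "n_snps"])


def _corr_group_weights(dos: np.ndarray, cutoff: float) -> np.ndarray:
    """1/group-size weights after greedy grouping of highly correlated sites."""
    m = dos.shape[1]
    sd = dos.std(axis=0)
    sd[sd == 0] = np.nan
    z = (dos - dos.mean(axis=0)) / sd
    corr = np.abs(np.nan_to_num(z.T @ z / dos.shape[0]))
    group = -np.ones(m, dtype=int)
    ng = 0
    reps: list[int] = []
    for j in range(m):
        for gi, rep in enumerate(reps):
            if corr[j, rep] > cutoff:
                group[j] = gi
                break
        if group[j] < 0:
            group[j] = ng
            reps.append(j)
            ng += 1
    sizes = np.bincount(group)
    return 1.0 / sizes[group]


def _interp_rows(table: np.ndarray, grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Row-wise linear interpolation: table[i, :] sampled at x[i, :]."""
    idx = np.clip(np.searchsorted(grid, x) - 1, 0, len(grid) - 2)
    x0 = grid[idx]
    frac = (x - x0) / (grid[idx + 1] - x0)
    rows = np.arange(table.shape[0])[:, None]
    return table[rows, idx] * (1 - frac) + table[rows, idx + 1] * frac


# ---------------------------------------------------------------------------
# Window combination and candidate genes


def combine_window_stats(
    fst_windows: pd.DataFrame,
    xpclr_scores: pd.DataFrame,
    pi_windows: pd.DataFrame,
    decile: float = 0.90,
) -> pd.DataFrame:
    """Merge Fst, window-averaged XP-CLR and pi-ratio QC into one table.

    Grid-point CLRs are averaged within each Fst window; the top
    ceil((1-decile) * n) windows per statistic are flagged; windows whose
    pi_pop1/pi_pop2 ratio falls below the genome-wide mean fail QC and are
    removed from both flagged sets.
    """
    df = fst_windows.merge(pi_windows, on=["chrom", "start", "end"], how="left")
    means = []
    for _, w in df.iterrows():
        m = (
            (xpclr_scores["chrom"] == w["chrom"])
            & (xpclr_scores["pos"] >= w["start"])
            & (xpclr_scores["pos"] <= w["end"])
        )
        vals = xpclr_scores.loc[m, "clr"]
        means.append(float(vals.mean()) if vals.notna().any() else np.nan)
    df["xpclr_mean"] = means
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pi_ratio"] = df["pi_pop1"] / df["pi_pop2"]
    # a fully swept window has pi_pop2 = 0: the ratio is infinite and passes
    df.loc[df["pi_ratio"].isna(), "pi_ratio"] = np.nan
    finite = df["pi_ratio"].replace(np.inf, np.nan)
    genome_mean = finite.mean()
    df["qc_pass"] = df["pi_ratio"] >= genome_mean

    for stat, flag in (("fst", "fst_top"), ("xpclr_mean", "xpclr_top")):
        valid = df[stat].notna()
        n_flag = int(np.ceil((1.0 - decile) * valid.sum()))
        df[flag] = False
        top_idx = df.loc[valid, stat].nlargest(n_flag).index
        df.loc[top_idx, flag] = True
        df.loc[~df["qc_pass"], flag] = False
    return df


def sweep_candidate_genes(window_table: pd.DataFrame, gene_models) -> list[str]:
    """Genes lying entirely within windows flagged by both Fst and XP-CLR
    (QC-passing). Containment is against the union of flagged windows per
    statistic."""

    def union(flag: str) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, grp in window_table[window_table[flag]].groupby("chrom"):
            ivals = sorted(zip(grp["start"], grp["end"]))
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[str(chrom)] = [(s, e) for s, e in merged]
        return out

    fst_u, xp_u = union("fst_top"), union("xpclr_top")

    def contained(gene, ivals) -> bool:
        return any(s <= gene.start and gene.end <= e for s, e in ivals.get(gene.chrom, []))

    return [
        g.gene_id
        for g in gene_models
        if contained(g, fst_u) and contained(g, xp_u)
    ]
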