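"""Percent-spliced-in (PSI) quantification of introns.

PSI = ucount / (depth / size): junction reads normalized by average
per-base intronic coverage. PSI is missing when depth is zero and is not
capped at 1 (the ratio can exceed 1 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IntronEvent:
    intron_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 1:
            raise ValueError(f"{self.intron_id}: size must be >= 1")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def compute_psi(ucount, depth, size):
    """PSI = ucount * size / depth; nan where depth == 0.

    Scalar or array inputs; negative inputs are rejected.
    """
    u = np.asarray(ucount, dtype=float)
    d = np.asarray(depth, dtype=float)
    s = np.asarray(size, dtype=float)
    if (u < 0).any() or (d < 0).any():
        raise ValueError("ucount and depth must be nonnegative")
    if (s < 1).any():
        raise ValueError("intron size must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(d > 0, u * s / np.where(d > 0, d, 1.0), np.nan)
    return psi if psi.ndim else float(psi)


def psi_matrix(
    ucount: pd.DataFrame, depth: pd.DataFrame, sizes: pd.Series
) -> pd.DataFrame:
    """Samples x introns PSI matrix from count matrices and intron sizes."""
    sizes = sizes.loc[ucount.columns]
    vals = compute_psi(
        ucount.to_numpy(), depth.to_numpy(), sizes.to_numpy()[None, :]
    )
    return pd.DataFrame(vals, index=ucount.index, columns=ucount.columns)


def filter_s_traits(
    ucount: pd.DataFrame,
    psi: pd.DataFrame,
    min_junction: int = 5,
    min_sample_frac: float = 0.05,
    min_se: float = 0.01,
) -> list[str]:
    """Introns analyzable as splicing traits.

    Keeps introns supported by >= ``min_junction`` junction reads in at
    least ceil(``min_sample_frac`` x n_samples) samples and whose PSI
    standard error across samples (sd / sqrt(n non-missing)) is
    >= ``min_se``.
    """
    n = len(ucount)
    required = int(np.ceil(min_sample_frac * n))
    support = (ucount >= min_junction).sum(axis=0) >= required
    n_obs = psi.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        se = psi.std(axis=0, ddof=1) / np.sqrt(n_obs.clip(lower=1))
    se = se.fillna(0.0)
    keep = support & (se >= min_se) & (n_obs >= 2)
    return list(psi.columns[keep])
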