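"""Metagene methylation profiles and methylation–expression correlation.

A metagene profile pools read counts from all genes into a fixed bin grid:
fixed-width flank bins (default 2 kb in 100-bp bins) on either side of the
gene body, and the body itself rescaled into a fixed number of bins
(default 60).  Minus-strand genes are reversed so bin 0 is always the most
upstream bin and the TSS sits at the flank/body junction.  Each bin's value
is the weighted methylation (sum methylated / sum total reads) over every
site any gene contributed to that bin — genes with more coverage weigh
more, which is the standard pooled-profile convention.

Expression ranking follows the 0–20 scheme: genes with zero abundance form
rank 0, and the remaining genes are split into 20 equal-size quantile bins
from lowest (rank 1) to highest (rank 20) expression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meth_io import GeneModel
from .methylome import CpGSiteTable

SPEARMAN_EXACT_MAX_N = 9


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    values: np.ndarray          # one weighted-methylation value per bin
    flank_bins: int
    body_bins: int
    flank_bin_bp: int
    n_genes_used: int
    n_genes_skipped: int
    bin_m: np.ndarray = field(repr=False, default=None)
    bin_cov: np.ndarray = field(repr=False, default=None)

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    @property
    def tss_bin(self) -> int:
        return self.flank_bins

    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)


def metagene_profile(
    table: CpGSiteTable,
    genes: Iterable[GeneModel],
    samples: Sequence[str] | None = None,
    flank_bp: int = 2000,
    body_bins: int = 60,
    flank_bin_bp: int = 100,
) -> ProfileMatrix:
    """Pooled weighted-methylation metagene profile over ``genes``.

    Genes whose body is shorter than ``body_bins`` bp are skipped (a body
    bin would be narrower than 1 bp) and counted in ``n_genes_skipped``.
    """
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    flank_bins = flank_bp // flank_bin_bp
    n_bins = 2 * flank_bins + body_bins
    samples = list(samples) if samples is not None else table.samples

    m_tot = sum(table.counts[(s, "m")].to_numpy() for s in samples)
    cov_tot = m_tot + sum(table.counts[(s, "u")].to_numpy() for s in samples)

    idx_chrom = table.counts.index.get_level_values(0).to_numpy()
    idx_pos = table.counts.index.get_level_values(1).to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(idx_chrom):
        sel = np.flatnonzero(idx_chrom == chrom)
        by_chrom[chrom] = (idx_pos[sel], sel)

    bin_m = np.zeros(n_bins)
    bin_cov = np.zeros(n_bins)
    used = skipped = 0
    for g in genes:
        bs, be = g.gene_body
        L = be - bs
        if L < body_bins:
            skipped += 1
            continue
        used += 1
        if g.chrom not in by_chrom:
            continue
        pos, sel = by_chrom[g.chrom]
        lo, hi = np.searchsorted(pos, [bs - flank_bp, be + flank_bp])
        if hi == lo:
            continue
        p = pos[lo:hi]
        rows = sel[lo:hi]
        # transcription coordinate: 0 at TSS, increasing downstream
        t = (p - bs) if g.strand == "+" else ((be - 1) - p)
        bins = np.empty(len(t), dtype=int)
        up = t < 0
        body = (t >= 0) & (t < L)
        down = t >= L
        bins[up] = flank_bins + np.floor_divide(t[up], flank_bin_bp)
        bins[body] = flank_bins + (t[body] * body_bins) // L
        bins[down] = flank_bins + body_bins + np.floor_divide(t[down] - L, flank_bin_bp)
        ok = (bins >= 0) & (bins < n_bins)
        np.add.at(bin_m, bins[ok], m_tot[rows[ok]])
        np.add.at(bin_cov, bins[ok], cov_tot[rows[ok]])

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(bin_cov > 0, bin_m / bin_cov, np.nan)
    return ProfileMatrix(values, flank_bins, body_bins, flank_bin_bp, used, skipped,
                         bin_m=bin_m, bin_cov=bin_cov)


# ---------------------------------------------------------------------------
# expression ranks
# ---------------------------------------------------------------------------

def assign_expression_ranks(abundance: pd.Series, n_bins: int = 20) -> pd.Series:
    """Rank genes 0–``n_bins`` by abundance.

    Rank 0 holds exactly the zero-abundance genes.  Nonzero genes are
    sorted ascending (ties broken by gene id for determinism) and split
    into ``n_bins`` contiguous, equal-size (±1) groups, rank 1 = lowest.
    """
    if (abundance < 0).any():
        raise ValueError("abundance must be non-negative")
    ranks = pd.Series(0, index=abundance.index, dtype=int, name="rank")
    nonzero = abundance[abundance > 0]
    if len(nonzero) == 0:
        import warnings

        warnings.warn("all genes have zero abundance; every rank is 0")
        return ranks
    order = nonzero.to_frame("x")
    order = order.iloc[np.lexsort((order.index.to_numpy(), order["x"].to_numpy()))]
    chunks = np.array_split(np.arange(len(order)), n_bins)
    for i, chunk in enumerate(chunks, start=1):
        ranks.loc[order.index[chunk]] = i
    return ranks


def rank_methylation_profiles(
    table: CpGSiteTable,
    genes: Sequence[GeneModel],
    ranks: pd.Series,
    samples: Sequence[str] | None = None,
    **profile_kwargs,
) -> dict[int, ProfileMatrix]:
    """One metagene profile per expression rank; empty ranks are omitted."""
    by_id = {g.gene_id: g for g in genes}
    out: dict[int, ProfileMatrix] = {}
    for rank in sorted(ranks.unique()):
        ids = ranks.index[ranks == rank]
        members = [by_id[i] for i in ids if i in by_id]
        if not members:
            continue
        out[int(rank)] = metagene_profile(table, members, samples=samples, **profile_kwargs)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n P
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    kind: str            # e.g. "promoter" / "gene_body"
    group: str           # e.g. "chrX/female"
    rho: float
    pvalue: float
    n: int
    method: str = "spearman"


def _spearman_exact_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact P by full enumeration of the n! pairings."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with a two-sided P.

    Exact by permutation enumeration for n <= 9, the large-sample
    approximation otherwise.  Constant input gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_pvalue(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def spearman_meth_expression(
    df: pd.DataFrame,
    meth_col: str = "meth",
    expr_col: str = "expression",
    by: Sequence[str] = (),
    kind: str = "promoter",
) -> list[CorrelationResult]:
    """Grouped Spearman correlation between methylation and expression.

    ``df`` holds one row per gene with a methylation summary and an
    abundance; ``by`` columns (e.g. chromosome class, sex, biotype) define
    the groups, each correlated separately.  Groups with fewer than 3
    complete genes yield an undefined result.
    """
    results = []
    groups = df.groupby(list(by)) if by else [((), df)]
    for key, sub in groups:
        sub = sub.dropna(subset=[meth_col, expr_col])
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        n = len(sub)
        if n < 3:
            results.append(CorrelationResult(kind, label, float("nan"), float("nan"), n))
            continue
        rho, p = spearman_correlation(sub[meth_col].to_numpy(), sub[expr_col].to_numpy())
        results.append(CorrelationResult(kind, label, rho, p, n))
    return results
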