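"""Female–male differential methylation and the associated statistics.

Site-level deltas treat animals as replicates: a site's sex mean is the
unweighted mean of per-sample fractional methylation values (each already
coverage-filtered), and ``delta_fm = female_mean - male_mean``.  Gene-level
promoter deltas are reported on the male-minus-female axis and classified
with a fixed band: a gene is *female hypomethylated* when the male−female
promoter difference exceeds +0.05, *female hypermethylated* below −0.05,
and unbiased inside the band.

Statistics:

* Mann–Whitney U, exact by enumeration when nA+nB <= 12 (handles ties),
  normal approximation with tie correction otherwise;
* Pearson chi-square on a 2x2 table without continuity correction;
* Spearman correlations via :mod:`xcimeth.profiles`.

No multiple-testing correction is applied across comparisons; reported P
values are raw, and outputs flag this in their metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CorrelationResult, spearman_correlation

DELTA_BAND = 0.05
MANN_WHITNEY_EXACT_MAX_N = 12

SEX_BIAS_CLASSES = ("female_hypo", "female_hyper", "unbiased")


@dataclass
class TestResult:
    name: str            # MannWhitneyU / ChiSquare / Spearman
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    method: str = ""
    extra: dict | None = None


# ---------------------------------------------------------------------------
# per-site deltas
# ---------------------------------------------------------------------------

def per_site_delta(
    fractions: pd.DataFrame,
    sex_of: Mapping[str, str],
    min_samples_per_sex: int = 1,
) -> pd.DataFrame:
    """Per-site sex means and female−male delta.

    ``fractions`` is the (chrom, pos0) x sample frame of coverage-filtered
    fractional methylation (NaN where unqualified).  A site is emitted only
    when both sexes have at least ``min_samples_per_sex`` qualifying
    samples; skipped sites are countable from the returned attrs.
    """
    females = [s for s in fractions.columns if sex_of[s] == "female"]
    males = [s for s in fractions.columns if sex_of[s] == "male"]
    f_n = fractions[females].notna().sum(axis=1)
    m_n = fractions[males].notna().sum(axis=1)
    keep = (f_n >= min_samples_per_sex) & (m_n >= min_samples_per_sex)
    out = pd.DataFrame(
        {
            "female_mean": fractions[females].mean(axis=1)[keep],
            "male_mean": fractions[males].mean(axis=1)[keep],
            "n_female": f_n[keep],
            "n_male": m_n[keep],
        }
    )
    out["delta_fm"] = out["female_mean"] - out["male_mean"]
    out.attrs["n_sites_skipped"] = int((~keep).sum())
    return out


def per_chromosome_delta_summary(site_deltas: pd.DataFrame) -> pd.DataFrame:
    """Median / mean / quartiles of delta_fm per chromosome."""
    g = site_deltas.groupby(level=0)["delta_fm"]
    return pd.DataFrame(
        {
            "n_sites": g.size(),
            "mean": g.mean(),
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
        }
    )


# ---------------------------------------------------------------------------
# per-gene deltas and sex-bias classes
# ---------------------------------------------------------------------------

def classify_sex_bias(delta_mf: float, band: float = DELTA_BAND) -> str:
    if np.isnan(delta_mf):
        return "undefined"
    if delta_mf > band:
        return "female_hypo"
    if delta_mf < -band:
        return "female_hyper"
    return "unbiased"


def per_gene_delta(
    summaries: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
    band: float = DELTA_BAND,
) -> pd.DataFrame:
    """Gene-level male−female methylation deltas with sex-bias classes.

    ``summaries`` is a long frame (one row per gene x sex x region kind)
    with columns ``gene_id, group ('female'/'male'), kind
    ('promoter'/'gene_body'), mean``.  ``de_table`` (optional, indexed or
    keyed by gene_id) contributes ``log2fc_fm`` and ``significant``;
    unmatched ids on either side are recorded in the result attrs.
    """
    wide = summaries.pivot_table(
        index="gene_id", columns=["kind", "group"], values="mean", aggfunc="first"
    )
    out = pd.DataFrame(index=wide.index)
    for kind, col in (("promoter", "promoter_delta_mf"), ("gene_body", "body_delta_mf")):
        if (kind, "male") in wide.columns and (kind, "female") in wide.columns:
            out[col] = wide[(kind, "male")] - wide[(kind, "female")]
        else:
            out[col] = np.nan
    out["sex_bias_class"] = [classify_sex_bias(d, band) for d in out["promoter_delta_mf"]]
    out.attrs["n_genes_missing_sex"] = int(out["promoter_delta_mf"].isna().sum())
    if de_table is not None:
        de = de_table.set_index("gene_id") if "gene_id" in de_table.columns else de_table
        if de.index.duplicated().any():
            raise ValueError("duplicate gene_id rows in DE table")
        out = out.join(de[[c for c in ("log2fc_fm", "pvalue", "padj", "significant") if c in de.columns]])
        out.attrs["n_de_unmatched"] = int(len(de.index.difference(wide.index)))
        out.attrs["de_unmatched_ids"] = list(de.index.difference(wide.index)[:50])
    return out


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group A over B, with 0.5 credit for ties."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact when nA+nB <= 12, enumerating every assignment of the pooled
    values to the two groups (tie-safe); otherwise the normal
    approximation with tie correction (no continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if n1 + n2 <= MANN_WHITNEY_EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        total = n1 * n2
        u_lo = min(u_obs, total - u_obs)
        u_hi = total - u_lo
        count = 0
        n_arr = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            eps = 1e-9
            if u <= u_lo + eps or u >= u_hi - eps:
                count += 1
            n_arr += 1
        p = min(1.0, count / n_arr)
        method = "exact-enumeration"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        p = float(res.pvalue)
        method = "normal-approximation-tie-corrected"
    return TestResult("MannWhitneyU", u_obs, p, (n1, n2), method)


# ---------------------------------------------------------------------------
# chi-square 2x2
# ---------------------------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on [[a, b], [c, d]], df=1, no continuity correction."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult("ChiSquare", float(res.statistic), float(res.pvalue),
                      (int(a + b), int(c + d)), "pearson-df1-no-correction")


# ---------------------------------------------------------------------------
# CpG-count dependence of the promoter delta
# ---------------------------------------------------------------------------

def cpg_count_binning(
    promoter_meth: pd.DataFrame,
    cpg_counts: pd.DataFrame,
    bin_width: int = 5,
    top_open_at: int = 80,
) -> pd.DataFrame:
    """Bin genes by promoter CpG count; summarise methylation per sex per bin.

    ``promoter_meth`` has columns ``gene_id, female, male`` (mean promoter
    methylation per sex); ``cpg_counts`` has ``gene_id, n_cpg``.  Bins are
    ``[0,w), [w,2w), ...`` with everything above ``top_open_at`` pooled
    into one open-ended top bin.  Returns per-bin mean female/male
    methylation and the male−female delta; empty bins are omitted.
    """
    df = promoter_meth.merge(cpg_counts[["gene_id", "n_cpg"]], on="gene_id")
    edges = list(range(0, top_open_at + bin_width, bin_width))
    labels = [f"[{lo},{lo + bin_width})" for lo in edges[:-1]] + [f">{top_open_at}"]
    idx = np.minimum(df["n_cpg"] // bin_width, len(edges) - 1)
    df["bin_index"] = idx
    df["bin_label"] = [labels[i] for i in idx]
    g = df.groupby(["bin_index", "bin_label"], as_index=False).agg(
        n_genes=("gene_id", "size"),
        female_mean=("female", "mean"),
        male_mean=("male", "mean"),
    )
    g["delta_mf"] = g["male_mean"] - g["female_mean"]
    return g.sort_values("bin_index").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression fold-change comparisons
# ---------------------------------------------------------------------------

def expression_fc_comparison(
    log2fc: pd.Series, chrom_class: pd.Series
) -> tuple[pd.Series, TestResult]:
    """Compare female/male expression log2 fold-changes between chromosome
    classes (autosome vs X): group means plus a Mann–Whitney test."""
    df = pd.DataFrame({"log2fc": log2fc, "cls": chrom_class}).dropna()
    classes = sorted(df["cls"].unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two chromosome classes, got {classes}")
    groups = [df.loc[df["cls"] == c, "log2fc"].to_numpy() for c in classes]
    means = pd.Series({c: g.mean() for c, g in zip(classes, groups)})
    return means, mann_whitney(groups[0], groups[1])


def delta_expression_correlation(
    gene_deltas: pd.DataFrame,
    significant_only: bool = False,
) -> list[CorrelationResult]:
    """Spearman correlation of gene methylation deltas with expression
    log2 fold-change, for promoter and gene-body deltas.

    ``gene_deltas`` is the frame from :func:`per_gene_delta` including a
    ``log2fc_fm`` column.  With ``significant_only`` the DE-significant
    subset is used.
    """
    if gene_deltas.index.duplicated().any():
        raise ValueError("duplicated gene rows")
    df = gene_deltas
    if significant_only:
        if "significant" not in df.columns:
            raise ValueError("no 'significant' column for DE-only subset")
        df = df[df["significant"].astype(bool)]
    out = []
    subset = "significant" if significant_only else "all"
    for kind, col in (("gene_body", "body_delta_mf"), ("promoter", "promoter_delta_mf")):
        sub = df.dropna(subset=[col, "log2fc_fm"])
        n = len(sub)
        if n < 3:
            out.append(CorrelationResult(kind, subset, float("nan"), float("nan"), n))
            continue
        rho, p = spearman_correlation(sub[col].to_numpy(), sub["log2fc_fm"].to_numpy())
        out.append(CorrelationResult(kind, subset, rho, p, n))
    return out
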