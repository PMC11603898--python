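"""Read-level allele-specific methylation (ASM) and per-CpG
methylation–expression correlation at a candidate locus.

In a female cell, one X chromosome is transcriptionally inactivated; at
the 5' CpG island of an Xist-like gene the two alleles carry opposite
methylation states, so individual bisulfite reads from the region are
either (almost) fully methylated or fully unmethylated.  The ASM caller
summarises each read's CpG calls into a per-read methylation fraction and
declares ASM when the fraction distribution is strongly bimodal at the
extremes: a minimum proportion of reads at <= ``low_cut`` or >=
``high_cut``, with both extreme modes populated.

The default extreme cuts (0.25 / 0.75) are chosen for short reads: a
read carrying only 3-6 CpG calls from a ~95%-methylated allele often
shows one unconverted-looking call, so a 0.9 cut would misclassify a
large share of genuinely single-allele reads, while mid-fraction reads
from a non-ASM locus still fall far inside (0.25, 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

MIN_SITES_PER_READ = 3


@dataclass
class AsmCall:
    region: str
    n_reads_used: int
    frac_extreme: float
    n_low_mode: int
    n_high_mode: int
    is_asm: bool
    determined: bool = True
    reason: str = ""
    fraction_summary: dict = field(default_factory=dict)


def per_read_profiles(
    calls: pd.DataFrame,
    chrom: str,
    start0: int,
    end0: int,
    min_sites_per_read: int = MIN_SITES_PER_READ,
) -> pd.DataFrame:
    """Per-read CpG methylation profiles within a region.

    ``calls`` carries one row per (read, position) with columns
    ``read_id, chrom, pos0, methylated``.  Conflicting duplicate calls for
    the same (read, position) raise; identical duplicates are dropped.
    Reads with fewer than ``min_sites_per_read`` CpG calls in the region
    are dropped and counted in the result attrs.
    """
    region = calls[
        (calls["chrom"] == chrom)
        & (calls["pos0"] >= start0)
        & (calls["pos0"] < end0)
    ]
    dup = region.duplicated(subset=["read_id", "pos0"], keep=False)
    if dup.any():
        conflicts = (
            region[dup].groupby(["read_id", "pos0"])["methylated"].nunique()
        )
        if (conflicts > 1).any():
            rid, pos = conflicts[conflicts > 1].index[0]
            raise ValueError(f"conflicting duplicate call for read {rid!r} at pos {pos}")
        region = region.drop_duplicates(subset=["read_id", "pos0"])
    g = region.groupby("read_id")["methylated"]
    prof = pd.DataFrame({"n_sites": g.size(), "n_methylated": g.sum().astype(int)})
    prof["per_read_fraction"] = prof["n_methylated"] / prof["n_sites"]
    keep = prof["n_sites"] >= min_sites_per_read
    out = prof[keep].reset_index()
    out.attrs["n_reads_dropped"] = int((~keep).sum())
    out.attrs["region"] = f"{chrom}:{start0}-{end0}"
    return out


def call_asm(
    profiles: pd.DataFrame,
    region: str = "",
    low_cut: float = 0.25,
    high_cut: float = 0.75,
    extreme_min: float = 0.9,
    mode_min: int = 5,
) -> AsmCall:
    """Bimodality-based ASM call from per-read methylation fractions.

    ASM is declared iff the proportion of reads at the extremes
    (fraction <= ``low_cut`` or >= ``high_cut``) is at least
    ``extreme_min`` AND each extreme mode holds at least ``mode_min``
    reads.  With fewer than ``2 * mode_min`` usable reads the call is
    returned undetermined.
    """
    region = region or profiles.attrs.get("region", "")
    frac = profiles["per_read_fraction"].to_numpy()
    n = len(frac)
    if n < 2 * mode_min:
        return AsmCall(region, n, float("nan"), 0, 0, False, determined=False,
                       reason=f"only {n} usable reads (< {2 * mode_min})")
    low = int((frac <= low_cut).sum())
    high = int((frac >= high_cut).sum())
    frac_extreme = (low + high) / n
    is_asm = frac_extreme >= extreme_min and low >= mode_min and high >= mode_min
    summary = {
        "mean": float(frac.mean()),
        "median": float(np.median(frac)),
        "q10": float(np.quantile(frac, 0.1)),
        "q90": float(np.quantile(frac, 0.9)),
    }
    return AsmCall(region, n, float(frac_extreme), low, high, bool(is_asm),
                   fraction_summary=summary)


# ---------------------------------------------------------------------------
# per-CpG methylation ~ expression correlation across samples
# ---------------------------------------------------------------------------

def cpg_expression_correlation(
    site_fractions: pd.DataFrame,
    expression: pd.Series,
    sex_of: Mapping[str, str],
    min_samples: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each CpG's methylation with gene expression.

    ``site_fractions`` is (chrom, pos0) x sample; ``expression`` gives the
    gene's abundance per sample (same sample set).  Only sites with
    complete data in at least ``min_samples`` samples are tested (P from
    the exact t distribution, two-sided); constant-methylation sites are
    reported with undefined r.  Each site is annotated with its sex-bias
    direction (female-hypo / male-hypo / none) from the per-sex means.
    """
    samples = [s for s in site_fractions.columns if s in expression.index]
    if len(samples) < len(site_fractions.columns):
        missing = set(site_fractions.columns) - set(samples)
        raise ValueError(f"expression missing samples {sorted(missing)}")
    expr = expression[samples].to_numpy(dtype=float)
    females = [s for s in samples if sex_of[s] == "female"]
    males = [s for s in samples if sex_of[s] == "male"]

    rows = []
    n_excluded = 0
    for idx, row in site_fractions[samples].iterrows():
        vals = row.to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() < min_samples:
            n_excluded += 1
            continue
        x, y = vals[ok], expr[ok]
        f_mean = row[females].mean()
        m_mean = row[males].mean()
        if np.isnan(f_mean) or np.isnan(m_mean) or f_mean == m_mean:
            direction = "none"
        else:
            direction = "female_hypo" if f_mean < m_mean else "male_hypo"
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append((*idx, np.nan, np.nan, int(ok.sum()), False, direction))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((*idx, float(r), float(p), int(ok.sum()), bool(p < alpha), direction))
    out = pd.DataFrame(
        rows,
        columns=["chrom", "pos0", "r", "pvalue", "n", "significant", "sex_bias"],
    )
    out.attrs["n_sites_excluded_incomplete"] = n_excluded
    out.attrs["multiple_testing_correction"] = "none (raw P values)"
    return out


# ---------------------------------------------------------------------------
# per-CpG sex delta track over a region
# ---------------------------------------------------------------------------

def region_delta_track(
    table,
    sex_of: Mapping[str, str],
    chrom: str,
    start0: int,
    end0: int,
    flank: int = 0,
    min_reads_either_sex: int = 2,
) -> pd.DataFrame:
    """Per-CpG female/male means and deltas across a region (± flank).

    Unlike the genome-wide >= 5-read site filter, region tracks use the
    locus rule: a site is included when its pooled coverage reaches
    ``min_reads_either_sex`` in females *or* in males.  The sex mean is
    the unweighted mean of per-sample fractions over samples with any
    coverage; a sex with no covered sample is left undefined (NaN) rather
    than dropping the site.
    """
    sub = table.subset(chrom, start0 - flank, end0 + flank)
    females = [s for s in sub.samples if sex_of[s] == "female"]
    males = [s for s in sub.samples if sex_of[s] == "male"]
    m, cov = sub.m(), sub.coverage()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = m / cov
    frac = frac.where(cov > 0)

    f_pooled = cov[females].sum(axis=1)
    m_pooled = cov[males].sum(axis=1)
    keep = (f_pooled >= min_reads_either_sex) | (m_pooled >= min_reads_either_sex)
    out = pd.DataFrame(
        {
            "female_mean": frac[females].mean(axis=1)[keep],
            "male_mean": frac[males].mean(axis=1)[keep],
            "coverage_female": f_pooled[keep],
            "coverage_male": m_pooled[keep],
        }
    )
    out["delta_fm"] = out["female_mean"] - out["male_mean"]
    return out.reset_index()
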