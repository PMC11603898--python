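"""Core methylome operations on per-cytosine counts.

WGBS reports one row per cytosine per strand.  CpG methylation is
symmetric, so the two cytosines of one CpG — the ``+`` strand C at position
``p`` and the ``-`` strand C at ``p+1`` — are merged into a single site
keyed by ``p`` before any site-level statistic is computed.

Two region statistics are supported, following the standard definitions:

* *weighted* methylation: sum of methylated reads over sum of all reads
  across the region's sites — coverage-weighted by construction;
* *mean* methylation: the unweighted average of per-site fractional
  methylation over sites passing the coverage filter (default >= 5 reads),
  reported only when more than ``min_sites`` sites qualify (default > 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_COVERAGE = 5
DEFAULT_MIN_SITES = 3  # "more than three CpG sites": strictly > 3 qualify


class DuplicateSiteError(ValueError):
    pass


# ---------------------------------------------------------------------------
# strand merging
# ---------------------------------------------------------------------------

def merge_symmetric_cpgs(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-strand CG records into strand-merged CpG sites.

    Parameters
    ----------
    records:
        Frame with columns ``chrom, pos0, strand, m, u`` (CG context only).

    Returns
    -------
    Frame with columns ``chrom, pos0, m, u`` where ``pos0`` is the
    position of the + strand cytosine.  A ``-`` strand record at ``p`` is
    assigned to site ``p - 1`` whether or not its partner was observed, so
    unpaired records are kept and total counts are conserved.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["chrom", "pos0", "m", "u"]).astype(
            {"pos0": np.int64, "m": np.int64, "u": np.int64}
        )
    for strand in ("+", "-"):
        sub = records[records["strand"] == strand]
        if sub.duplicated(subset=["chrom", "pos0"]).any():
            dup = sub[sub.duplicated(subset=["chrom", "pos0"])].iloc[0]
            raise DuplicateSiteError(
                f"duplicate {strand} strand record at {dup['chrom']}:{dup['pos0']}"
            )
    site_pos = records["pos0"].to_numpy(copy=True)
    site_pos[records["strand"].to_numpy() == "-"] -= 1
    merged = (
        pd.DataFrame(
            {
                "chrom": records["chrom"].to_numpy(),
                "pos0": site_pos,
                "m": records["m"].to_numpy(),
                "u": records["u"].to_numpy(),
            }
        )
        .groupby(["chrom", "pos0"], as_index=False, sort=True)[["m", "u"]]
        .sum()
    )
    return merged


# ---------------------------------------------------------------------------
# multi-sample site table
# ---------------------------------------------------------------------------

class CpGSiteTable:
    """Strand-merged CpG counts for a set of samples.

    Internally a wide frame indexed by ``(chrom, pos0)`` with one ``m`` and
    one ``u`` column per sample (column MultiIndex ``(sample, 'm'|'u')``);
    sites absent from a sample's report carry zero counts.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts.columns, pd.MultiIndex):
            raise ValueError("counts must have (sample, m/u) MultiIndex columns")
        self.counts = counts.sort_index()

    @classmethod
    def from_sample_frames(cls, per_sample: Mapping[str, pd.DataFrame]) -> "CpGSiteTable":
        """Build from per-sample merged frames (``chrom, pos0, m, u``)."""
        pieces = {}
        for sample, df in per_sample.items():
            pieces[sample] = df.set_index(["chrom", "pos0"])[["m", "u"]]
        wide = pd.concat(pieces, axis=1).fillna(0)
        wide = wide.astype(np.int64)
        wide.columns.names = ["sample", "count"]
        return cls(wide)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    def m(self) -> pd.DataFrame:
        return self.counts.xs("m", axis=1, level="count")

    def u(self) -> pd.DataFrame:
        return self.counts.xs("u", axis=1, level="count")

    def coverage(self) -> pd.DataFrame:
        return self.m() + self.u()

    def __len__(self) -> int:
        return len(self.counts)

    def subset(self, chrom: str, start0: int | None = None, end0: int | None = None) -> "CpGSiteTable":
        sub = self.counts.loc[[chrom]] if chrom in self.counts.index.get_level_values(0) else self.counts.iloc[0:0]
        if start0 is not None or end0 is not None:
            pos = sub.index.get_level_values("pos0")
            mask = np.ones(len(sub), dtype=bool)
            if start0 is not None:
                mask &= pos >= start0
            if end0 is not None:
                mask &= pos < end0
            sub = sub[mask]
        return CpGSiteTable(sub)


# ---------------------------------------------------------------------------
# site-level fractional methylation
# ---------------------------------------------------------------------------

@dataclass
class SiteMethylationResult:
    fractions: pd.DataFrame          # (chrom, pos0) x sample, NaN below cutoff
    coverage: pd.DataFrame           # (chrom, pos0) x sample
    qualifying_proportion: pd.Series  # per sample, fraction of sites >= cutoff
    min_coverage: int


def site_fractional_methylation(
    table: CpGSiteTable, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> SiteMethylationResult:
    """Fraction methylated per merged site per sample, with coverage filter.

    A fraction is emitted only where the site's coverage in that sample is
    at least ``min_coverage`` (default 5 reads); other cells are NaN.
    """
    m, cov = table.m(), table.coverage()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = m / cov
    frac = frac.where(cov >= min_coverage)
    qualifying = (cov >= min_coverage).mean(axis=0)
    return SiteMethylationResult(frac, cov, qualifying, min_coverage)


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

@dataclass
class RegionMethylSummary:
    region_id: str
    group: str                 # sample id or sex label
    weighted: float            # sum(m)/sum(m+u), NaN if no covered site
    mean: float                # mean of qualifying site fractions, NaN if too few
    n_sites_qualifying: int
    n_sites_total: int
    reason: str = ""           # set when a statistic is undefined


def _summarise_counts(
    region_id: str,
    group: str,
    m: np.ndarray,
    u: np.ndarray,
    min_coverage: int,
    min_sites: int,
) -> RegionMethylSummary:
    cov = m + u
    covered = cov > 0
    total_reads = cov.sum()
    weighted = float(m.sum() / total_reads) if total_reads > 0 else float("nan")
    qual = cov >= min_coverage
    n_qual = int(qual.sum())
    if n_qual > min_sites:
        mean = float((m[qual] / cov[qual]).mean())
        reason = ""
    else:
        mean = float("nan")
        reason = f"<= {min_sites} qualifying sites"
    if total_reads == 0:
        reason = "no covered sites"
    return RegionMethylSummary(
        region_id, group, weighted, mean, n_qual, int(covered.sum()), reason
    )


def region_methylation(
    table: CpGSiteTable,
    chrom: str,
    start0: int,
    end0: int,
    region_id: str = "",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_sites: int = DEFAULT_MIN_SITES,
    sex_of: Mapping[str, str] | None = None,
) -> list[RegionMethylSummary]:
    """Weighted and mean methylation of one region.

    Per sample by default.  With ``sex_of`` mapping sample -> sex label,
    summaries are produced per sex instead: weighted mode pools raw counts
    across the sex's samples (one big count pool), while mean mode averages
    per-site fractions computed from the pooled counts.
    """
    if end0 <= start0:
        raise ValueError(f"empty region {chrom}:{start0}-{end0}")
    sub = table.subset(chrom, start0, end0)
    out = []
    if sex_of is None:
        for sample in sub.samples:
            m = sub.counts[(sample, "m")].to_numpy()
            u = sub.counts[(sample, "u")].to_numpy()
            out.append(_summarise_counts(region_id, sample, m, u, min_coverage, min_sites))
    else:
        by_sex: dict[str, list[str]] = {}
        for sample in sub.samples:
            by_sex.setdefault(sex_of[sample], []).append(sample)
        for sex, samples in sorted(by_sex.items()):
            m = sum(sub.counts[(s, "m")].to_numpy() for s in samples)
            u = sum(sub.counts[(s, "u")].to_numpy() for s in samples)
            out.append(_summarise_counts(region_id, sex, m, u, min_coverage, min_sites))
    return out


def regions_methylation_frame(
    table: CpGSiteTable,
    regions: Sequence[tuple[str, str, int, int]],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_sites: int = DEFAULT_MIN_SITES,
    sex_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`region_methylation` over many regions.

    ``regions`` is a sequence of ``(region_id, chrom, start0, end0)``.
    Returns a long frame with one row per region x group.
    """
    idx_chrom = table.counts.index.get_level_values(0).to_numpy()
    idx_pos = table.counts.index.get_level_values(1).to_numpy()

    if sex_of is None:
        groups = {s: [s] for s in table.samples}
    else:
        groups = {}
        for s in table.samples:
            groups.setdefault(sex_of[s], []).append(s)

    group_m = {
        g: sum(table.counts[(s, "m")].to_numpy() for s in ss) for g, ss in groups.items()
    }
    group_u = {
        g: sum(table.counts[(s, "u")].to_numpy() for s in ss) for g, ss in groups.items()
    }

    # per-chrom sorted position index for fast interval slicing
    order_by_chrom: dict[str, np.ndarray] = {}
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in pd.unique(idx_chrom):
        sel = np.flatnonzero(idx_chrom == chrom)
        order_by_chrom[chrom] = sel
        pos_by_chrom[chrom] = idx_pos[sel]

    rows = []
    for region_id, chrom, start0, end0 in regions:
        if chrom in pos_by_chrom:
            pos = pos_by_chrom[chrom]
            lo, hi = np.searchsorted(pos, [start0, end0])
            sel = order_by_chrom[chrom][lo:hi]
        else:
            sel = np.array([], dtype=int)
        for g in groups:
            s = _summarise_counts(
                region_id, g, group_m[g][sel], group_u[g][sel], min_coverage, min_sites
            )
            rows.append(
                (s.region_id, s.group, s.weighted, s.mean, s.n_sites_qualifying,
                 s.n_sites_total, s.reason)
            )
    return pd.DataFrame(
        rows,
        columns=["region_id", "group", "weighted", "mean", "n_sites_qualifying",
                 "n_sites_total", "reason"],
    )


# ---------------------------------------------------------------------------
# read-count downsampling
# ---------------------------------------------------------------------------

def downsample_counts(
    table: CpGSiteTable, keep_fraction: float, seed: int
) -> CpGSiteTable:
    """Binomially thin methylated and unmethylated counts independently.

    Each read is retained with probability ``keep_fraction``, emulating
    random read subsampling at the count level (expectation-equivalent).
    Deterministic under ``seed``.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return CpGSiteTable(table.counts.copy())
    rng = np.random.default_rng(seed)
    vals = table.counts.to_numpy()
    thinned = rng.binomial(vals, keep_fraction)
    return CpGSiteTable(
        pd.DataFrame(thinned, index=table.counts.index, columns=table.counts.columns)
    )
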