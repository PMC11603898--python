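"""Read-depth-based sex-linkage classification of contigs.

WGBS read depth carries chromosome dosage: with a diploid female (XX) and
a male (XY), X-linked sequence is covered roughly twice as deeply in
females as in males, Y-linked sequence is covered only in males, and
autosomes are covered equally.  For each contig the per-sex mean cytosine
depth (CG context, per-strand cytosines, averaged first within and then
across same-sex samples) gives the metric::

    D = 1 - mean_depth_female / mean_depth_male

with expected values near 0 (autosomal), -1 (X-linked) and 1 (Y-linked).
Classification uses fixed thresholds: Y if D > 0.95, autosomal if
-0.5 <= D <= 0.5, X if D < -0.5; the gap (0.5, 0.95] is left
unclassified, as are contigs with at most 40 informative cytosines or no
male coverage.

A windowed variant of the same comparison scans an assembled chromosome
for female-absent intervals (misassembled Y material) and PAR-like
intervals (female:male depth ratio near 1 on an X chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

MIN_CYTOSINES = 40
Y_THRESHOLD = 0.95
AUTOSOME_BAND = 0.5


@dataclass
class ContigDepthRecord:
    contig: str
    n_cytosines: int
    mean_depth_female: float
    mean_depth_male: float
    eligible: bool


@dataclass
class SexLinkageCall:
    contig: str
    d: float
    label: str           # 'Y' | 'A' | 'X' | 'unclassified'
    reason: str = ""


def contig_depth_summary(
    per_sample: Mapping[str, pd.DataFrame],
    sex_of: Mapping[str, str],
    min_cytosines: int = MIN_CYTOSINES,
) -> list[ContigDepthRecord]:
    """Per-contig mean cytosine depth per sex.

    ``per_sample`` maps sample id -> pre-merge CG records
    (``chrom, pos0, strand, m, u``).  Depth at a cytosine is ``m + u``.
    Per sample, depth is averaged over that contig's cytosines; per sex,
    the per-sample means are averaged unweighted.  ``n_cytosines`` counts
    cytosines with nonzero depth in at least one sample; contigs with
    ``n_cytosines <= min_cytosines`` are flagged ineligible.
    """
    for s in per_sample:
        if sex_of.get(s) not in ("female", "male"):
            raise ValueError(f"unknown sex label for sample {s!r}: {sex_of.get(s)}")

    contigs: dict[str, dict] = {}
    covered: dict[str, set] = {}
    per_sample_means: dict[str, dict[str, float]] = {}
    for sample, df in per_sample.items():
        depth = (df["m"] + df["u"]).to_numpy()
        grouped = pd.DataFrame({"chrom": df["chrom"], "depth": depth}).groupby("chrom")["depth"]
        per_sample_means[sample] = grouped.mean().to_dict()
        has_cov = df.loc[depth > 0, ["chrom", "pos0", "strand"]]
        for chrom, sub in has_cov.groupby("chrom"):
            covered.setdefault(chrom, set()).update(
                zip(sub["pos0"].to_numpy(), sub["strand"].to_numpy())
            )
        for chrom in pd.unique(df["chrom"]):
            contigs.setdefault(chrom, {})

    records = []
    for contig in sorted(contigs):
        f_means = [
            per_sample_means[s].get(contig, 0.0)
            for s in per_sample if sex_of[s] == "female"
        ]
        m_means = [
            per_sample_means[s].get(contig, 0.0)
            for s in per_sample if sex_of[s] == "male"
        ]
        n_cyt = len(covered.get(contig, ()))
        records.append(
            ContigDepthRecord(
                contig=contig,
                n_cytosines=n_cyt,
                mean_depth_female=float(np.mean(f_means)) if f_means else float("nan"),
                mean_depth_male=float(np.mean(m_means)) if m_means else float("nan"),
                eligible=n_cyt > min_cytosines,
            )
        )
    return records


def classify_contig(record: ContigDepthRecord) -> SexLinkageCall:
    """Deterministic class from the depth-ratio metric D = 1 - F/M."""
    if not record.eligible:
        return SexLinkageCall(record.contig, float("nan"), "unclassified",
                              f"n_cytosines {record.n_cytosines} <= threshold")
    m = record.mean_depth_male
    if not np.isfinite(m) or m == 0:
        return SexLinkageCall(record.contig, float("nan"), "unclassified",
                              "no male coverage")
    d = 1.0 - record.mean_depth_female / m
    if d > Y_THRESHOLD:
        label, reason = "Y", ""
    elif -AUTOSOME_BAND <= d <= AUTOSOME_BAND:
        label, reason = "A", ""
    elif d < -AUTOSOME_BAND:
        label, reason = "X", ""
    else:
        label, reason = "unclassified", f"D in gap ({AUTOSOME_BAND}, {Y_THRESHOLD}]"
    return SexLinkageCall(record.contig, float(d), label, reason)


def classify_contigs(records) -> pd.DataFrame:
    calls = [classify_contig(r) for r in records]
    return pd.DataFrame(
        {
            "contig": [c.contig for c in calls],
            "D": [c.d for c in calls],
            "label": [c.label for c in calls],
            "reason": [c.reason for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# windowed depth anomaly scan
# ---------------------------------------------------------------------------

def windowed_depth_scan(
    per_sample: Mapping[str, pd.DataFrame],
    sex_of: Mapping[str, str],
    chrom: str,
    window: int = 100_000,
    absent_threshold: float = 0.5,
    present_threshold: float = 5.0,
    par_band: float = 0.2,
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Scan one chromosome for sex-specific depth anomalies.

    Windows are flagged ``female_absent`` when mean female depth falls
    below ``absent_threshold`` while male depth is at least
    ``present_threshold`` (putative misassembled Y material), ``PAR_like``
    when |1 - F/M| < ``par_band`` (equal coverage, as in a pseudoautosomal
    region), else ``normal``.  Windows without cytosines are skipped.
    Contiguous ``female_absent`` windows are merged into exclusion
    intervals, returned alongside the window frame.
    """
    females = [s for s in per_sample if sex_of[s] == "female"]
    males = [s for s in per_sample if sex_of[s] == "male"]

    frames = {}
    max_pos = 0
    for sample, df in per_sample.items():
        sub = df[df["chrom"] == chrom]
        frames[sample] = sub
        if len(sub):
            max_pos = max(max_pos, int(sub["pos0"].max()))
    n_windows = max_pos // window + 1

    def sex_window_means(samples):
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows)
        per_sample_mean = np.zeros((len(samples), n_windows))
        per_sample_has = np.zeros((len(samples), n_windows), dtype=bool)
        for i, s in enumerate(samples):
            sub = frames[s]
            if not len(sub):
                continue
            w = (sub["pos0"].to_numpy() // window).astype(int)
            depth = (sub["m"] + sub["u"]).to_numpy()
            sums[:] = 0
            counts[:] = 0
            np.add.at(sums, w, depth)
            np.add.at(counts, w, 1)
            has = counts > 0
            per_sample_has[i] = has
            with np.errstate(invalid="ignore"):
                per_sample_mean[i][has] = sums[has] / counts[has]
        any_has = per_sample_has.any(axis=0)
        means = np.full(n_windows, np.nan)
        if len(samples):
            with np.errstate(invalid="ignore"):
                vals = np.where(per_sample_has, per_sample_mean, np.nan)
                means[any_has] = np.nanmean(vals[:, any_has], axis=0)
        return means, any_has

    f_mean, f_has = sex_window_means(females)
    m_mean, m_has = sex_window_means(males)

    rows = []
    for w in range(n_windows):
        if not (f_has[w] or m_has[w]):
            continue  # no cytosines in window
        f = f_mean[w] if f_has[w] else 0.0
        m = m_mean[w] if m_has[w] else 0.0
        if f < absent_threshold and m >= present_threshold:
            flag = "female_absent"
        elif m > 0 and abs(1.0 - f / m) < par_band:
            flag = "PAR_like"
        else:
            flag = "normal"
        rows.append((chrom, w * window, (w + 1) * window, f, m, flag))
    windows_df = pd.DataFrame(
        rows, columns=["chrom", "start0", "end0", "mean_depth_female",
                       "mean_depth_male", "flag"]
    )

    excluded: list[list[int]] = []
    for _, row in windows_df[windows_df["flag"] == "female_absent"].iterrows():
        s, e = int(row["start0"]), int(row["end0"])
        if excluded and s <= excluded[-1][1]:
            excluded[-1][1] = e
        else:
            excluded.append([s, e])
    return windows_df, [tuple(x) for x in excluded]


# ---------------------------------------------------------------------------
# per-class contig methylation
# ---------------------------------------------------------------------------

def contig_class_methylation(
    calls: pd.DataFrame,
    site_fractions: pd.DataFrame,
) -> pd.DataFrame:
    """Mean methylation per contig per sample, labelled by linkage class.

    ``site_fractions`` is the coverage-filtered (chrom, pos0) x sample
    fraction frame; the contig mean is the unweighted mean of its
    qualifying site fractions.  Samples with no qualifying site on a
    contig (e.g. females on Y contigs) contribute no value.
    """
    label_of = dict(zip(calls["contig"], calls["label"]))
    per_contig = site_fractions.groupby(level=0).mean()
    long = per_contig.stack().rename("mean_meth").reset_index()
    long.columns = ["contig", "sample", "mean_meth"]
    long["label"] = long["contig"].map(label_of).fillna("unknown")
    return long.dropna(subset=["mean_meth"]).reset_index(drop=True)
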