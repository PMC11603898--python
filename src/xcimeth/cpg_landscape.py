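"""CpG composition statistics: sliding-window observed/expected ratios,
promoter CpG counts, and a Gardiner–Garden-style CpG-island scan.

The O/E ratio of a window of non-N length ``L`` is::

    O/E = (n_CpG * L) / (n_C * n_G)

i.e. the observed CpG dinucleotide count relative to the expectation from
the window's C and G composition.  Values near 1 indicate CpG-island-like
sequence; bulk vertebrate genome sits far below 1 because methylated CpGs
are depleted by deamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .meth_io import GeneModel

WINDOW_COLUMNS = [
    "chrom", "start0", "end0", "n_C", "n_G", "n_CpG", "length_non_n",
    "oe_ratio", "oe_defined", "partial",
]


def _base_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cpg = np.zeros(arr.shape, dtype=bool)
    if len(arr) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]  # CpG counted at the C position
    return is_c, is_g, is_n, is_cpg


def sliding_window_oe(
    sequence: str,
    chrom: str = "",
    window: int = 1000,
    step: int = 500,
) -> pd.DataFrame:
    """CpG O/E over sliding windows (default 1000 bp, 500 bp overlap).

    N bases are excluded from all counts.  A trailing partial window is
    included, flagged ``partial``, iff it is at least ``window/2`` long.
    Windows with no C or no G have an undefined ratio (``oe_defined`` False).
    CpG dinucleotides are attributed to the window containing their C.
    """
    if window < step:
        raise ValueError("window must be >= step")
    is_c, is_g, is_n, is_cpg = _base_arrays(sequence)
    cum = lambda a: np.concatenate([[0], np.cumsum(a)])
    cc, cg, cn, ccpg = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)

    n = len(sequence)
    rows: list[tuple[int, int, bool]] = []
    s = 0
    while s + window <= n:
        rows.append((s, s + window, False))
        s += step
    # trailing partial window at the next start, iff >= half a window long
    if s < n and (n - s) >= window / 2:
        rows.append((s, n, True))

    out = []
    for s, e, partial in rows:
        ncc = int(cc[e] - cc[s])
        ngg = int(cg[e] - cg[s])
        ncpg = int(ccpg[e] - ccpg[s])
        length = (e - s) - int(cn[e] - cn[s])
        defined = ncc > 0 and ngg > 0
        oe = (ncpg * length) / (ncc * ngg) if defined else float("nan")
        out.append((chrom, s, e, ncc, ngg, ncpg, length, oe, defined, partial))
    return pd.DataFrame(out, columns=WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# window annotation
# ---------------------------------------------------------------------------

def annotate_windows(windows: pd.DataFrame, genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Label each window promoter / gene_body / intergenic by its center.

    A window is a promoter window if its center base falls inside any
    gene's 2-kb promoter; promoter takes precedence over gene body when
    intervals overlap; anything else is intergenic.
    """
    promoters: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for g in genes:
        ps, pe = g.promoter
        if pe > ps:
            promoters.setdefault(g.chrom, IntervalTree()).addi(ps, pe)
        bs, be = g.gene_body
        bodies.setdefault(g.chrom, IntervalTree()).addi(bs, be)

    labels = []
    for chrom, s, e in zip(windows["chrom"], windows["start0"], windows["end0"]):
        center = (s + e) // 2
        if chrom in promoters and promoters[chrom].overlaps_point(center):
            labels.append("promoter")
        elif chrom in bodies and bodies[chrom].overlaps_point(center):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    annotated = windows.copy()
    annotated["annotation"] = labels
    return annotated


# ---------------------------------------------------------------------------
# promoter CpG counts
# ---------------------------------------------------------------------------

def promoter_cpg_count(
    genes: Iterable[GeneModel],
    sequences: Mapping[str, str] | None = None,
    site_positions: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Number of CpG dinucleotides in each gene's 2-kb promoter.

    Exactly one of ``sequences`` (count CG dinucleotides in the sequence)
    or ``site_positions`` (count strand-merged CpG sites per chrom, sorted
    0-based positions) must be given; the mode used is recorded.
    """
    if (sequences is None) == (site_positions is None):
        raise ValueError("give exactly one of sequences / site_positions")
    rows = []
    if sequences is not None:
        cpg_cum: dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            *_, is_cpg = _base_arrays(seq)
            cpg_cum[chrom] = np.concatenate([[0], np.cumsum(is_cpg)])
        for g in genes:
            s, e = g.promoter
            cum = cpg_cum[g.chrom]
            n = int(cum[min(e, len(cum) - 1)] - cum[min(s, len(cum) - 1)])
            rows.append((g.gene_id, n, "sequence"))
    else:
        for g in genes:
            s, e = g.promoter
            pos = site_positions.get(g.chrom, np.array([], dtype=int))
            lo, hi = np.searchsorted(pos, [s, e])
            rows.append((g.gene_id, int(hi - lo), "site_table"))
    return pd.DataFrame(rows, columns=["gene_id", "n_cpg", "mode"])


# ---------------------------------------------------------------------------
# CpG island scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start0: int
    end0: int
    gc_content: float
    oe_ratio: float


def cpg_island_scan(
    sequence: str,
    chrom: str = "",
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    step: int = 50,
) -> list[CpGIsland]:
    """Scan for CpG islands with Gardiner–Garden-style criteria.

    Windows of ``min_len`` advanced by ``step`` must satisfy GC content
    >= ``min_gc`` and CpG O/E >= ``min_oe``; overlapping or adjacent
    qualifying windows are merged into maximal intervals, whose summary
    statistics are recomputed over the merged span.
    """
    is_c, is_g, is_n, is_cpg = _base_arrays(sequence)
    cum = lambda a: np.concatenate([[0], np.cumsum(a)])
    cc, cg, cn, ccpg = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)

    n = len(sequence)
    qualifying: list[tuple[int, int]] = []
    for s in range(0, n - min_len + 1, step):
        e = s + min_len
        ncc = cc[e] - cc[s]
        ngg = cg[e] - cg[s]
        ncpg = ccpg[e] - ccpg[s]
        length = (e - s) - (cn[e] - cn[s])
        if length == 0 or ncc == 0 or ngg == 0:
            continue
        gc = (ncc + ngg) / length
        oe = (ncpg * length) / (ncc * ngg)
        if gc >= min_gc and oe >= min_oe:
            qualifying.append((s, e))

    merged: list[list[int]] = []
    for s, e in qualifying:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    islands = []
    for s, e in merged:
        if e - s < min_len:
            continue
        ncc = cc[e] - cc[s]
        ngg = cg[e] - cg[s]
        ncpg = ccpg[e] - ccpg[s]
        length = (e - s) - (cn[e] - cn[s])
        gc = (ncc + ngg) / length if length else float("nan")
        oe = (ncpg * length) / (ncc * ngg) if ncc and ngg else float("nan")
        # the merged span must itself satisfy the criteria, otherwise a
        # short dense CpG cluster could ride in on its flanking windows
        if not (gc >= min_gc and oe >= min_oe):
            continue
        islands.append(CpGIsland(chrom, int(s), int(e), float(gc), float(oe)))
    return islands
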