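"""Readers and writers for the external formats the pipeline consumes.

Every reader normalises coordinates into the package-wide convention:
**0-based, half-open** intervals, with single positions giving the 0-based
offset of the cytosine on the + strand.  Dialect shifts are applied on
ingest (cytosine reports and GTF are 1-based; BED12 is already 0-based
half-open) so that no other module ever sees a 1-based coordinate.

Formats handled here:

* Bismark-style per-cytosine reports
  (``chrom  pos  strand  count_methylated  count_unmethylated  context  tri_context``)
* gene annotation as GTF (via :mod:`gffutils`) or BED12
* per-gene expression tables (TSV, one abundance column per sample)
* methylation-extractor-style per-read CpG call records
  (``read_id  strand_flag  chrom  pos  call``, ``Z`` methylated / ``z`` not)

All readers transparently accept gzip-compressed files (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROMOTER_BP = 2000

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})

CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "tri_context",
]

READ_CALL_COLUMNS = ["read_id", "strand_flag", "chrom", "pos", "call"]


class FormatError(ValueError):
    """A file violated its declared dialect; message carries the location."""


def _opener(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path, contexts: Sequence[str] | None = ("CG",)) -> pd.DataFrame:
    """Read a per-cytosine report into a tidy frame.

    Parameters
    ----------
    path:
        TSV with columns ``chrom, pos (1-based), strand, count_methylated,
        count_unmethylated, context, tri_context`` and no header.
    contexts:
        Keep only rows whose context is in this set; ``None`` keeps all.

    Returns
    -------
    DataFrame with columns ``chrom, pos0, strand, m, u, context`` where
    ``pos0`` is 0-based.  Malformed rows raise :class:`FormatError` naming
    the 1-based line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CYTOSINE_REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "tri_context": str,
            },
            comment="#",
            compression="infer",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            columns=["chrom", "pos0", "strand", "m", "u", "context"]
        ).astype({"pos0": np.int64, "m": np.int64, "u": np.int64})

    for col in ("pos", "count_methylated", "count_unmethylated"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise FormatError(f"{path}: line {line}: non-integer value in column {col!r}")
        df[col] = coerced.astype(np.int64)

    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise FormatError(
            f"{path}: line {line}: unknown strand {df['strand'].iloc[line - 1]!r}"
        )
    neg = (df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)
    if neg.any():
        line = int(neg.idxmax()) + 1
        raise FormatError(f"{path}: line {line}: negative count")
    if (df["pos"] < 1).any():
        line = int((df["pos"] < 1).idxmax()) + 1
        raise FormatError(f"{path}: line {line}: position < 1 in a 1-based file")
    bad_ctx = ~df["context"].isin(VALID_CONTEXTS)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        raise FormatError(
            f"{path}: line {line}: unknown context {df['context'].iloc[line - 1]!r}"
        )

    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos0": df["pos"] - 1,  # 1-based file -> 0-based internal
            "strand": df["strand"],
            "m": df["count_methylated"],
            "u": df["count_unmethylated"],
            "context": df["context"],
        }
    )
    if contexts is not None:
        out = out[out["context"].isin(set(contexts))].reset_index(drop=True)
    return out


def write_cytosine_report(records: pd.DataFrame, path, tri_context: str = "CGN") -> None:
    """Write records (``chrom, pos0, strand, m, u, context``) back to the
    1-based report dialect.  Inverse of :func:`read_cytosine_report`."""
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "pos": records["pos0"] + 1,
            "strand": records["strand"],
            "count_methylated": records["m"],
            "count_unmethylated": records["u"],
            "context": records["context"],
            "tri_context": records.get("tri_context", tri_context),
        }
    )
    with _opener(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with its derived analysis intervals.

    The gene body is the span of the *longest transcript*; the promoter is
    the 2-kb interval immediately upstream of the gene body's start on the
    gene's own strand, truncated (never extended) at contig boundaries.
    All intervals are 0-based half-open.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"
    contig_length: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        for s, e in self.transcripts:
            if e <= s or s < 0:
                raise ValueError(f"gene {self.gene_id}: bad transcript interval ({s},{e})")
            if self.contig_length is not None and e > self.contig_length:
                raise ValueError(
                    f"gene {self.gene_id}: transcript ({s},{e}) outside contig "
                    f"of length {self.contig_length}"
                )

    @property
    def gene_body(self) -> tuple[int, int]:
        return max(self.transcripts, key=lambda t: (t[1] - t[0], -t[0]))

    @property
    def tss0(self) -> int:
        s, e = self.gene_body
        return s if self.strand == "+" else e - 1

    @property
    def promoter(self) -> tuple[int, int]:
        s, e = self.gene_body
        if self.strand == "+":
            lo, hi = s - PROMOTER_BP, s
        else:
            lo, hi = e, e + PROMOTER_BP
        lo = max(lo, 0)
        if self.contig_length is not None:
            hi = min(hi, self.contig_length)
        return (lo, min(lo, hi) if hi < lo else hi)

    @property
    def promoter_truncated(self) -> bool:
        lo, hi = self.promoter
        return (hi - lo) < PROMOTER_BP


@dataclass
class AnnotationReadResult:
    genes: list[GeneModel]
    n_excluded_strandless: int = 0
    excluded_ids: list[str] = field(default_factory=list)


def read_gene_annotation(
    path,
    fmt: str = "gtf",
    contig_lengths: dict[str, int] | None = None,
) -> AnnotationReadResult:
    """Load gene models from GTF (1-based inclusive) or BED12 (0-based).

    One :class:`GeneModel` is built per ``gene_id``, taking the longest
    transcript as the gene body.  Records without strand information are
    excluded and counted rather than guessed.
    """
    fmt = fmt.lower()
    if fmt == "gtf":
        return _read_gtf(path, contig_lengths)
    if fmt == "bed12":
        return _read_bed12(path, contig_lengths)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gtf(path, contig_lengths) -> AnnotationReadResult:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    strandless: list[str] = []
    for tx in db.features_of_type("transcript"):
        gid = tx.attributes.get("gene_id", [tx.id])[0]
        if tx.strand not in ("+", "-"):
            strandless.append(gid)
            continue
        biotype = tx.attributes.get(
            "gene_biotype", tx.attributes.get("gene_type", ["protein_coding"])
        )[0]
        entry = per_gene.setdefault(
            gid, {"chrom": tx.seqid, "strand": tx.strand, "biotype": biotype, "tx": []}
        )
        # GTF is 1-based inclusive -> 0-based half-open
        entry["tx"].append((tx.start - 1, tx.end))
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=e["chrom"],
            strand=e["strand"],
            transcripts=tuple(sorted(e["tx"])),
            biotype=e["biotype"],
            contig_length=(contig_lengths or {}).get(e["chrom"]),
        )
        for gid, e in per_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.gene_body[0], g.gene_id))
    return AnnotationReadResult(genes, len(strandless), strandless)


def _read_bed12(path, contig_lengths) -> AnnotationReadResult:
    per_gene: dict[str, dict] = {}
    strandless: list[str] = []
    with _opener(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {ln}: BED12 needs >= 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                strandless.append(name)
                continue
            entry = per_gene.setdefault(
                name, {"chrom": chrom, "strand": strand, "biotype": "protein_coding", "tx": []}
            )
            entry["tx"].append((int(start), int(end)))
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=e["chrom"],
            strand=e["strand"],
            transcripts=tuple(sorted(e["tx"])),
            biotype=e["biotype"],
            contig_length=(contig_lengths or {}).get(e["chrom"]),
        )
        for gid, e in per_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.gene_body[0], g.gene_id))
    return AnnotationReadResult(genes, len(strandless), strandless)


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Emit gene models as minimal transcript-level GTF (1-based inclusive)."""
    with _opener(path, "wt") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_body[0], g.gene_id)):
            for i, (s, e) in enumerate(g.transcripts):
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t{i + 1}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\txcimeth\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(
    path, expected_samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read a per-gene expression TSV (``gene_id`` + one column per sample).

    Abundances must be non-negative; duplicate gene ids and missing expected
    sample columns raise :class:`FormatError`.
    Returns a frame indexed by gene_id.
    """
    df = pd.read_csv(path, sep="\t", compression="infer")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing 'gene_id' column")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    df = df.set_index("gene_id")
    if expected_samples is not None:
        missing = [s for s in expected_samples if s not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: missing sample columns {missing}; expected {list(expected_samples)}"
            )
    if (df.select_dtypes(include=[np.number]) < 0).any().any():
        raise FormatError(f"{path}: negative abundance value")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    with _opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# per-read methylation calls
# ---------------------------------------------------------------------------

def read_read_calls(path) -> pd.DataFrame:
    """Read methylation-extractor-style CpG calls.

    Columns: ``read_id, strand_flag, chrom, pos (1-based), call`` with call
    ``Z`` (methylated CpG) or ``z`` (unmethylated CpG).  Returns a frame with
    ``read_id, chrom, pos0, methylated`` (bool).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=READ_CALL_COLUMNS,
            dtype={"read_id": str, "strand_flag": str, "chrom": str, "call": str},
            comment="#",
            compression="infer",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["read_id", "chrom", "pos0", "methylated"]).astype(
            {"pos0": np.int64, "methylated": bool}
        )
    bad = ~df["call"].isin(["Z", "z"])
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise FormatError(f"{path}: line {line}: call must be 'Z' or 'z'")
    return pd.DataFrame(
        {
            "read_id": df["read_id"],
            "chrom": df["chrom"],
            "pos0": df["pos"].astype(np.int64) - 1,
            "methylated": df["call"] == "Z",
        }
    )


def write_read_calls(df: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_read_calls` (strand flag written as '+')."""
    out = pd.DataFrame(
        {
            "read_id": df["read_id"],
            "strand_flag": "+",
            "chrom": df["chrom"],
            "pos": df["pos0"] + 1,
            "call": np.where(df["methylated"], "Z", "z"),
        }
    )
    with _opener(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# generic TSV round-trip
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    with _opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", compression="infer")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> dict of upper-case sequences (gzip transparent)."""
    with _opener(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with _opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
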