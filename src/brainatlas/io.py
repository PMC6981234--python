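"""Standard-format I/O: GTF 2.2, BED, and count-matrix TSVs.

Internal coordinates are 0-based half-open; GTF conversion to/from the
1-based closed convention happens only here.  Parse errors name the line.
"""
from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .containers import (
    METADATA_COLUMNS,
    CountMatrix,
    GenomicInterval,
    ParseError,
    TranscriptModel,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF into transcript models.

    Requires transcript_id and gene_id attributes on every exon line;
    transcripts are keyed by transcript_id, exons sorted by coordinate.
    """
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    lineno,
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer coordinates", lineno) from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(
                    f"invalid 1-based closed interval [{start}, {end}]", lineno
                )
            attr = dict(_ATTR_RE.findall(attrs))
            for required in ("transcript_id", "gene_id"):
                if required not in attr:
                    raise ParseError(f"missing attribute {required}", lineno)
            tid = attr["transcript_id"]
            rec = transcripts.setdefault(
                tid,
                {"gene_id": attr["gene_id"], "chrom": chrom, "strand": strand,
                 "exons": [], "attributes": {}},
            )
            rec["exons"].append((start_i - 1, end_i))  # to 0-based half-open
            for k, v in attr.items():
                if k not in ("transcript_id", "gene_id"):
                    rec["attributes"].setdefault(k, v)
    return [
        TranscriptModel(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], exons=rec["exons"],
            attributes=rec["attributes"],
        )
        for tid, rec in transcripts.items()
    ]


def write_gtf(transcripts: list[TranscriptModel], path,
              source: str = "brainatlas") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            extra = "".join(
                f' {k} "{v}";' for k, v in sorted(t.attributes.items())
            )
            base = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                + extra
            )
            fh.write(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.start + 1),
                     str(t.end), ".", t.strand, ".", base]
                ) + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(s + 1), str(e), ".",
                         t.strand, ".", base]
                    ) + "\n"
                )


def read_bed(path) -> list[GenomicInterval]:
    """BED3+ reader (0-based half-open, preserved exactly)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED needs >= 3 columns", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", lineno) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"invalid BED interval [{start}, {end})", lineno
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(fields[0], start, end, strand, name))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                f"{iv.strand}\n"
            )


def read_counts(path, metadata_path) -> CountMatrix:
    """Count TSV (genes x samples) plus metadata sidecar TSV.

    Metadata rows must match count columns exactly; entries must be
    non-negative integers.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    counts.columns.name = meta.index.name
    if list(counts.columns) != list(meta.index):
        raise ValueError(
            "sample columns of the count matrix do not match metadata rows"
        )
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    arr = counts.to_numpy()
    if not (arr == arr.astype(int)).all():
        raise ValueError("count matrix contains non-integer entries")
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")
    return CountMatrix(counts.astype(int), meta)


def write_counts(cm: CountMatrix, path, metadata_path) -> None:
    cm.counts.to_csv(path, sep="\t")
    cm.samples.to_csv(metadata_path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
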