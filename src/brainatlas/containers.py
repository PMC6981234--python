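"""Shared in-memory containers for the atlas pipeline.

Coordinates are 0-based half-open throughout the package (BED convention);
GTF I/O converts from/to the 1-based closed convention at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class BrainAtlasError(Exception):
    """Base class for package errors."""


class InvalidConfigError(BrainAtlasError, ValueError):
    """A simulation or run configuration is inconsistent."""


class DesignError(BrainAtlasError, ValueError):
    """The sample design is rank-deficient, unbalanced, or otherwise unusable."""


class DegenerateFitError(BrainAtlasError, ValueError):
    """A per-gene fit is degenerate (e.g. all-zero counts)."""


class ParseError(BrainAtlasError, ValueError):
    """A standard-format file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


METADATA_COLUMNS = ["individual", "sex", "age", "region", "replicate"]


@dataclass
class CountMatrix:
    """Gene-by-sample (or peak-by-sample) integer counts with sample metadata.

    ``counts``: DataFrame, features in rows, samples in columns.
    ``samples``: DataFrame indexed by sample id with columns
    individual, sex, age, region, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise DesignError("count columns do not match metadata sample ids")
        missing = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DesignError(f"metadata missing columns: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.samples)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusPeak:
    """A union-merged peak with per-input-set presence and reproducibility."""

    interval: GenomicInterval
    presence: dict[str, bool]

    @property
    def reproducibility(self) -> int:
        return sum(self.presence.values())


@dataclass
class TranscriptModel:
    """A transcript: ordered exons on a strand plus screening annotations.

    Exons are 0-based half-open, sorted, non-overlapping.  Annotation fields
    (class label, distance to the nearest protein-coding gene, coding-
    potential calls) are populated by the screening steps and may be None.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    tclass: str | None = None
    distance_to_coding: int | None = None
    coding_a: bool | None = None
    coding_b: bool | None = None
    min_expr_threshold: float | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"transcript {self.transcript_id}: strand must be +/-")
        exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if s < 0 or s >= e:
                raise ValueError(f"transcript {self.transcript_id}: bad exon ({s},{e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def tss(self) -> int:
        """First transcribed base: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.transcript_id)

    def copy(self, **changes) -> "TranscriptModel":
        out = replace(self)
        out.exons = [tuple(e) for e in self.exons]
        out.attributes = dict(self.attributes)
        for k, v in changes.items():
            setattr(out, k, v)
        return out


def geometric_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))
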