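"""Assembly evaluation (exon/intron F1 sweep) and lncRNA screening.

The assembly side scores an assembled transcript set against a reference
at the exon and intron level by exact-coordinate matching, combines
sensitivity and precision into F1, and picks the expression-filter
threshold as the mean of the per-level F1 argmaxes over the 0.5..9.5 grid.

The lncRNA side classifies novel transcripts against the reference
(exact match / exonic overlap / intragenic / antisense / intergenic),
combines two coding-potential predictions, and applies the filter cascade:
intergenic-or-antisense class, >= 1 kb from the nearest protein-coding
gene, called non-coding by at least one predictor, length >= 200 nt, and
at least two exons.  Every excluded transcript carries an audit of the
rule(s) that rejected it.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import TranscriptModel

THRESHOLD_GRID = [x / 2.0 for x in range(1, 20)]  # 0.5 .. 9.5 step 0.5


@dataclass
class MatchStats:
    threshold: float
    level: str               # 'exon' | 'intron'
    sensitivity: float
    precision: float

    @property
    def f1_score(self) -> float:
        return f1(self.sensitivity, self.precision)


def _features(transcripts, level: str) -> set[tuple]:
    """Unique (chrom, start, end, strand) features at the requested level."""
    out = set()
    for t in transcripts:
        parts = t.exons if level == "exon" else t.introns
        for s, e in parts:
            out.add((t.chrom, s, e, t.strand))
    return out


def match_stats(assembled, reference, level: str) -> tuple[float, float]:
    """Exact-coordinate (sensitivity, precision) at 'exon' or 'intron' level."""
    if level not in ("exon", "intron"):
        raise ValueError("level must be 'exon' or 'intron'")
    ref = _features(reference, level)
    asm = _features(assembled, level)
    if not ref or not asm:
        raise ValueError(f"empty {level} feature set")
    matched = ref & asm
    return len(matched) / len(ref), len(matched) / len(asm)


def f1(sensitivity: float, precision: float) -> float:
    """Harmonic mean 2SP/(S+P); zero when both are zero."""
    for v in (sensitivity, precision):
        if not 0.0 <= v <= 1.0:
            raise ValueError("sensitivity/precision must lie in [0, 1]")
    if sensitivity + precision == 0.0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def select_threshold(stats: list[MatchStats]) -> tuple[float, float, float]:
    """Per-level F1 argmaxes and their arithmetic mean as final threshold.

    The stats must cover both levels at every threshold of the grid; ties
    break toward the smaller threshold.
    """
    by_level: dict[str, dict[float, float]] = {"exon": {}, "intron": {}}
    for s in stats:
        by_level[s.level][s.threshold] = s.f1_score
    thresholds = sorted(
        set(by_level["exon"]) | set(by_level["intron"])
    )
    for level in ("exon", "intron"):
        missing = [t for t in thresholds if t not in by_level[level]]
        if missing:
            raise ValueError(f"missing {level}-level stats at {missing}")
    argmax = {}
    for level in ("exon", "intron"):
        best_t, best_f = None, -1.0
        for t in thresholds:  # ascending: ties go to smaller threshold
            if by_level[level][t] > best_f:
                best_t, best_f = t, by_level[level][t]
        argmax[level] = best_t
    final = (argmax["exon"] + argmax["intron"]) / 2.0
    return argmax["exon"], argmax["intron"], final


def combine_coding_calls(call_a: bool, call_b: bool) -> bool:
    """Coding only when both predictors call coding (maximal specificity)."""
    return bool(call_a and call_b)


# ---------------------------------------------------------------------------
# classification against the reference
# ---------------------------------------------------------------------------

def classify_transcripts(
    novel: list[TranscriptModel],
    reference: list[TranscriptModel],
    intergenic_min_distance: int = 1000,
) -> list[TranscriptModel]:
    """Assign each novel transcript a class and a distance to the nearest
    reference gene.

    exact_match: identical exon chain (same strand);
    exonic_overlap: shares >= 1 bp with a same-strand reference exon;
    intragenic: falls within a same-strand reference intron (gene body
    overlap without exon overlap);
    antisense: overlaps a reference gene span on the opposite strand only;
    intergenic: no gene-span overlap.

    The distance excludes opposite-strand genes the transcript overlaps
    (an antisense transcript's host does not count against the minimum-
    distance screen, which would otherwise empty the antisense class).
    """
    ref_chains = {
        (t.chrom, t.strand, tuple(t.exons)) for t in reference
    }
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in reference:
        by_chrom.setdefault(t.chrom, []).append(t)

    out = []
    for t in novel:
        refs = by_chrom.get(t.chrom, [])
        same_exon = False
        same_body = False
        anti_body = False
        min_dist = None
        for r in refs:
            dist = max(r.start - t.end, t.start - r.end, 0)
            overlap_span = t.start < r.end and r.start < t.end
            if not (overlap_span and r.strand != t.strand):
                if min_dist is None or dist < min_dist:
                    min_dist = dist
            if not overlap_span:
                continue
            if r.strand == t.strand:
                same_body = True
                if any(
                    es < re_ and rs < ee
                    for es, ee in t.exons for rs, re_ in r.exons
                ):
                    same_exon = True
            else:
                anti_body = True
        if (t.chrom, t.strand, tuple(t.exons)) in ref_chains:
            tclass = "exact_match"
        elif same_exon:
            tclass = "exonic_overlap"
        elif same_body:
            tclass = "intragenic"
        elif anti_body:
            tclass = "antisense"
        else:
            tclass = "intergenic"
        out.append(
            t.copy(tclass=tclass,
                   distance_to_coding=int(min_dist) if min_dist is not None
                   else None)
        )
    return out


def summarize_composition(class_counts: dict[str, int],
                          exact_match: int | None = None,
                          intergenic_coding: int | None = None
                          ) -> dict[str, float]:
    """Percentage composition of an assembled transcript set.

    ``class_counts`` partitions the set (exonic_overlap / intergenic /
    intragenic); each class's share of the total is returned in percent.
    ``exact_match`` is the perfect-match subset of the exonic-overlap
    class, reported against the same total; ``intergenic_coding`` is the
    coding-predicted subset of the intergenic class, reported as its share
    of the intergenic count.
    """
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("no transcripts to summarize")
    out = {k: 100.0 * v / total for k, v in class_counts.items()}
    if exact_match is not None:
        out["exact_match"] = 100.0 * exact_match / total
    if intergenic_coding is not None:
        n_inter = class_counts.get("intergenic", 0)
        if n_inter == 0:
            raise ValueError("no intergenic transcripts")
        out["intergenic_coding"] = 100.0 * intergenic_coding / n_inter
    return out


def composition_from_classes(classified: list[TranscriptModel],
                             ) -> tuple[dict[str, int], int]:
    """Fold mutually-exclusive class labels into the partition used for
    composition summaries (perfect matches count within exonic overlap);
    returns (partition counts, number of exact matches)."""
    counts: dict[str, int] = {}
    n_exact = 0
    for t in classified:
        cls = t.tclass or "unclassified"
        if cls == "exact_match":
            n_exact += 1
            cls = "exonic_overlap"
        counts[cls] = counts.get(cls, 0) + 1
    return counts, n_exact


# ---------------------------------------------------------------------------
# lncRNA filter cascade
# ---------------------------------------------------------------------------

LNC_RULES = ("class", "distance", "coding", "length", "exons")


def filter_lncrna(
    candidates: list[TranscriptModel],
    min_distance: int = 1000,
    min_length: int = 200,
    min_exons: int = 2,
    noncoding_mode: str = "either",
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Apply the lncRNA filter cascade; return survivors and a full audit.

    Rules (all must pass):
      class     in {intergenic, antisense}
      distance  >= min_distance bp from the nearest protein-coding gene
      coding    called non-coding by at least one predictor
                ('either'; set noncoding_mode='both' to require both)
      length    >= min_length nt (sum of exon lengths)
      exons     >= min_exons

    The audit has one row per candidate with a boolean per rule and the
    retained flag; excluded transcripts show exactly which rules failed.
    """
    if noncoding_mode not in ("either", "both"):
        raise ValueError("noncoding_mode must be 'either' or 'both'")
    rows = []
    survivors = []
    for t in candidates:
        for fieldname in ("tclass", "distance_to_coding", "coding_a", "coding_b"):
            if getattr(t, fieldname) is None:
                raise ValueError(
                    f"transcript {t.transcript_id}: missing annotation "
                    f"field '{fieldname}'"
                )
        noncoding_calls = (not t.coding_a, not t.coding_b)
        passes = {
            "class": t.tclass in ("intergenic", "antisense"),
            "distance": t.distance_to_coding >= min_distance,
            "coding": (any(noncoding_calls) if noncoding_mode == "either"
                       else all(noncoding_calls)),
            "length": t.length >= min_length,
            "exons": t.n_exons >= min_exons,
        }
        retained = all(passes.values())
        rows.append({"transcript_id": t.transcript_id, **passes,
                     "retained": retained})
        if retained:
            survivors.append(t)
    audit = pd.DataFrame(rows, columns=["transcript_id", *LNC_RULES, "retained"])
    return survivors, audit


def sweep_f1(
    assembled_by_threshold: dict[float, list[TranscriptModel]],
    reference: list[TranscriptModel],
) -> pd.DataFrame:
    """MatchStats table over a threshold sweep, both levels per threshold."""
    rows = []
    for t in sorted(assembled_by_threshold):
        for level in ("exon", "intron"):
            sens, prec = match_stats(assembled_by_threshold[t], reference, level)
            rows.append(
                {"threshold": t, "level": level, "sensitivity": sens,
                 "precision": prec, "f1": f1(sens, prec)}
            )
    return pd.DataFrame(rows)
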