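"""ATAC peak procedures: consensus merging, TMM normalization, peak-gene
correlation linking, TSS distance, genomic-feature annotation, chi-square
enrichment.

Consensus peaks are the transitive union-merge of region-wise peak sets
(any 1-bp overlap merges); each merged peak records which input sets
contributed, and the reproducibility label counts them.  Peak intensities
are TMM-normalized (trimmed mean of M-values against a reference sample)
and linked to same-chromosome gene expression by Pearson correlation with
BH-adjusted p-values (default gate r > 0.7, FDR < 0.1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConsensusPeak, GenomicInterval, TranscriptModel, geometric_mean


# ---------------------------------------------------------------------------
# consensus merging
# ---------------------------------------------------------------------------

def merge_consensus(
    peak_sets: dict[str, list[GenomicInterval]]
) -> list[ConsensusPeak]:
    """Union-merge all input sets; >= 1 bp overlap merges transitively.

    Presence marks input sets contributing at least one interval to the
    merged peak.  Output is sorted by (chrom, start) and independent of the
    order of the input sets.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    set_names = sorted(peak_sets)
    events = []
    for name in set_names:
        for iv in peak_sets[name]:
            events.append((iv.chrom, iv.start, iv.end, name))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    out: list[ConsensusPeak] = []
    cur = None  # [chrom, start, end, contributing names]
    for chrom, start, end, name in events:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(name)
        else:
            if cur is not None:
                out.append(_close_consensus(cur, set_names))
            cur = [chrom, start, end, {name}]
    if cur is not None:
        out.append(_close_consensus(cur, set_names))
    return out


def _close_consensus(cur, set_names) -> ConsensusPeak:
    chrom, start, end, contributing = cur
    n = sum(1 for s in set_names if s in contributing)
    iv = GenomicInterval(chrom, start, end, ".", f"reproducible_{n}")
    return ConsensusPeak(iv, {s: s in contributing for s in set_names})


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs, ref, n_obs, n_ref, m_trim=0.30, a_trim=0.05):
    """TMM factor of one sample against the reference (log2 scale inside)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = M.size
    lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    rank_m = stats.rankdata(M, method="average")
    rank_a = stats.rankdata(A, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, m_trim: float = 0.30,
                a_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    The reference sample is the one whose library-size-scaled upper
    quartile is closest to the mean upper quartile; each sample's factor is
    the doubly-trimmed (30% by M, 5% by A), precision-weighted mean of the
    M-values against the reference.
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    uq = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(
                X[:, j], X[:, ref_idx], lib[j], lib[ref_idx], m_trim, a_trim
            )
            for j in range(X.shape[1])
        ]
    )
    f = f / geometric_mean(f)
    return pd.Series(f, index=counts.columns)


def tmm_log_intensity(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(TMM-scaled count + 1): counts rescaled to the mean effective
    library size divided by each sample's (library size x TMM factor)."""
    f = tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * f.to_numpy()
    scale = np.exp(np.mean(np.log(eff))) / eff
    return np.log2(counts * scale + 1.0)


# ---------------------------------------------------------------------------
# peak-gene linking
# ---------------------------------------------------------------------------

@dataclass
class PeakGeneLink:
    peak_id: str
    gene_id: str
    r: float
    fdr: float
    distance: int


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations of two (features x samples) blocks."""
    Za = A - A.mean(axis=1, keepdims=True)
    Zb = B - B.mean(axis=1, keepdims=True)
    Za /= np.linalg.norm(Za, axis=1, keepdims=True)
    Zb /= np.linalg.norm(Zb, axis=1, keepdims=True)
    return Za @ Zb.T


def correlate_peak_gene(
    peak_intensity: pd.DataFrame,
    expression: pd.DataFrame,
    peak_coords: dict[str, GenomicInterval],
    gene_models: dict[str, TranscriptModel],
    r_threshold: float = 0.7,
    fdr_threshold: float = 0.1,
) -> tuple[list[PeakGeneLink], pd.DataFrame]:
    """Link peaks to same-chromosome genes by Pearson correlation.

    p-values come from the t transform with n-2 df and are BH-adjusted over
    all tested same-chromosome pairs; a link is retained when
    r > r_threshold and FDR < fdr_threshold.  Returns (links, full table).
    """
    if list(peak_intensity.columns) != list(expression.columns):
        raise ValueError("peak and expression sample columns do not match")
    n = peak_intensity.shape[1]
    chroms = sorted(
        {iv.chrom for iv in peak_coords.values()}
        & {g.chrom for g in gene_models.values()}
    )
    frames = []
    for chrom in chroms:
        p_ids = [p for p in peak_intensity.index if
                 p in peak_coords and peak_coords[p].chrom == chrom]
        g_ids = [g for g in expression.index if
                 g in gene_models and gene_models[g].chrom == chrom]
        if not p_ids or not g_ids:
            continue
        R = _pearson_matrix(
            peak_intensity.loc[p_ids].to_numpy(dtype=float),
            expression.loc[g_ids].to_numpy(dtype=float),
        )
        pi, gi = np.meshgrid(np.arange(len(p_ids)), np.arange(len(g_ids)),
                             indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "peak_id": np.array(p_ids)[pi.ravel()],
                    "gene_id": np.array(g_ids)[gi.ravel()],
                    "r": R.ravel(),
                }
            )
        )
    if not frames:
        return [], pd.DataFrame(columns=["peak_id", "gene_id", "r", "p", "fdr"])
    table = pd.concat(frames, ignore_index=True)
    r = np.clip(table["r"].to_numpy(), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    table["p"] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    links = []
    retained = table[(table["r"] > r_threshold) & (table["fdr"] < fdr_threshold)]
    for row in retained.itertuples():
        dist = peak_tss_distance(peak_coords[row.peak_id],
                                 gene_models[row.gene_id])
        links.append(
            PeakGeneLink(row.peak_id, row.gene_id, float(row.r),
                         float(row.fdr), dist)
        )
    return links, table


def peak_tss_distance(peak: GenomicInterval, gene: TranscriptModel) -> int:
    """bp between peak and the gene's TSS: 0 if the TSS falls inside the
    peak, else the distance to the nearest peak edge (end-1 for the right
    edge, intervals being half-open)."""
    if peak.chrom != gene.chrom:
        raise ValueError("peak and gene on different chromosomes")
    tss = gene.tss
    if peak.start <= tss < peak.end:
        return 0
    return int(min(abs(tss - peak.start), abs(tss - (peak.end - 1))))


def annotate_feature(
    peak: GenomicInterval,
    gene_models: list[TranscriptModel],
    promoter_window: int = 1000,
) -> str:
    """Priority classification promoter > exon > intron > distal_intergenic.

    Promoter means the peak overlaps [TSS - w, TSS + w) of any gene.
    """
    is_exon = False
    is_intron = False
    for gene in gene_models:
        if gene.chrom != peak.chrom:
            continue
        tss = gene.tss
        if peak.start < tss + promoter_window and tss - promoter_window < peak.end:
            return "promoter"
        for s, e in gene.exons:
            if peak.start < e and s < peak.end:
                is_exon = True
        for s, e in gene.introns:
            if peak.start < e and s < peak.end:
                is_intron = True
    if is_exon:
        return "exon"
    if is_intron:
        return "intron"
    return "distal_intergenic"


def overlap_chisq(group_in: int, group_out: int, bg_in: int, bg_out: int
                  ) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 overlap
    table, e.g. differential peaks in/out of known enhancers vs consensus
    background."""
    table = np.array([[group_in, group_out], [bg_in, bg_out]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
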