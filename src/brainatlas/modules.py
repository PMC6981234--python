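"""Module eigengenes and module-region association gating.

Gene modules themselves are consumed from an upstream co-expression step
(a gene -> module assignment table); this module computes each module's
eigengene -- the first principal component of the gene-standardized
expression submatrix -- and gates module-region associations on a Pearson
correlation and its Student asymptotic p-value, as the atlas analysis does
(r >= 0.8 and p < 0.01 by default; the cortical-lobe gating uses r > 0.9).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ModuleEigengene:
    module: str
    scores: pd.Series          # per-sample, unit norm
    variance_explained: float


def compute_eigengene(expr: pd.DataFrame, module: str = "") -> ModuleEigengene:
    """First principal component of the gene-standardized submatrix.

    Rows are genes, columns samples.  Zero-variance genes are dropped with
    a warning; the eigengene sign is aligned to correlate positively with
    the mean expression profile of the module.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("eigengene needs >= 2 genes and >= 3 samples")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"module {module or '?'}: dropping {int((sd == 0).sum())} "
            "zero-variance gene(s)"
        )
        X = X[sd > 0]
        if X.shape[0] < 2:
            raise ValueError("all-constant module expression matrix")
        sd = sd[sd > 0]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[0]
    var_explained = float(S[0] ** 2 / np.sum(S**2))
    mean_profile = Z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    return ModuleEigengene(
        module=module,
        scores=pd.Series(scores, index=expr.columns),
        variance_explained=var_explained,
    )


def correlate_trait(
    me: ModuleEigengene,
    region_indicator,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
) -> tuple[float, float, bool]:
    """Pearson r between eigengene and a binary region trait, with the
    Student asymptotic p-value (t = r sqrt(n-2)/sqrt(1-r^2), n-2 df).

    Significant means r >= r_threshold and p < p_threshold.
    """
    x = me.scores.to_numpy(dtype=float)
    y = np.asarray(region_indicator, dtype=float)
    if x.shape != y.shape:
        raise ValueError("eigengene and trait lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("constant eigengene")
    if np.ptp(y) == 0:
        raise ValueError("constant trait indicator")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    significant = bool(r >= r_threshold and p < p_threshold)
    return r, p, significant


def module_trait_table(
    expr: pd.DataFrame,
    assignments: pd.DataFrame,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Eigengene-region correlation table over all modules and regions.

    ``assignments`` has columns (gene, module); regions are taken from
    sample ids of the form produced by the simulator or supplied as a
    metadata frame via the caller.  Samples' region labels are parsed from
    a ``region`` row if ``expr`` carries a MultiIndex, otherwise from a
    ``region`` column in ``assignments.attrs['samples']``.
    """
    samples = assignments.attrs.get("samples")
    if samples is None:
        raise ValueError("assignments.attrs['samples'] metadata is required")
    rows = []
    for module, genes in assignments.groupby("module")["gene"]:
        sub = expr.loc[[g for g in genes if g in expr.index]]
        me = compute_eigengene(sub, module=str(module))
        for region in sorted(samples["region"].unique()):
            indicator = (samples["region"] == region).astype(float).to_numpy()
            r, p, sig = correlate_trait(me, indicator, r_threshold, p_threshold)
            rows.append(
                {"module": module, "region": region, "r": r, "p": p,
                 "significant": sig,
                 "variance_explained": me.variance_explained}
            )
    return pd.DataFrame(rows)
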