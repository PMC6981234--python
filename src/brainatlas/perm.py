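"""Permutation-based empirical-null inference for covariate-related genes.

The study design is balanced: two sexes x two age levels with the same
number of individuals in every (sex, age) cell.  To test one covariate
(say sex) free of the other, individuals are pooled *within* each level of
the other covariate and reassigned to the tested covariate's cells in every
possible way; two reassignments that differ only by a simultaneous swap of
the tested covariate's labels in all other-covariate levels produce the
same fit up to sign and are counted once.  For the study's 2x2x2 design
this yields exactly 18 distinct assignments, the identity among them.

Each assignment refits the NB mixed model for every gene; the pooled signed
z-values form an empirical null that is then corrected, in the spirit of
Efron's local-fdr machinery, by fitting N(delta0, sigma0^2) to the central
portion of the z distribution (truncated-normal maximum likelihood), with
the null proportion p0 read off the fitted central mass.  Gene selection
applies a tail-area FDR computed under that estimated null.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CountMatrix, DesignError
from .nbglmm import DesignMatrices, fit_nbmegm, log2_fold_change, wald_test

_OTHER = {"sex": "age", "age": "sex"}


@dataclass
class Assignment:
    """One relabeling: individual -> (sex, age) cell."""

    mapping: dict[str, tuple[int, int]]
    is_identity: bool


@dataclass
class PermutationPlan:
    covariate: str
    assignments: list[Assignment]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class EmpiricalNull:
    """Estimated null component of a z-value mixture."""

    delta0: float
    sigma0: float
    p0: float
    interval: tuple[float, float]


@dataclass
class DiffGeneResult:
    gene: str
    z: float
    log2fc: float
    fdr: float
    significant: bool


def enumerate_permutations(samples: pd.DataFrame,
                           covariate: str) -> PermutationPlan:
    """Exhaustive within-other-level reassignments, deduplicated.

    Raises :class:`DesignError` for unbalanced designs (unequal individuals
    per (sex, age) cell), where the global-label-swap equivalence does not
    hold.
    """
    if covariate not in _OTHER:
        raise ValueError("covariate must be 'sex' or 'age'")
    other = _OTHER[covariate]
    per_indiv = samples.drop_duplicates("individual").set_index("individual")
    cell_sizes = per_indiv.groupby(["sex", "age"])["region"].count()
    if len(cell_sizes) != 4 or cell_sizes.nunique() != 1:
        raise DesignError(
            "permutation enumeration requires a balanced 2x2 design "
            f"(got cell sizes {dict(cell_sizes)})"
        )
    c = int(cell_sizes.iloc[0])
    other_levels = sorted(per_indiv[other].unique())
    pools = {
        lv: sorted(per_indiv.index[per_indiv[other] == lv]) for lv in other_levels
    }
    identity_level0 = {
        lv: frozenset(
            per_indiv.index[(per_indiv[other] == lv) & (per_indiv[covariate] == 0)]
        )
        for lv in other_levels
    }

    per_level_choices = {
        lv: [frozenset(s) for s in itertools.combinations(pools[lv], c)]
        for lv in other_levels
    }
    seen = set()
    assignments: list[Assignment] = []
    for combo in itertools.product(*(per_level_choices[lv] for lv in other_levels)):
        chosen = dict(zip(other_levels, combo))
        direct = tuple(tuple(sorted(chosen[lv])) for lv in other_levels)
        swapped = tuple(
            tuple(sorted(set(pools[lv]) - chosen[lv])) for lv in other_levels
        )
        key = min(direct, swapped)
        if key in seen:
            continue
        seen.add(key)
        is_identity = all(
            chosen[lv] == identity_level0[lv] for lv in other_levels
        ) or all(
            chosen[lv] == frozenset(set(pools[lv]) - identity_level0[lv])
            for lv in other_levels
        )
        if is_identity:  # orient the identity class as observed
            chosen = identity_level0
        mapping = {}
        for lv in other_levels:
            for ind in pools[lv]:
                cov_level = 0 if ind in chosen[lv] else 1
                cell = (
                    (cov_level, lv) if covariate == "sex" else (lv, cov_level)
                )
                mapping[ind] = cell
        assignments.append(Assignment(mapping=mapping, is_identity=is_identity))
    # put the identity first for convenience
    assignments.sort(key=lambda a: not a.is_identity)
    return PermutationPlan(covariate=covariate, assignments=assignments)


def apply_assignment(samples: pd.DataFrame, assignment: Assignment
                     ) -> pd.DataFrame:
    """Relabel every sample's (sex, age) cell by its individual's assignment."""
    out = samples.copy()
    out["sex"] = [assignment.mapping[i][0] for i in out["individual"]]
    out["age"] = [assignment.mapping[i][1] for i in out["individual"]]
    return out


def permute_and_fit(
    counts: CountMatrix,
    plan: PermutationPlan,
    covariate: str | None = None,
    warn_nonconverged_frac: float = 0.2,
) -> pd.DataFrame:
    """Refit every gene under every assignment; pool signed z and p.

    Returns a tidy frame (assignment, is_identity, gene, z, p, log2fc,
    converged); non-converged fits carry NaN statistics and are excluded
    from downstream pooling.  The report dict is attached as ``.attrs``.
    """
    covariate = covariate or plan.covariate
    rows = []
    mat = counts.counts.to_numpy(dtype=float)
    for a_idx, assignment in enumerate(plan.assignments):
        relabeled = apply_assignment(counts.samples, assignment)
        dm = DesignMatrices(relabeled)
        for g_idx, gene in enumerate(counts.counts.index):
            fit = fit_nbmegm(mat[g_idx], dm, gene=gene)
            z, p = wald_test(fit, covariate)
            rows.append(
                (a_idx, assignment.is_identity, gene, z, p,
                 log2_fold_change(fit, covariate), fit.converged)
            )
    out = pd.DataFrame(
        rows,
        columns=["assignment", "is_identity", "gene", "z", "p", "log2fc",
                 "converged"],
    )
    frac_bad = 1.0 - out["converged"].mean()
    out.attrs["convergence_rate"] = 1.0 - frac_bad
    out.attrs["warning"] = (
        f"{frac_bad:.1%} of permuted fits failed to converge"
        if frac_bad > warn_nonconverged_frac else ""
    )
    return out


def estimate_empirical_null(z: np.ndarray,
                            central_fraction: float = 0.75) -> EmpiricalNull:
    """Truncated-normal MLE of the null component from the central z-values.

    The central interval is the ``central_fraction`` quantile range of z;
    N(delta0, sigma0^2) is fitted by maximum likelihood to the z-values
    inside it, and p0 is the observed central mass divided by the fitted
    normal mass on the interval (capped at 1).
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 200:
        raise ValueError("need >= 200 finite z-values to estimate the null")
    if np.ptp(z) == 0:
        raise ValueError("degenerate z-values (all equal)")
    lo = float(np.quantile(z, (1.0 - central_fraction) / 2.0))
    hi = float(np.quantile(z, (1.0 + central_fraction) / 2.0))
    inside = z[(z >= lo) & (z <= hi)]
    if inside.size < 10 or np.ptp(inside) == 0:
        raise ValueError("degenerate central interval")

    def nll(params):
        d, log_s = params
        s = np.exp(log_s)
        mass = stats.norm.cdf(hi, d, s) - stats.norm.cdf(lo, d, s)
        if mass <= 1e-12:
            return 1e10
        return -(np.sum(stats.norm.logpdf(inside, d, s)) -
                 inside.size * np.log(mass))

    start = np.array([float(np.mean(inside)), np.log(np.std(inside) * 2.0)])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 2000})
    delta0 = float(res.x[0])
    sigma0 = float(np.exp(res.x[1]))
    fitted_mass = float(stats.norm.cdf(hi, delta0, sigma0)
                        - stats.norm.cdf(lo, delta0, sigma0))
    p0 = float(min(1.0, (inside.size / z.size) / fitted_mass))
    return EmpiricalNull(delta0=delta0, sigma0=sigma0, p0=p0,
                         interval=(lo, hi))


def select_significant(
    observed: pd.DataFrame,
    null: EmpiricalNull,
    fdr_threshold: float = 0.1,
    lfc_threshold: float = 1.0,
) -> list[DiffGeneResult]:
    """Tail-area FDR under the estimated null; q-value style monotonization.

    ``observed`` needs columns gene, z, log2fc.  For threshold t = |z_g|,
    FDR(t) = p0 * G * P(|Z| >= t | N(delta0, sigma0^2)) / #{|z| >= t};
    each gene's value is the minimum over all thresholds at or below its
    own |z| (non-increasing in t).  Significant means FDR < fdr_threshold
    and |log2fc| > lfc_threshold.
    """
    obs = observed.dropna(subset=["z"]).copy()
    if obs.empty:
        return []
    G = len(obs)
    absz = obs["z"].abs().to_numpy()
    order = np.argsort(absz)  # ascending |z|
    t_sorted = absz[order]
    n_ge = G - np.arange(G)  # #{|z| >= t} with ties counted at their value
    # ties: for equal t the count at the first occurrence applies
    tail = (
        stats.norm.sf((t_sorted - null.delta0) / null.sigma0)
        + stats.norm.cdf((-t_sorted - null.delta0) / null.sigma0)
    )
    raw = null.p0 * G * tail / n_ge
    mono = np.minimum.accumulate(raw)  # prefix min over ascending t
    fdr = np.empty(G)
    fdr[order] = np.clip(mono, 0.0, 1.0)

    results = []
    for (_, row), q in zip(obs.iterrows(), fdr):
        sig = bool(q < fdr_threshold and abs(row["log2fc"]) > lfc_threshold)
        results.append(
            DiffGeneResult(gene=row["gene"], z=float(row["z"]),
                           log2fc=float(row["log2fc"]), fdr=float(q),
                           significant=sig)
        )
    return results


def covariate_pipeline(
    counts: CountMatrix,
    covariate: str,
    fdr_threshold: float = 0.1,
    lfc_threshold: float = 1.0,
    central_fraction: float = 0.75,
) -> tuple[pd.DataFrame, EmpiricalNull, dict]:
    """End-to-end covariate-gene discovery on one count matrix.

    Enumerates the permutation plan, refits all genes under every
    assignment, estimates the empirical null from the pooled permutation
    z-values, and selects significant genes from the identity assignment's
    observed statistics.  Returns (results frame, null, run report).
    """
    plan = enumerate_permutations(counts.samples, covariate)
    fits = permute_and_fit(counts, plan, covariate)
    pooled_z = fits.loc[fits["converged"], "z"].to_numpy()
    null = estimate_empirical_null(pooled_z, central_fraction)
    obs = fits[fits["is_identity"]][["gene", "z", "log2fc"]]
    results = select_significant(obs, null, fdr_threshold, lfc_threshold)
    frame = pd.DataFrame(
        [
            {"gene": r.gene, "z": r.z, "log2fc": r.log2fc, "fdr": r.fdr,
             "significant": r.significant}
            for r in results
        ]
    )
    report = {
        "plan_size": len(plan),
        "convergence_rate": float(fits.attrs["convergence_rate"]),
        "delta0": null.delta0,
        "sigma0": null.sigma0,
        "p0": null.p0,
        "n_significant": int(frame["significant"].sum()) if len(frame) else 0,
    }
    if fits.attrs.get("warning"):
        report["warning"] = fits.attrs["warning"]
    return frame, null, report
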