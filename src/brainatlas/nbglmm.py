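"""Per-gene negative-binomial mixed-model fitting and inference.

The model for one gene: counts y ~ NB(mu, theta) with log link,

    log mu = intercept + alpha * sex + beta * age + gamma_region
             + delta_individual,      delta_l ~ N(0, sigma^2),

fixed sex/age/region effects (treatment coding, first region as reference)
and a Gaussian per-individual random intercept.  Estimation is a Laplace
approximation to the marginal likelihood: an inner penalized IRLS finds the
joint mode of (fixed effects, random effects) for given (theta, sigma^2),
and an outer derivative-free optimization profiles (log theta, log sigma^2)
on the Laplace objective.  Everything is deterministic given the data.

Region-specific genes use a fixed-effect likelihood-ratio test comparing
~ region + individual against ~ individual, chi-square with R-1 df,
with the dispersion estimated on the full model and shared by both fits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import CountMatrix, DegenerateFitError, DesignError

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

class DesignMatrices:
    """Fixed-effect design and random-effect indexing built from metadata.

    Validates that every individual sits in exactly one (sex, age) cell and
    exposes the treatment-coded design matrix reused across genes.
    """

    def __init__(self, samples: pd.DataFrame, include_region: bool = True,
                 covariates: tuple[str, ...] = ("sex", "age")):
        self.samples = samples
        cells = samples.groupby("individual")[["sex", "age"]].nunique()
        if (cells > 1).any().any():
            raise DesignError("an individual maps to more than one (sex, age) cell")
        self.individuals = list(dict.fromkeys(samples["individual"]))
        self.indiv_codes = pd.Categorical(
            samples["individual"], categories=self.individuals
        ).codes.astype(np.intp)
        self.regions = sorted(samples["region"].unique())

        cols = [np.ones(len(samples))]
        names = ["intercept"]
        for cov in covariates:
            cols.append(samples[cov].to_numpy(float))
            names.append(cov)
        if include_region and len(self.regions) > 1:
            for r in self.regions[1:]:
                cols.append((samples["region"] == r).to_numpy(float))
                names.append(f"region_{r}")
        self.X = np.column_stack(cols)
        self.names = names
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("rank-deficient fixed-effect design")

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def is_balanced(self) -> bool:
        per_cell = self.samples.drop_duplicates("individual").groupby(
            ["sex", "age"]
        )["individual"].count()
        return len(per_cell) == 4 and per_cell.nunique() == 1


@dataclass
class NBFit:
    """A converged (or flagged) per-gene mixed-model fit."""

    gene: str
    coef: pd.Series
    se: pd.Series
    sigma2: float
    theta: float
    loglik: float
    converged: bool
    random_effects: pd.Series | None = None


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _pirls(y, C, pen, coef, theta, tol=1e-10, max_iter=60):
    """Maximize the penalized NB log-likelihood in eta = C @ coef.

    Fisher-scoring steps with step-halving, so the penalized objective is
    non-decreasing across iterations.  Returns (coef, objective, weights,
    converged).
    """
    def objective(c):
        eta = np.clip(C @ c, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        return _nb_loglik(y, mu, theta) - 0.5 * np.sum(pen * c * c), mu

    obj, mu = objective(coef)
    converged = False
    for _ in range(max_iter):
        W = mu * theta / (theta + mu)
        score = y - mu * (y + theta) / (theta + mu)
        A = C.T @ (C * W[:, None])
        A[np.diag_indices_from(A)] += pen + 1e-12
        g = C.T @ score - pen * coef
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            break
        new_coef = coef + step
        new_obj, new_mu = objective(new_coef)
        halved = 0
        while new_obj < obj - 1e-12 and halved < 30:
            step *= 0.5
            new_coef = coef + step
            new_obj, new_mu = objective(new_coef)
            halved += 1
        if new_obj < obj:
            converged = True
            break
        delta = new_obj - obj
        coef, obj, mu = new_coef, new_obj, new_mu
        if delta < tol * (abs(obj) + 1.0):
            converged = True
            break
    return coef, obj, mu, converged


def _laplace_objective(y, C, n_fixed, indiv_codes, n_indiv, theta, sigma2,
                       coef0):
    """Negative Laplace marginal log-likelihood profiled over (beta, u)."""
    pen = np.zeros(C.shape[1])
    pen[n_fixed:] = 1.0 / sigma2
    coef, pen_obj, mu, conv = _pirls(y, C, pen, coef0, theta, tol=1e-9,
                                     max_iter=30)
    W = mu * theta / (theta + mu)
    H = np.bincount(indiv_codes, weights=W, minlength=n_indiv)
    lm = pen_obj - 0.5 * np.sum(np.log1p(sigma2 * H))
    return -lm, coef, conv


def fit_nbmegm(
    counts_for_gene,
    design: pd.DataFrame | DesignMatrices,
    gene: str = "",
    max_outer: int = 200,
) -> NBFit:
    """Fit the NB mixed model for one gene's counts.

    ``design`` is the per-sample metadata (individual, sex, age, region,
    replicate) or a prebuilt :class:`DesignMatrices` for reuse across genes.
    """
    if not isinstance(design, DesignMatrices):
        design = DesignMatrices(design)
    y = np.asarray(counts_for_gene, dtype=float)
    if y.shape[0] != design.X.shape[0]:
        raise DesignError("counts length does not match design")
    if np.all(y == 0):
        raise DegenerateFitError(f"gene {gene or '?'}: all counts are zero")
    n_fixed = design.n_fixed
    n_indiv = design.n_individuals
    C = np.column_stack(
        [design.X, (design.indiv_codes[:, None] == np.arange(n_indiv)).astype(float)]
    )

    # moment starts for (theta, sigma2)
    m, v = float(np.mean(y)), float(np.var(y))
    theta0 = m * m / max(v - m, 0.1 * m) if m > 0 else 1.0
    theta0 = float(np.clip(theta0, 1e-2, 1e4))
    coef0 = np.zeros(C.shape[1])
    coef0[0] = np.log(m + 0.1)

    state = {"coef": coef0}

    def f(a, b):
        val, coef, _ = _laplace_objective(
            y, C, n_fixed, design.indiv_codes, n_indiv,
            np.exp(a), np.exp(b), state["coef"],
        )
        state["coef"] = coef
        return val

    # coordinate-wise profiling of (log theta, log sigma^2): two bounded 1-D
    # minimizations per sweep, repeated until the objective stabilizes
    a, b = float(np.log(theta0)), float(np.log(0.1))
    prev = np.inf
    outer_conv = False
    for sweep in range(max_outer):
        # full bounds on the first sweep, then a shrinking local bracket
        if sweep == 0:
            ba, bb = (-6.0, 14.0), (-18.0, 6.0)
        else:
            ba = (max(-6.0, a - 1.0), min(14.0, a + 1.0))
            bb = (max(-18.0, b - 1.0), min(6.0, b + 1.0))
        ra = optimize.minimize_scalar(
            lambda t: f(t, b), bounds=ba, method="bounded",
            options={"xatol": 5e-3},
        )
        a = float(ra.x)
        rb = optimize.minimize_scalar(
            lambda t: f(a, t), bounds=bb, method="bounded",
            options={"xatol": 5e-3},
        )
        b = float(rb.x)
        val = float(rb.fun)
        if abs(prev - val) < 1e-8 * (abs(val) + 1.0):
            outer_conv = True
            break
        prev = val
    theta, sigma2 = float(np.exp(a)), float(np.exp(b))

    # final tight inner fit at the optimum + curvature for standard errors
    pen = np.zeros(C.shape[1])
    pen[n_fixed:] = 1.0 / sigma2
    coef, pen_obj, mu, inner_conv = _pirls(
        y, C, pen, state["coef"], theta, tol=1e-12, max_iter=120
    )
    W = mu * theta / (theta + mu)
    H = np.bincount(design.indiv_codes, weights=W, minlength=n_indiv)
    loglik = pen_obj - 0.5 * float(np.sum(np.log1p(sigma2 * H)))
    A = C.T @ (C * W[:, None])
    A[np.diag_indices_from(A)] += pen + 1e-12
    try:
        cov = np.linalg.inv(A)
        se = np.sqrt(np.clip(np.diag(cov)[:n_fixed], 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_fixed, np.nan)
        inner_conv = False

    converged = bool(inner_conv and outer_conv and np.all(np.isfinite(se)))
    return NBFit(
        gene=gene,
        coef=pd.Series(coef[:n_fixed], index=design.names),
        se=pd.Series(se, index=design.names),
        sigma2=sigma2,
        theta=theta,
        loglik=loglik,
        converged=converged,
        random_effects=pd.Series(coef[n_fixed:], index=design.individuals),
    )


def wald_test(fit: NBFit, term: str) -> tuple[float, float]:
    """Wald z and two-sided normal p for a fitted 'sex' or 'age' contrast."""
    if term not in ("sex", "age"):
        raise ValueError("term must be 'sex' or 'age'")
    if not fit.converged or not np.isfinite(fit.se[term]) or fit.se[term] <= 0:
        return float("nan"), float("nan")
    z = float(fit.coef[term] / fit.se[term])
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return z, p


def log2_fold_change(fit: NBFit, term: str) -> float:
    """Natural-log contrast converted to the log2 scale used for selection."""
    return float(fit.coef[term] / np.log(2.0))


# ---------------------------------------------------------------------------
# fixed-effect NB GLM (region LRT)
# ---------------------------------------------------------------------------

def _nb_glm_profile(y, X, coef0=None):
    """Fixed-effect NB GLM with theta profiled by 1-D optimization."""
    pen = np.zeros(X.shape[1])
    coef0 = np.zeros(X.shape[1]) if coef0 is None else coef0
    coef0[0] = np.log(np.mean(y) + 0.1)
    state = {"coef": coef0.copy()}

    def f(log_theta):
        theta = float(np.exp(np.clip(log_theta, -6.0, 14.0)))
        coef, obj, _, _ = _pirls(y, X, pen, state["coef"], theta)
        state["coef"] = coef
        return -obj

    res = optimize.minimize_scalar(f, bounds=(-6.0, 14.0), method="bounded",
                                   options={"xatol": 1e-6})
    theta = float(np.exp(res.x))
    coef, ll, _, _ = _pirls(y, X, pen, state["coef"], theta, tol=1e-12,
                            max_iter=120)
    return coef, theta, float(ll)


def _nb_glm_fixed_theta(y, X, theta, coef0=None):
    pen = np.zeros(X.shape[1])
    coef0 = np.zeros(X.shape[1]) if coef0 is None else coef0
    coef0[0] = np.log(np.mean(y) + 0.1)
    coef, ll, _, _ = _pirls(y, X, pen, coef0, theta, tol=1e-12, max_iter=120)
    return coef, float(ll)


def lrt_region(counts_for_gene, samples: pd.DataFrame,
               gene: str = "") -> tuple[float, float, pd.Series]:
    """Likelihood-ratio test for any region effect: ~region+ID vs ~ID.

    Both models are fixed-effect NB GLMs; the dispersion is estimated on the
    full model and held fixed for the reduced fit.  Returns the LR statistic,
    the chi-square p-value with R-1 df, and per-region fold-changes (each
    region's fitted mean over the arithmetic mean of the other regions').
    """
    y = np.asarray(counts_for_gene, dtype=float)
    if np.all(y == 0):
        raise DegenerateFitError(f"gene {gene or '?'}: all counts are zero")
    regions = sorted(samples["region"].unique())
    if len(regions) < 2:
        raise DesignError("region LRT needs >= 2 regions")
    individuals = list(dict.fromkeys(samples["individual"]))

    def dummies(values, levels):
        return np.column_stack(
            [(values == lv).astype(float) for lv in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(values), 0))

    ind_d = dummies(samples["individual"].to_numpy(), individuals)
    reg_d = dummies(samples["region"].to_numpy(), regions)
    ones = np.ones((len(y), 1))
    X_full = np.column_stack([ones, ind_d, reg_d])
    X_red = np.column_stack([ones, ind_d])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DesignError("rank-deficient region+individual design")

    coef_full, theta, ll_full = _nb_glm_profile(y, X_full)
    _, ll_red = _nb_glm_fixed_theta(y, X_red, theta)
    lr = max(0.0, 2.0 * (ll_full - ll_red))
    df = len(regions) - 1
    p = float(stats.chi2.sf(lr, df))

    gamma = np.concatenate([[0.0], coef_full[-(len(regions) - 1):]])
    mu_r = np.exp(gamma)
    fc = pd.Series(
        [mu_r[k] / np.mean(np.delete(mu_r, k)) for k in range(len(regions))],
        index=regions,
    )
    return lr, p, fc


def filter_expressed(counts: CountMatrix, min_count: int = 1,
                     min_samples: int = 3) -> CountMatrix:
    """Detection filter: keep genes with count > min_count in >= min_samples."""
    keep = (counts.counts > min_count).sum(axis=1) >= min_samples
    return CountMatrix(counts.counts.loc[keep], counts.samples)
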