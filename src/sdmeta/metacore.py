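"""Per-gene random-effects meta-analysis with REML heterogeneity estimation.

Each gene's per-contrast log2 fold changes y_i with sampling variances
v_i are modelled as

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, v_i),

with the between-contrast heterogeneity tau^2 estimated by restricted
maximum likelihood and the coefficients by inverse-variance weighted
(generalised) least squares at the REML tau^2. The intercept-only model
gives the pooled SD effect mu; the moderated model adds SD duration
(centered) as a numeric predictor and recovery sleep as a factor.
Inference is Wald-type on the normal scale; p-values are adjusted with
the Benjamini-Hochberg step-up procedure over genes whose fits
converged ("stable" estimates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .harmonize import GeneEffectMatrix

__all__ = [
    "MetaFit",
    "MetaRegFit",
    "MetaResultsTable",
    "InsufficientContrastsError",
    "CollinearDesignError",
    "reml_tau2",
    "fit_random_effects",
    "fit_moderated",
    "bh_adjust",
    "run_meta",
]

#: 95% Wald confidence-interval multiplier
CI_Z = 1.96

#: Fisher-scoring convergence tolerance on tau^2 and iteration cap
REML_TOL = 1e-8
REML_MAXITER = 100


class InsufficientContrastsError(ValueError):
    """Too few contrasts for the requested model."""


class CollinearDesignError(ValueError):
    """The moderator design matrix is rank deficient."""


@dataclass(frozen=True)
class MetaFit:
    """Intercept-only random-effects fit for one gene."""

    gene: str
    k: int
    mu_hat: float
    se_mu: float
    tau2_hat: float
    z: float
    p: float
    ci_lb: float
    ci_ub: float
    converged: bool


@dataclass(frozen=True)
class MetaRegFit:
    """Moderator meta-regression fit for one gene.

    ``beta`` holds (intercept, duration, rs): the SD effect at mean
    duration without recovery sleep, the per-hour duration slope, and
    the recovery-sleep factor effect.
    """

    gene: str
    k: int
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2_hat: float
    converged: bool


@dataclass
class MetaResultsTable:
    """Per-gene results plus run-level summary counts."""

    table: pd.DataFrame
    model: str
    n_total: int
    n_stable: int
    n_significant: int
    q: float


def _restricted_nll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    XtWX = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, (X.T * w) @ y)
    r = y - X @ beta
    return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r * r))


def reml_tau2(
    y: np.ndarray, v: np.ndarray, X: np.ndarray | None = None
) -> tuple[float, bool]:
    """REML estimate of the between-contrast variance tau^2.

    Maximises the restricted log-likelihood

        -1/2 [ sum log(v_i + tau^2) + log|X'WX| + r'Wr ],
        W = diag(1/(v_i + tau^2)),

    by Fisher scoring with projection at zero, falling back to a bounded
    scalar search when scoring fails to settle. Returns (tau2_hat,
    converged).
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if X is None:
        X = np.ones((len(y), 1))
    X = np.atleast_2d(np.asarray(X, float))
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(v)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite inputs")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    k, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if len(y) != k or len(v) != k:
        raise ValueError("y, v and X must have matching length")
    if k <= rank:
        raise InsufficientContrastsError(
            f"insufficient contrasts: k={k} with design rank {rank}"
        )

    # Fisher scoring on tau^2 with projection at the zero boundary
    tau2 = max(np.var(y, ddof=min(p, k - 1)) - np.mean(v), 0.0)
    converged = False
    hit_zero = 0
    for _ in range(REML_MAXITER):
        w = 1.0 / (v + tau2)
        XtWX = (X.T * w) @ X
        try:
            A = np.linalg.solve(XtWX, (X.T * w))
        except np.linalg.LinAlgError:
            break
        # P = W - W X (X'WX)^-1 X' W acting through its diagonal/quadratic forms
        WX = X * w[:, None]
        Py = w * y - WX @ (A @ y)
        trP = np.sum(w) - np.sum(WX * A.T)
        PP_tr = np.sum(w**2) - 2 * np.sum((WX * w[:, None]) * A.T) + np.sum((WX @ A) * (WX @ A).T)
        score = -0.5 * (trP - np.sum(Py * Py))
        info = 0.5 * PP_tr
        if info <= 0 or not np.isfinite(score):
            break
        step = score / info
        new = tau2 + step
        if new < 0:
            new = 0.0
            hit_zero += 1
        if abs(new - tau2) < REML_TOL:
            tau2 = new
            converged = True
            break
        if hit_zero >= 2:
            tau2 = 0.0
            converged = True
            break
        tau2 = new
    if not converged:
        upper = 100.0 * float(np.max(v))
        res = optimize.minimize_scalar(
            _restricted_nll,
            bounds=(0.0, upper),
            args=(y, v, X),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.success and np.isfinite(res.fun):
            tau2 = max(float(res.x), 0.0)
            converged = True
    return float(tau2), bool(converged)


def _gls(y, v, X, tau2):
    w = 1.0 / (v + tau2)
    XtWX = (X.T * w) @ X
    cov = np.linalg.inv(XtWX)
    beta = cov @ ((X.T * w) @ y)
    se = np.sqrt(np.diag(cov))
    return beta, se


def fit_random_effects(y, v, gene: str = "", inference: str = "z") -> MetaFit:
    """Intercept-only random-effects pooling of one gene's contrasts.

    With REML tau^2 and weights w_i = 1/(v_i + tau^2):
    mu = sum(w y)/sum(w), se = sum(w)^(-1/2), Wald z = mu/se,
    p = 2 Phi(-|z|), 95% CI = mu +/- 1.96 se. The default normal-scale
    inference is mildly anticonservative at small k because it ignores
    the uncertainty in tau^2; ``inference="t"`` switches the reference
    distribution (and CI multiplier) to t on k - 1 degrees of freedom.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if len(y) < 2:
        raise InsufficientContrastsError("k >= 2 contrasts required")
    if inference not in ("z", "t"):
        raise ValueError(f"unknown inference mode: {inference!r}")
    tau2, converged = reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = mu / se
    if inference == "z":
        p = 2.0 * stats.norm.sf(abs(z))
        mult = CI_Z
    else:
        df = len(y) - 1
        p = 2.0 * stats.t.sf(abs(z), df)
        mult = float(stats.t.ppf(0.975, df))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    if not np.isfinite(se):
        converged = False
    return MetaFit(
        gene=gene,
        k=len(y),
        mu_hat=mu,
        se_mu=se,
        tau2_hat=tau2,
        z=float(z),
        p=p,
        ci_lb=mu - mult * se,
        ci_ub=mu + mult * se,
        converged=converged,
    )


def fit_moderated(
    y,
    v,
    duration,
    rs,
    duration_center: float | None = None,
    gene: str = "",
) -> MetaRegFit:
    """Meta-regression with centered SD duration and a recovery-sleep factor.

    Design X = [1, duration - center, rs-indicator]; ``duration_center``
    defaults to the mean duration of the supplied contrasts but should
    be the mean over the full contrast metadata so intercepts are
    comparable across genes with different coverage.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    duration = np.asarray(duration, float)
    rs = np.asarray(rs, float)
    if len(y) < 4:
        raise InsufficientContrastsError("k >= 4 contrasts required")
    if duration_center is None:
        duration_center = float(np.mean(duration))
    X = np.column_stack(
        [np.ones_like(y), duration - duration_center, (rs > 0).astype(float)]
    )
    for j, name in [(1, "duration"), (2, "rs")]:
        if np.ptp(X[:, j]) == 0:
            raise CollinearDesignError(f"moderator column {name!r} does not vary")
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearDesignError("design matrix is rank deficient")
    tau2, converged = reml_tau2(y, v, X)
    beta, se = _gls(y, v, X, tau2)
    z = beta / se
    p = np.minimum(np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1)), 1.0)
    if not np.all(np.isfinite(se)):
        converged = False
    return MetaRegFit(
        gene=gene,
        k=len(y),
        beta=beta,
        se=se,
        z=z,
        p=p,
        tau2_hat=tau2,
        converged=converged,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i}( p_(j) * m / j ), capped at 1, mapped back to
    input order; missing entries are excluded from m and stay missing.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def run_meta(
    matrix: GeneEffectMatrix,
    model: str = "intercept",
    q: float = 0.05,
) -> MetaResultsTable:
    """Fit the per-gene meta-analysis over an aligned effect matrix.

    Each gene is fit on its present contrasts only. Genes whose REML fit
    fails are reported with ``converged=False`` and excluded from the
    FDR adjustment. For ``model="moderated"`` the duration predictor is
    centered on the unweighted mean duration over all contrasts in the
    matrix metadata, and per-coefficient FDR columns are produced.
    """
    if model not in ("intercept", "moderated"):
        raise ValueError(f"unknown model: {model!r}")
    durations = np.array([c.sd_hours for c in matrix.contrasts])
    rs_hours = np.array([c.rs_hours for c in matrix.contrasts])
    center = float(np.mean(durations))

    rows = []
    for gene in matrix.genes:
        y, v, mask = matrix.gene_arrays(gene)
        try:
            if model == "intercept":
                fit = fit_random_effects(y, v, gene=gene)
                rows.append(
                    {
                        "gene": gene,
                        "k": fit.k,
                        "log2fc": fit.mu_hat,
                        "ci_lb": fit.ci_lb,
                        "ci_ub": fit.ci_ub,
                        "se": fit.se_mu,
                        "tstat": fit.z,
                        "pval": fit.p,
                        "tau2": fit.tau2_hat,
                        "converged": fit.converged,
                    }
                )
            else:
                fit = fit_moderated(
                    y,
                    v,
                    durations[mask],
                    rs_hours[mask],
                    duration_center=center,
                    gene=gene,
                )
                rows.append(
                    {
                        "gene": gene,
                        "k": fit.k,
                        "log2fc": fit.beta[0],
                        "se": fit.se[0],
                        "tstat": fit.z[0],
                        "pval": fit.p[0],
                        "ci_lb": fit.beta[0] - CI_Z * fit.se[0],
                        "ci_ub": fit.beta[0] + CI_Z * fit.se[0],
                        "beta_duration": fit.beta[1],
                        "se_duration": fit.se[1],
                        "pval_duration": fit.p[1],
                        "beta_rs": fit.beta[2],
                        "se_rs": fit.se[2],
                        "pval_rs": fit.p[2],
                        "tau2": fit.tau2_hat,
                        "converged": fit.converged,
                    }
                )
        except (InsufficientContrastsError, CollinearDesignError, ValueError):
            rows.append({"gene": gene, "k": int(mask.sum()), "converged": False})
    table = pd.DataFrame(rows)
    stable = table["converged"].fillna(False).astype(bool)

    pcols = ["pval"] + (
        ["pval_duration", "pval_rs"] if model == "moderated" else []
    )
    for pc in pcols:
        fc = "fdr" + pc.removeprefix("pval")
        pvals = table[pc].where(stable, np.nan) if pc in table else np.nan
        table[fc] = bh_adjust(pvals.to_numpy(float)) if pc in table else np.nan

    n_sig = int((table["fdr"] < q).sum())
    return MetaResultsTable(
        table=table,
        model=model,
        n_total=len(table),
        n_stable=int(stable.sum()),
        n_significant=n_sig,
        q=q,
    )
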