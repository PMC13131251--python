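"""Two-group RNA-seq re-analysis and congruence with the meta-analysis.

The validation stage mirrors a standard count-based differential
expression pipeline: genes with mean raw count < 10 are removed, TMM
(trimmed mean of M-values) scale factors normalise effective library
sizes, log2-CPM values receive observation-level precision weights from
the empirical mean-variance trend, a treatment-only weighted linear
model is fit per gene, residual variances are shrunk toward a common
prior by empirical Bayes, and moderated-t p-values are BH-adjusted.
The resulting per-gene effects are then compared with the meta-analytic
effects: direction agreement, "fully validated" classification (same
direction and FDR < q in the validation data), an OLS slope of
validation log2FC on meta log2FC, and Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
import statsmodels.api as sm

from .metacore import bh_adjust

__all__ = [
    "ValidationSummary",
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
    "voom_weights",
    "fit_de",
    "run_validation_de",
    "congruence",
]

LOW_COUNT_MEAN = 10.0
CPM_PRIOR = 0.5


@dataclass(frozen=True)
class ValidationSummary:
    """Congruence between meta-analysis DEGs and the validation re-analysis."""

    n_degs: int
    n_represented: int
    n_same_direction: int
    n_fully_validated: int
    ols_slope: float
    ols_slope_se: float
    spearman_rho: float

    def __post_init__(self) -> None:
        chain = (
            self.n_fully_validated
            <= self.n_same_direction
            <= self.n_represented
            <= self.n_degs
        )
        if not chain:
            raise ValueError("congruence counts violate the chain inequality")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_low_counts(counts: pd.DataFrame, min_mean: float = LOW_COUNT_MEAN) -> pd.DataFrame:
    """Remove genes with mean raw count strictly below ``min_mean``."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = counts.mean(axis=1) >= min_mean
    out = counts.loc[keep]
    if out.empty:
        raise ValueError("no genes remain after the low-count filter")
    return out


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """TMM normalisation factors (trimmed mean of M-values).

    The reference sample is the column whose 75th-percentile
    count-per-library value is closest to the mean of those. For each
    sample, log-ratios M and average abundances A versus the reference
    are computed over genes expressed in both; the extreme 30% of M and
    5% of A are trimmed, and the factor is 2 to the precision-weighted
    mean of the remaining M (weights: inverse asymptotic binomial
    variance). Factors are rescaled to geometric mean 1.
    """
    x = counts.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("at least two samples are required")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        obs, refc = x[:, j], x[:, ref]
        mask = (obs > 0) & (refc > 0)
        if not mask.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed genes with "
                "the reference"
            )
        o, r = obs[mask], refc[mask]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        if weighted:
            factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        else:
            factors[j] = 2.0 ** np.mean(m[keep])
    return factors / np.exp(np.mean(np.log(factors)))


def log_cpm(
    counts: pd.DataFrame, factors: np.ndarray | None = None, prior: float = CPM_PRIOR
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    log2((count + prior) / (effective library + 2 * prior) * 1e6) with a
    default prior count of 0.5; the effective library is the raw library
    size times the sample's normalisation factor.
    """
    x = counts.to_numpy(float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    if factors is None:
        factors = np.ones(x.shape[1])
    if np.any(np.asarray(factors) <= 0):
        raise ValueError("normalisation factors must be positive")
    efflib = lib * np.asarray(factors, float)
    y = np.log2((x + prior) / (efflib + 2.0 * prior) * 1e6)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


def _ols_fit(y: np.ndarray, X: np.ndarray, w: np.ndarray | None = None):
    """Row-wise (weighted) least squares of genes x samples on a common
    two-column design [intercept, indicator]; closed-form 2x2 solve."""
    d = X[:, 1]
    if w is None:
        w = np.ones_like(y)
    sw = w.sum(axis=1)
    swd = (w * d).sum(axis=1)
    swdd = (w * d * d).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swdy = (w * d * y).sum(axis=1)
    det = sw * swdd - swd**2
    b1 = (sw * swdy - swd * swy) / det
    b0 = (swy - b1 * swd) / sw
    resid = y - b0[:, None] - np.outer(b1, d)
    df = y.shape[1] - 2
    s2 = (w * resid**2).sum(axis=1) / df
    leverage = sw / det  # (X'WX)^-1 [1,1]
    return b0, b1, s2, df, leverage, resid


def voom_weights(
    counts: pd.DataFrame,
    factors: np.ndarray,
    design: np.ndarray,
    span: float = 0.5,
    prior: float = CPM_PRIOR,
) -> pd.DataFrame:
    """Observation-level precision weights from the mean-variance trend.

    Per-gene linear fits on log-CPM give residual standard deviations;
    a lowess smooth (span 0.5) of sqrt(sd) against mean log2 count is
    interpolated at each observation's fitted log2 count (constant
    beyond the trend's boundary) and the weight is the predicted
    sqrt(sd) to the power -4.
    """
    x = counts.to_numpy(float)
    if x.shape[1] - np.linalg.matrix_rank(design) < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    lib = x.sum(axis=0)
    efflib = lib * np.asarray(factors, float)
    y = np.log2((x + prior) / (efflib + 2.0 * prior) * 1e6)
    b0, b1, s2, df, _, _ = _ols_fit(y, design)
    fitted = b0[:, None] + np.outer(b1, design[:, 1])

    sx = y.mean(axis=1) + np.mean(np.log2(efflib + 2.0 * prior)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(s2))  # quarter-root of variance = sqrt of residual sd
    trend = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]

    fitted_logcount = fitted + np.log2(efflib + 2.0 * prior)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    w = pred_sqrt_sd**-4.0
    return pd.DataFrame(w, index=counts.index, columns=counts.columns)


def _trigamma_inverse(y: float, iters: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches the mean and excess variance of e_g = log(s_g^2)
    - digamma(df/2) + log(df/2) to recover the prior degrees of freedom
    d0 (via trigamma inversion) and prior variance s0^2.
    """
    ok = s2 > 0
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def fit_de(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    condition,
    treatment: str = "SD",
) -> pd.DataFrame:
    """Per-gene weighted linear model with empirical-Bayes moderation.

    Fits [intercept, treatment-indicator] per gene by (weighted) least
    squares, shrinks residual variances toward the common prior
    (d0, s0^2) estimated by method of moments, and tests the treatment
    coefficient with a moderated t on d0 + df degrees of freedom;
    p-values are BH-adjusted across genes.

    Returns a table with columns gene, log2fc, ave_expr, se, t_mod, p,
    fdr (log2fc is treatment minus reference).
    """
    cond = np.asarray(condition)
    groups = pd.unique(cond)
    if len(groups) != 2:
        raise ValueError("exactly two conditions are required")
    ind = (cond == treatment).astype(float)
    if ind.sum() < 2 or (1 - ind).sum() < 2:
        raise ValueError("each condition needs at least 2 samples")
    y = logcpm.to_numpy(float)
    w = None if weights is None else weights.to_numpy(float)
    X = np.column_stack([np.ones_like(ind), ind])

    b0, b1, s2, df, leverage, _ = _ols_fit(y, X, w)
    d0, s02 = _squeeze_var(s2, df)
    if np.isfinite(d0):
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    else:
        s2_post = np.full_like(s2, s02)
        df_total = 1e9  # effectively normal
    se = np.sqrt(s2_post * leverage)
    t_mod = b1 / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    return pd.DataFrame(
        {
            "gene": logcpm.index,
            "log2fc": b1,
            "ave_expr": y.mean(axis=1),
            "se": se,
            "t_mod": t_mod,
            "p": p,
            "fdr": bh_adjust(p),
        }
    ).reset_index(drop=True)


def run_validation_de(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Full validation pipeline: filter, TMM, log-CPM, voom, moderated fit."""
    cond = samples.set_index("sample_id").loc[counts.columns, "condition"].to_numpy()
    filtered = filter_low_counts(counts)
    factors = tmm_factors(filtered)
    lcpm = log_cpm(filtered, factors)
    design = np.column_stack(
        [np.ones(len(cond)), (cond == "SD").astype(float)]
    )
    w = voom_weights(filtered, factors, design)
    return fit_de(lcpm, w, cond)


def congruence(
    meta_table: pd.DataFrame,
    de_table: pd.DataFrame,
    q: float = 0.05,
    orientation: str = "validation_on_meta",
) -> ValidationSummary:
    """Congruence statistics between meta-analysis DEGs and the
    validation re-analysis.

    DEGs are meta-analysis genes with FDR < q; among those represented
    in the validation table, direction agreement and "fully validated"
    status (same direction and validation FDR < q) are counted. The
    slope regresses validation log2FC on meta log2FC
    (``orientation="meta_on_validation"`` flips the axes); Spearman's
    rho is computed over the same pairs.
    """
    degs = meta_table.loc[meta_table["fdr"] < q]
    n_degs = len(degs)
    de_idx = de_table.set_index("gene")
    rep = degs.loc[degs["gene"].isin(de_idx.index)]
    if rep.empty:
        raise ValueError("no meta-analysis DEGs are represented in the validation table")
    meta_fc = rep["log2fc"].to_numpy(float)
    val = de_idx.loc[rep["gene"]]
    val_fc = val["log2fc"].to_numpy(float)
    same_dir = np.sign(meta_fc) == np.sign(val_fc)
    fully = same_dir & (val["fdr"].to_numpy(float) < q)

    if orientation == "validation_on_meta":
        xv, yv = meta_fc, val_fc
    elif orientation == "meta_on_validation":
        xv, yv = val_fc, meta_fc
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    ols = sm.OLS(yv, sm.add_constant(xv)).fit()
    rho = stats.spearmanr(xv, yv).statistic

    return ValidationSummary(
        n_degs=n_degs,
        n_represented=len(rep),
        n_same_direction=int(same_dir.sum()),
        n_fully_validated=int(fully.sum()),
        ols_slope=float(ols.params[1]),
        ols_slope_se=float(ols.bse[1]),
        spearman_rho=float(rho),
    )
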