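"""Precision-weighted linear-model differential expression with moderated t-tests.

Counts are transformed to log2-CPM, a mean-variance trend is estimated from
per-feature residual standard deviations and converted to per-observation
precision weights, per-feature weighted least squares is fit under a
group-means design, residual variances are shrunk toward a common prior by
empirical Bayes (scaled inverse chi-square prior, hyperparameters estimated by
moment matching on the log scale), and each dose group is contrasted against
the control with Benjamini-Hochberg FDR adjustment per contrast.

Significance calls use strict inequalities: FDR < alpha and |log2FC| > tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from splicegrade.errors import ConfigError, DegenerateDataError, ValidationError
from splicegrade.preprocess import NormFactors

LOWESS_SPAN = 0.5
LOWESS_ITER = 4


@dataclass
class DesignInfo:
    """Group-means design: per-sample group labels plus (treatment, control) contrasts."""

    groups: pd.Series  # sample -> group label
    contrasts: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        levels = []
        for g in self.groups:
            if g not in levels:
                levels.append(g)
        self.levels = levels
        for trt, ctl in self.contrasts:
            for g in (trt, ctl):
                if g not in levels:
                    raise ValidationError(f"contrast group {g!r} not present in design")

    @property
    def matrix(self) -> pd.DataFrame:
        """Samples x groups indicator matrix."""
        x = pd.DataFrame(0.0, index=self.groups.index, columns=self.levels)
        for s, g in self.groups.items():
            x.loc[s, g] = 1.0
        return x

    def contrast_vector(self, contrast: tuple[str, str]) -> np.ndarray:
        trt, ctl = contrast
        c = np.zeros(len(self.levels))
        c[self.levels.index(trt)] = 1.0
        c[self.levels.index(ctl)] = -1.0
        return c

    def group_sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()


@dataclass
class FitResult:
    """Per-feature WLS output for a set of contrasts."""

    features: list[str]
    contrasts: list[tuple[str, str]]
    coef: np.ndarray  # features x contrasts (log2FC)
    unscaled_se: np.ndarray  # features x contrasts, SE per unit residual sd
    s2: np.ndarray  # residual variance per feature
    df_residual: np.ndarray  # residual df per feature
    amean: np.ndarray  # average log2-CPM per feature


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-moderation hyperparameters and posteriors.

    posterior variance = (d0*s0^2 + d*s^2) / (d0 + d) for finite prior df d0;
    equals s^2 when d0 = 0 and s0^2 when d0 is infinite.
    """

    prior_df: float
    prior_var: float
    posterior_var: np.ndarray
    total_df: np.ndarray


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F distribution to observed residual variances.

    Models s^2 ~ s0^2 * F(d, d0); on the log scale the mean and variance have
    closed forms in digamma/trigamma, so (d0, s0^2) follow from the empirical
    mean and variance of log s^2 with a Newton-refined trigamma inversion.
    Returns (inf, exp(mean adjustment)) when the observed spread is at or
    below the sampling noise (all variances effectively equal).
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise DegenerateDataError("need >= 2 positive variances to estimate the prior")
    x, d = s2[ok], df[ok]
    z = np.log(x)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


def moderate(
    s2: np.ndarray,
    df: np.ndarray,
    prior_df: float | None = None,
    prior_var: float | None = None,
    min_features: int = 10,
) -> ModerationParams:
    """Shrink residual variances toward the empirical-Bayes prior.

    ``prior_df``/``prior_var`` may be imposed (0 disables moderation, inf
    shrinks fully); otherwise they are estimated via :func:`estimate_prior`.
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape).astype(float)
    if prior_df is None or prior_var is None:
        if s2.size < min_features:
            import warnings

            warnings.warn(
                f"only {s2.size} features; prior estimate may be unstable", stacklevel=2
            )
        est_d0, est_s02 = estimate_prior(s2, df)
        prior_df = est_d0 if prior_df is None else prior_df
        prior_var = est_s02 if prior_var is None else prior_var
    if np.isinf(prior_df):
        post = np.full_like(s2, prior_var)
        total = np.full_like(s2, np.inf)
    elif prior_df == 0:
        post = s2.copy()
        total = df.copy()
    else:
        post = (prior_df * prior_var + df * s2) / (prior_df + df)
        total = prior_df + df
    return ModerationParams(
        prior_df=float(prior_df), prior_var=float(prior_var), posterior_var=post, total_df=total
    )


def voom_weights(
    counts: pd.DataFrame,
    norm: NormFactors,
    design: DesignInfo,
    span: float = LOWESS_SPAN,
    quality_weights: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate the log-CPM mean-variance trend and per-observation weights.

    y = log2-CPM with prior count 0.5 against effective library sizes; an
    unweighted group-means fit yields per-feature residual sd; the lowess
    trend of sqrt(sd) on fitted mean log-count is evaluated at each
    observation's fitted log-count and the weight is predicted-sd^-4.
    With ``quality_weights`` a single multiplicative per-sample weight
    (one round of gene-averaged residual-variance ratios, geometric mean 1)
    is folded in.
    """
    x = design.matrix.loc[counts.columns].to_numpy()
    n, p = x.shape
    if n < p or np.linalg.matrix_rank(x) < p:
        raise DegenerateDataError("design is rank deficient (fewer samples than groups?)")
    if n - p < 1:
        raise DegenerateDataError("no residual degrees of freedom")
    lib = norm.effective_library_sizes[counts.columns].to_numpy()
    y = np.log2((counts.to_numpy(float) + 0.5) / (lib + 1.0) * 1e6)

    # unweighted group-means fit: fitted values and residual sd per feature
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    fitted = (x @ beta).T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    amean = y.mean(axis=1)

    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = sm_lowess(sy, sx, frac=span, it=LOWESS_ITER, return_sorted=True)
    tx, ti = np.unique(trend[:, 0], return_index=True)
    ty = trend[ti, 1]
    # flat extrapolation outside the fitted range; guard against zero trend
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    w = pred_sqrt_sd**-4.0

    if quality_weights:
        sw = _sample_quality_weights(y, w, x)
        w = w * sw[None, :]

    index, cols = counts.index, counts.columns
    return (
        pd.DataFrame(y, index=index, columns=cols),
        pd.DataFrame(w, index=index, columns=cols),
    )


def _sample_quality_weights(y: np.ndarray, w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One round of per-sample variance-ratio weights, geometric mean 1.

    Fits each feature by WLS with the trend weights, then averages the
    weighted squared residuals per sample; a sample's weight is the inverse
    of its variance ratio.
    """
    a = np.einsum("ni,gn,nj->gij", x, w, x)
    b = np.einsum("ni,gn->gi", x, w * y)
    beta = np.linalg.solve(a, b[..., None])[..., 0]
    resid = y - beta @ x.T
    ms = np.maximum(np.mean(w * resid**2, axis=0), 1e-12)
    inv = 1.0 / ms
    return inv / np.exp(np.mean(np.log(inv)))


def fit_contrasts(
    y: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: DesignInfo,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> FitResult:
    """Per-feature weighted least squares and treatment-minus-control contrasts.

    Returns exact WLS quantities: contrast estimates, unscaled standard
    errors (sqrt of c' (X'WX)^-1 c), residual variance s^2 and residual df.
    """
    contrasts = list(design.contrasts if contrasts is None else contrasts)
    sizes = design.group_sizes()
    for trt, ctl in contrasts:
        for g in (trt, ctl):
            if sizes.get(g, 0) < 2:
                raise DegenerateDataError(
                    f"group {g!r} has {sizes.get(g, 0)} sample(s); SE undefined (need >= 2)"
                )
    x = design.matrix.loc[y.columns].to_numpy()
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise DegenerateDataError("design is rank deficient")
    yv = y.to_numpy(float)
    wv = np.ones_like(yv) if weights is None else weights.to_numpy(float)
    g = yv.shape[0]

    # batched normal equations: A[g] = X' W_g X, b[g] = X' W_g y_g
    a = np.einsum("ni,gn,nj->gij", x, wv, x)
    b = np.einsum("ni,gn->gi", x, wv * yv)
    beta = np.linalg.solve(a, b[..., None])[..., 0]
    resid = yv - beta @ x.T
    df_res = float(n - p)
    s2 = np.einsum("gn,gn->g", wv, resid**2) / df_res
    a_inv = np.linalg.inv(a)

    coef = np.empty((g, len(contrasts)))
    use = np.empty((g, len(contrasts)))
    for k, contrast in enumerate(contrasts):
        c = design.contrast_vector(contrast)
        coef[:, k] = beta @ c
        use[:, k] = np.sqrt(np.einsum("i,gij,j->g", c, a_inv, c))
    return FitResult(
        features=list(y.index),
        contrasts=contrasts,
        coef=coef,
        unscaled_se=use,
        s2=s2,
        df_residual=np.full(g, df_res),
        amean=yv.mean(axis=1),
    )


def moderated_t(fit: FitResult, mod: ModerationParams) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values for every contrast.

    t = coef / (unscaled SE * posterior sd), on prior-df + residual-df degrees
    of freedom (normal reference when the prior df is infinite).
    """
    post_sd = np.sqrt(mod.posterior_var)[:, None]
    t = fit.coef / (fit.unscaled_se * post_sd)
    df = mod.total_df[:, None]
    df_eval = np.where(np.isinf(df), 1e12, df)  # normal limit for infinite prior df
    p = 2.0 * t_dist.sf(np.abs(t), df_eval)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return t, p


def bh_adjust(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sorted ascending, q_(i) = p_(i) * m / i with running minimum from the
    largest p downward, capped at 1, returned in input order.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def classify_deg(
    log2fc: np.ndarray | Sequence[float],
    fdr: np.ndarray | Sequence[float],
    alpha: float = 0.05,
    tau: float = 0.5,
) -> np.ndarray:
    """Call up/down/ns with strict thresholds FDR < alpha and |log2FC| > tau.

    alpha >= 1 disables the FDR gate entirely (otherwise an adjusted p of
    exactly 1 could never satisfy the strict inequality).
    """
    log2fc = np.asarray(log2fc, float)
    fdr = np.asarray(fdr, float)
    sig = np.ones_like(fdr, bool) if alpha >= 1 else fdr < alpha
    calls = np.where(
        sig & (log2fc > tau), "up", np.where(sig & (log2fc < -tau), "down", "ns")
    )
    return calls


def de_table(
    counts: pd.DataFrame,
    norm: NormFactors,
    design: DesignInfo,
    alpha: float = 0.05,
    tau: float = 0.5,
    quality_weights: bool = False,
) -> tuple[pd.DataFrame, FitResult, ModerationParams]:
    """End-to-end DE for one tissue and feature level: tidy records per contrast.

    Columns: feature_id, contrast, log2FC, AveExpr, t, P.Value, adj.P.Val,
    call.  BH is applied within each contrast family.
    """
    if alpha <= 0 or tau < 0:
        raise ConfigError("alpha must be positive and tau non-negative")
    y, w = voom_weights(counts, norm, design, quality_weights=quality_weights)
    fit = fit_contrasts(y, w, design)
    mod = moderate(fit.s2, fit.df_residual)
    t, p = moderated_t(fit, mod)
    frames = []
    for k, (trt, ctl) in enumerate(fit.contrasts):
        fdr = bh_adjust(p[:, k])
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": fit.features,
                    "contrast": f"{trt}-{ctl}",
                    "log2FC": fit.coef[:, k],
                    "AveExpr": fit.amean,
                    "t": t[:, k],
                    "P.Value": p[:, k],
                    "adj.P.Val": fdr,
                    "call": classify_deg(fit.coef[:, k], fdr, alpha, tau),
                }
            )
        )
    return pd.concat(frames, ignore_index=True), fit, mod
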