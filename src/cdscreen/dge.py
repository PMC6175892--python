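"""Two-group differential expression with an empirical-Bayes moderated t.

Per gene g, with a control/case design of n1 + n2 samples, the ordinary
pooled two-sample t uses the residual variance s_g^2 on d_g = n1 + n2 - 2
degrees of freedom.  The moderated t shrinks each s_g^2 toward a prior
value s0^2 learned from all genes:

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_tilde_g   = (mean_case - mean_ctrl) / (s_tilde_g * sqrt(1/n1 + 1/n2))

and t_tilde_g follows a t-distribution with d0 + d_g degrees of freedom
under the null.  The prior (d0, s0^2) is fit by method of moments on
log s^2: under the model, s_g^2 ~ s0^2 * F(d_g, d0), so

    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)

has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
trigamma(d_g/2) + trigamma(d0/2); matching the empirical mean and
variance of e_g and inverting the trigamma by Newton iteration gives the
estimates.  When the empirical variance of e_g does not exceed
trigamma(d_g/2) the excess spread is zero and d0 = infinity (complete
shrinkage; the moderated t is then normal-referenced).

Multiple testing uses Benjamini-Hochberg adjusted p-values; genes pass at
adjusted p < alpha (default 0.05), signed up/down by the log fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from cdscreen.io_formats import CASE, CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

UP = "up"
DOWN = "down"
AMBIGUOUS = "ambiguous"


@dataclass
class EBayesPrior:
    """Hyperparameters of the inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom; may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if not self.s0_sq > 0:
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def _digamma(x: float) -> float:
    return float(polygamma(0, x))


def _trigamma(x: float) -> float:
    return float(polygamma(1, x))


def trigamma_inverse(y: float, max_iter: int = 100, tol: float = 1e-12) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone substitution x -> 1/x for a stable update (trigamma
    is convex and decreasing; the iteration below converges globally from
    the 1/y + 0.5 start).
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    # large y -> small x: trigamma(x) ~ 1/x^2 + 1/x
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        # Newton on f(x) = 1/trigamma(x) - 1/y, f'(x) = -tetragamma/trigamma^2
        tetra = float(polygamma(2, x))
        step = tri * (1.0 - tri / y) / tetra
        x_new = x + step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    raise RuntimeError(
        f"trigamma_inverse failed to converge for y={y} after {max_iter} "
        f"iterations (last x={x})"
    )


def fit_prior(variances: np.ndarray, df: float) -> EBayesPrior:
    """Fit (d0, s0^2) to per-gene sample variances by method of moments.

    ``variances`` are the per-gene pooled residual variances s_g^2, all on
    the common residual degrees of freedom ``df``.  Genes with zero
    variance are excluded from the fit (logged).
    """
    s2 = np.asarray(variances, dtype=float)
    if df < 1:
        raise ValueError(f"residual df must be >= 1, got {df}")
    pos = s2 > 0
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("fit_prior: excluding %d zero-variance genes", n_zero)
    s2 = s2[pos]
    if s2.size < 10:
        raise ValueError(
            f"need >= 10 genes with positive variance, got {s2.size}"
        )
    z = np.log(s2)
    e = z - _digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - _trigamma(df / 2.0)
    if excess <= 0:
        return EBayesPrior(d0=math.inf, s0_sq=float(math.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + _digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_t(
    study: ExpressionStudy,
    prior: EBayesPrior | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Moderated-t differential expression table for a two-group study.

    If ``prior`` is None it is fit from the study's own gene variances.
    Returns a gene-indexed DataFrame with columns mean_control, mean_case,
    log_fc, s2, df_residual, s2_post, t, p, adj_p, significant, sign.

    Setting the prior to ``EBayesPrior(d0 -> 0)`` recovers the ordinary
    pooled t; the d0 = 0 limit itself is requested with ``prior=None`` and
    ``alpha`` handling unchanged via :func:`ordinary_t`.
    """
    study.require_two_groups()
    ctrl = study.values[study.samples_in_group(CONTROL)].to_numpy(dtype=float)
    case = study.values[study.samples_in_group(CASE)].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], case.shape[1]
    d_g = n1 + n2 - 2

    mean_c = ctrl.mean(axis=1)
    mean_t = case.mean(axis=1)
    log_fc = mean_t - mean_c
    ss = ctrl.var(axis=1, ddof=1) * (n1 - 1) + case.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d_g

    if prior is None:
        prior = fit_prior(s2, d_g)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / se
    # zero posterior variance can only arise at d0 = 0 with a constant gene;
    # sentinel: infinite t, p = 0 when the means actually differ
    zero_se = se == 0.0
    if zero_se.any():
        logger.info("moderated_t: %d genes with zero residual variance",
                    int(zero_se.sum()))
        t[zero_se & (log_fc == 0)] = np.nan
        t[zero_se & (log_fc > 0)] = np.inf
        t[zero_se & (log_fc < 0)] = -np.inf

    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isnan(t), 1.0, p)
    adj_p = bh_adjust(p)

    significant = adj_p < alpha
    sign = np.where(log_fc > 0, UP, np.where(log_fc < 0, DOWN, AMBIGUOUS))

    return pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_case": mean_t,
            "log_fc": log_fc,
            "s2": s2,
            "df_residual": float(d_g),
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "adj_p": adj_p,
            "significant": significant,
            "sign": sign,
        },
        index=study.values.index,
    )


def ordinary_t(study: ExpressionStudy, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Ordinary equal-variance pooled two-sample t (the d0 = 0 limit)."""
    study.require_two_groups()
    ctrl = study.values[study.samples_in_group(CONTROL)].to_numpy(dtype=float)
    case = study.values[study.samples_in_group(CASE)].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], case.shape[1]
    d_g = n1 + n2 - 2
    mean_c, mean_t = ctrl.mean(axis=1), case.mean(axis=1)
    log_fc = mean_t - mean_c
    s2 = (ctrl.var(axis=1, ddof=1) * (n1 - 1) + case.var(axis=1, ddof=1) * (n2 - 1)) / d_g
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / se
    t[(se == 0.0) & (log_fc == 0)] = np.nan
    t[(se == 0.0) & (log_fc > 0)] = np.inf
    t[(se == 0.0) & (log_fc < 0)] = -np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df=d_g)
    p = np.where(np.isnan(t), 1.0, p)
    adj_p = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_case": mean_t,
            "log_fc": log_fc,
            "s2": s2,
            "df_residual": float(d_g),
            "s2_post": s2,
            "t": t,
            "p": p,
            "adj_p": adj_p,
            "significant": adj_p < alpha,
            "sign": np.where(log_fc > 0, UP, np.where(log_fc < 0, DOWN, AMBIGUOUS)),
        },
        index=study.values.index,
    )


def select_degs(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_abs_log_fc: float = 0.0,
) -> dict[str, str]:
    """Signed DEG set {gene: 'up'|'down'|'ambiguous'} at adjusted p < alpha.

    A gene with a significant adjusted p but exactly zero log fold change
    is kept with sign 'ambiguous' (it cannot inform a direction-dependent
    query).  An optional absolute log-fold-change cutoff supports stricter
    selection settings.
    """
    mask = table["adj_p"] < alpha
    if min_abs_log_fc > 0:
        mask &= table["log_fc"].abs() >= min_abs_log_fc
    sub = table.loc[mask]
    return {str(g): str(s) for g, s in zip(sub.index, sub["sign"])}
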