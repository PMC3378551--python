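"""Feature-wise two-group testing with empirical-Bayes moderated t statistics.

Per feature g, the two-group linear model gives the group-mean difference
diff_g = mean(group 2) - mean(group 1) and a pooled residual variance s_g^2
on d = n1 + n2 - 2 degrees of freedom.  An inverse-chi-square prior
(d0, s0^2) for the residual variances is estimated by moment matching on
log s_g^2, and the moderated statistic

    t_g = diff_g / sqrt( s~_g^2 * (1/n1 + 1/n2) ),
    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

is referred to a Student t distribution on d0 + d degrees of freedom.
One-sided p-values are reported in both directions; "up" means a higher
mean in group 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import ExpressionMatrix, GroupDesign, ValidationError

logger = logging.getLogger("mirset")


@dataclass
class TwoGroupFit:
    """Ordinary per-feature two-group fit (before moderation)."""

    feature_ids: list[str]
    diff: np.ndarray       # mean(group2) - mean(group1)
    s_sq: np.ndarray       # pooled within-group variance
    d: int                 # residual df, n1 + n2 - 2 (same for all features)
    n1: int
    n2: int


@dataclass
class EBHyper:
    """Empirical-Bayes prior for residual variances.

    d0 may be math.inf, in which case every posterior variance collapses
    to s0_sq; d0 = 0 recovers the ordinary (unmoderated) t statistic.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValidationError("d0 must be non-negative")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be positive")


@dataclass
class FeatureStats:
    """Per-feature moderated statistics and directional p-values."""

    feature_ids: list[str]
    diff: np.ndarray
    s_sq: np.ndarray
    s_tilde_sq: np.ndarray
    t_mod: np.ndarray
    df_total: float
    p_two: np.ndarray
    p_up: np.ndarray
    p_down: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "diff": self.diff,
                "t_mod": self.t_mod,
                "p_up": self.p_up,
                "p_down": self.p_down,
                "p_two": self.p_two,
            }
        )

    def index_of(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}


def fit_two_group_model(x: ExpressionMatrix, design: GroupDesign) -> TwoGroupFit:
    """Group-mean difference and pooled variance for every feature."""
    ind = design.indicator(x.sample_ids)
    g2 = ind == 1
    g1 = ~g2
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"each group needs >=2 samples (n1={n1}, n2={n2})")
    m1 = x.values[:, g1].mean(axis=1)
    m2 = x.values[:, g2].mean(axis=1)
    ss1 = ((x.values[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x.values[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    return TwoGroupFit(list(x.feature_ids), m2 - m1, (ss1 + ss2) / d, d, n1, n2)


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Initialised from the large-argument expansion trigamma(x) ~ 1/x + 1/(2x^2).
    """
    if y <= 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = _trigamma(x) - y
        fp = special.polygamma(2, x)  # derivative of trigamma
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < tol * max(1.0, x):
            return float(x_new)
        x = x_new
    return float(x)


def estimate_prior(s_sq: np.ndarray, d: int) -> EBHyper:
    """Moment-matching estimate of (d0, s0^2) from observed pooled variances.

    Works on e_g = log s_g^2: under the scaled-F model
    Var(e) = trigamma(d/2) + trigamma(d0/2) and
    E(e)   = log s0^2 + digamma(d/2) - digamma(d0/2) + log(d0/d).
    If the observed spread does not exceed trigamma(d/2), d0 = +inf and
    s0^2 is matched from the mean equation alone.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq > 0
    if not positive.all():
        logger.warning(
            "estimate_prior: excluding %d features with zero variance",
            int((~positive).sum()),
        )
    s_sq = s_sq[positive]
    if s_sq.size < 2:
        raise ValidationError("degenerate variances: need >=2 features with s_sq > 0")
    e = np.log(s_sq)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1))
    excess = var_e - float(_trigamma(d / 2))
    if excess <= 0:
        d0 = math.inf
        # E(e) = log s0^2 + digamma(d/2) - log(d/2) as d0 -> inf
        log_s0 = mean_e - float(special.digamma(d / 2)) + math.log(d / 2)
        return EBHyper(d0, math.exp(log_s0))
    half_d0 = trigamma_inverse(excess)
    d0 = 2 * half_d0
    log_s0 = (
        mean_e
        - float(special.digamma(d / 2))
        + float(special.digamma(half_d0))
        - math.log(d0 / d)
    )
    return EBHyper(d0, math.exp(log_s0))


def moderated_stats(fit: TwoGroupFit, hyper: EBHyper) -> FeatureStats:
    """Moderated t statistics and one-sided p-values from a fit and prior."""
    d0, s0 = hyper.d0, hyper.s0_sq
    d = fit.d
    if math.isinf(d0):
        s_tilde = np.full_like(fit.s_sq, s0)
        df_total = math.inf
    else:
        s_tilde = (d0 * s0 + d * fit.s_sq) / (d0 + d)
        df_total = d0 + d
    se_factor = 1.0 / fit.n1 + 1.0 / fit.n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.diff / np.sqrt(s_tilde * se_factor)
    degenerate = s_tilde == 0
    if degenerate.any():
        logger.warning("moderated_stats: %d features with zero posterior variance",
                       int(degenerate.sum()))
        t = np.where(degenerate, np.sign(fit.diff) * np.inf, t)
        t = np.where(degenerate & (fit.diff == 0), 0.0, t)
    if math.isinf(df_total):
        p_up = stats.norm.sf(t)
    else:
        p_up = stats.t.sf(t, df_total)
    p_down = 1.0 - p_up
    p_two = 2.0 * np.minimum(p_up, p_down)
    return FeatureStats(
        feature_ids=list(fit.feature_ids),
        diff=fit.diff,
        s_sq=fit.s_sq,
        s_tilde_sq=s_tilde,
        t_mod=t,
        df_total=df_total,
        p_two=p_two,
        p_up=p_up,
        p_down=p_down,
    )


def run_feature_tests(x: ExpressionMatrix, design: GroupDesign) -> FeatureStats:
    """Fit, estimate the variance prior, and compute moderated statistics."""
    fit = fit_two_group_model(x, design)
    hyper = estimate_prior(fit.s_sq, fit.d)
    return moderated_stats(fit, hyper)
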