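"""Two-stage initial marker screen for ordinal traits.

Stage 1 is a genome-wide single-marker chi-square independence test of
genotype class against phenotype level.  Stage 2 refits the survivors
with a binary logistic model (two levels) or a proportional-odds
cumulative-logit model (three or more levels) and keeps markers whose
likelihood-ratio p-value clears the threshold.  Both stages default to
the nominal 0.05 level; the screen is deliberately lenient — its job is
to cut the marker universe down for the multi-locus model, not to call
significance.

Both regression fits are maximum-likelihood with marker-only designs
(intercept / cutpoints plus one centered dosage column).  Markers whose
fit fails to converge or lands at an implausibly large logit-scale
coefficient are dropped: complete or quasi-complete separation produces
exactly the pathology of a huge effect estimate with a near-1
likelihood-ratio p-value, and such markers carry no usable information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .genio import GenotypeMatrix, OrdinalPhenotype, ValidationError

logger = logging.getLogger("ordgwas")

__all__ = [
    "ScreenResult",
    "chi_square_scan",
    "fit_binary_logistic",
    "fit_proportional_odds",
    "screen",
]

#: logit-scale coefficient magnitude beyond which a fit is treated as separated
SEPARATION_COEF = 15.0
MAX_NEWTON_ITER = 100


@dataclass
class ScreenResult:
    """Per-marker p-value profiles and the surviving marker indices."""

    chi2_p: np.ndarray
    logit_p: np.ndarray
    logit_coef: np.ndarray
    retained: np.ndarray
    thresholds: tuple[float, float]
    stage1_survivors: np.ndarray = field(default=None)

    def to_frame(self, markers=None):
        import pandas as pd

        m = len(self.chi2_p)
        retained = np.zeros(m, dtype=bool)
        retained[self.retained] = True
        return pd.DataFrame(
            {
                "marker": markers if markers is not None else np.arange(m),
                "chi2_p": self.chi2_p,
                "logit_p": self.logit_p,
                "retained": retained,
            }
        )


def chi_square_scan(
    G: GenotypeMatrix | np.ndarray,
    y: OrdinalPhenotype,
    threshold: float = 0.05,
):
    """Single-marker chi-square independence scan over the whole panel.

    For each marker the contingency table of observed genotype classes
    (dosages rounded to 0/1/2; imputed fractional cells join the nearest
    class) against phenotype levels is tested with the asymptotic
    chi-square statistic on ``(rows-1)(cols-1)`` degrees of freedom.  No
    continuity correction is applied in any table size, so 2x2 tables
    are treated the same as larger ones.  Monomorphic markers get p = 1
    and never survive.

    Returns ``(p_values, survivor_indices)``.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    D = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    n, m = D.shape
    codes = y.codes()
    if len(codes) != n:
        raise ValidationError("genotypes and phenotype are not aligned")
    levels = np.unique(codes)
    Dr = np.clip(np.round(D), 0, 2)

    # counts[c, l, j] built from boolean matrix products; NaN never matches
    counts = np.empty((3, len(levels), m))
    for ci, c in enumerate((0.0, 1.0, 2.0)):
        Ic = (Dr == c).astype(float)
        for li, l in enumerate(levels):
            counts[ci, li, :] = (codes == l).astype(float) @ Ic

    row_tot = counts.sum(axis=1)              # (3, m)
    col_tot = counts.sum(axis=0)              # (L, m)
    n_obs = row_tot.sum(axis=0)               # (m,)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row_tot[:, None, :] * col_tot[None, :, :] / n_obs
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = cells.sum(axis=(0, 1))
    n_rows = (row_tot > 0).sum(axis=0)
    n_cols = (col_tot > 0).sum(axis=0)
    df = (n_rows - 1) * (n_cols - 1)

    p = np.ones(m)
    ok = df >= 1
    p[ok] = stats.chi2.sf(stat[ok], df[ok])
    n_mono = int((~ok).sum())
    if n_mono:
        logger.warning("%d monomorphic markers excluded from the screen", n_mono)
    small = ((expected < 5) & (expected > 0)).any(axis=(0, 1)) & ok
    if small.any():
        logger.info(
            "%d markers have an expected cell count < 5; the asymptotic "
            "chi-square approximation may be rough there", int(small.sum())
        )
    survivors = np.flatnonzero(ok & (p <= threshold))
    return p, survivors


def fit_binary_logistic(x: np.ndarray, y01: np.ndarray):
    """ML logistic fit of a binary level indicator on intercept + marker.

    Returns ``(coef, p_value, converged)`` where the p-value comes from
    the likelihood-ratio test against the intercept-only model.  A fit
    that fails to converge, or converges to ``|coef| > 15`` on the logit
    scale (complete or quasi-complete separation), is reported with
    ``converged=False`` and p = 1 so the marker is dropped.
    """
    x = np.asarray(x, float)
    y01 = np.asarray(y01, float)
    if np.ptp(x) == 0:
        raise ValidationError("marker is constant; logistic fit undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(MAX_NEWTON_ITER):
        eta = X @ beta
        p = special.expit(eta)
        w = p * (1.0 - p)
        grad = X.T @ (y01 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        beta = beta + step
        if np.abs(beta).max() > 1e3:
            break
        if np.abs(step).max() < 1e-10:
            converged = True
            break
    coef = float(beta[1])
    if not converged or abs(coef) > SEPARATION_COEF:
        return coef, 1.0, False
    eta = X @ beta
    ll = float(y01 @ eta - np.logaddexp(0.0, eta).sum())
    p0 = y01.mean()
    n = len(y01)
    ll0 = float(n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))) if 0 < p0 < 1 else 0.0
    lrt = max(0.0, 2.0 * (ll - ll0))
    return coef, float(stats.chi2.sf(lrt, 1)), True


def _cumlogit_nll_grad(params: np.ndarray, x: np.ndarray, codes: np.ndarray, L: int):
    """Negative log-likelihood and gradient of the proportional-odds model.

    Parameters are ``[b, theta_1, d_2, ..., d_{L-1}]`` with cutpoints
    ``theta_k = theta_1 + sum_{j<=k} exp(d_j)`` to enforce ordering.
    """
    b = params[0]
    theta = np.empty(L - 1)
    theta[0] = params[1]
    if L > 2:
        theta[1:] = params[1] + np.cumsum(np.exp(params[2:]))
    eta = b * x
    # cumulative probabilities F(theta_k - b x); pad with 0 and 1
    z = theta[None, :] - eta[:, None]          # (n, L-1)
    F = special.expit(z)
    f = F * (1.0 - F)
    Fpad = np.concatenate([np.zeros((len(x), 1)), F, np.ones((len(x), 1))], axis=1)
    upper = codes          # y_i = k -> P = F_k - F_{k-1}, k in 1..L
    P = Fpad[np.arange(len(x)), upper] - Fpad[np.arange(len(x)), upper - 1]
    P = np.clip(P, 1e-300, None)
    nll = -np.log(P).sum()

    fpad = np.concatenate([np.zeros((len(x), 1)), f, np.zeros((len(x), 1))], axis=1)
    fu = fpad[np.arange(len(x)), upper]
    fl = fpad[np.arange(len(x)), upper - 1]
    invP = 1.0 / P
    # d nll / d b  = sum_i x_i (f_u - f_l) / P
    g_b = float(np.sum(x * (fu - fl) * invP))
    # d nll / d theta_k = -sum_{y=k} f_k/P + sum_{y=k+1} f_k/P
    g_theta = np.zeros(L - 1)
    for k in range(1, L):
        at_upper = upper == k
        at_lower = upper == k + 1
        g_theta[k - 1] = -float(np.sum(fu[at_upper] * invP[at_upper])) + float(
            np.sum(fl[at_lower] * invP[at_lower])
        )
    grad = np.empty_like(params)
    grad[0] = g_b
    grad[1] = g_theta.sum()
    if L > 2:
        ed = np.exp(params[2:])
        # theta_j depends on d_k for j >= k+1
        tail = np.cumsum(g_theta[::-1])[::-1]
        grad[2:] = ed * tail[1:]
    return nll, grad


def fit_proportional_odds(x: np.ndarray, y: OrdinalPhenotype):
    """ML proportional-odds (cumulative-logit) fit with one slope.

    Returns ``(coef, p_value, converged)``; the p-value is the
    likelihood-ratio test of the slope against the cutpoints-only model,
    whose maximum likelihood has the closed multinomial form.  Unobserved
    intermediate levels are collapsed out (with a warning) before
    fitting; separation handling mirrors the binary fit.
    """
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise ValidationError("marker is constant; ordinal fit undefined")
    codes = y.codes()
    observed, codes = np.unique(codes, return_inverse=True)
    codes = codes + 1
    L = len(observed)
    if L < len(y.levels):
        logger.warning(
            "collapsed %d unobserved levels before the proportional-odds fit",
            len(y.levels) - L,
        )
    if L == 2:
        return fit_binary_logistic(x, (codes - 1).astype(float))

    n = len(x)
    props = np.bincount(codes, minlength=L + 1)[1:] / n
    cum = np.cumsum(props)[:-1]
    theta0 = special.logit(np.clip(cum, 1e-12, 1 - 1e-12))
    ll0 = float(n * np.sum(props[props > 0] * np.log(props[props > 0])))

    params0 = np.zeros(L)
    params0[1] = theta0[0]
    if L > 2:
        params0[2:] = np.log(np.maximum(np.diff(theta0), 1e-6))
    res = optimize.minimize(
        _cumlogit_nll_grad,
        params0,
        args=(x, codes, L),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10},
    )
    coef = float(res.x[0])
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm < 1e-5)
    if not converged or abs(coef) > SEPARATION_COEF:
        return coef, 1.0, False
    lrt = max(0.0, 2.0 * (-res.fun - ll0))
    return coef, float(stats.chi2.sf(lrt, 1)), True


def screen(
    G: GenotypeMatrix,
    y: OrdinalPhenotype,
    p_chi2: float = 0.05,
    p_logit: float = 0.05,
) -> ScreenResult:
    """Compose the chi-square and logistic stages into one screen.

    Stage-1 survivors (chi-square p <= ``p_chi2``) are refit one at a
    time with the binary-logistic or proportional-odds model on the
    centered dosage; markers with likelihood-ratio p <= ``p_logit`` and a
    well-behaved fit are retained, sorted by marker index.
    """
    chi2_p, stage1 = chi_square_scan(G, y, p_chi2)
    m = G.m
    logit_p = np.full(m, np.nan)
    logit_coef = np.full(m, np.nan)
    binary = y.L == 2 or len(np.unique(y.codes())) == 2
    y01 = (y.codes() == y.codes().max()).astype(float) if binary else None
    dropped = 0
    for j in stage1:
        xj = G.dosages[:, j]
        xj = xj - xj.mean()
        if binary:
            coef, p, ok = fit_binary_logistic(xj, y01)
        else:
            coef, p, ok = fit_proportional_odds(xj, y)
        logit_p[j] = p
        logit_coef[j] = coef
        if not ok:
            dropped += 1
    if dropped:
        logger.info(
            "dropped %d stage-1 survivors with separated/non-converged fits",
            dropped,
        )
    retained = stage1[np.nan_to_num(logit_p[stage1], nan=1.0) <= p_logit]
    return ScreenResult(
        chi2_p=chi2_p,
        logit_p=logit_p,
        logit_coef=logit_coef,
        retained=np.sort(retained),
        thresholds=(p_chi2, p_logit),
        stage1_survivors=stage1,
    )
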