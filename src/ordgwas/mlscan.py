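"""Two-stage multi-locus genome scan for continuous phenotypes.

Stage 1 is a fast single-marker fixed-effect scan (ordinary least
squares, optionally generalized least squares under a genomic
relationship matrix); markers below a lenient candidate p-value enter
stage 2, an empirical-Bayes multi-locus fit whose shrunken effects are
scored with LOD and called at LOD >= 3.  This is a reimplementation in
the style of the mrMLM family of random-SNP-effect methods, not a port:
the stage-1 threshold defaults to 0.005 and stage 2 is capped at
min(2n, m) candidates.

The scan is agnostic about where its phenotype came from: the
transformed CPData, raw continuous measurements, or integer-coded
ordinal levels all run the identical code path, which is what makes
"scan alone" vs "transform + scan" comparisons meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ebayes import EBayesConfig, eb_fit
from .genio import (
    ContinuousPhenotype,
    CovariateDesign,
    GenotypeMatrix,
    OrdinalPhenotype,
    ValidationError,
)

logger = logging.getLogger("ordgwas")

__all__ = ["ScanConfig", "ScanHit", "single_marker_scan", "scan", "kinship_matrix"]


@dataclass
class ScanConfig:
    """Stage thresholds and options of the multi-locus scan."""

    candidate_p: float = 0.005
    lod_threshold: float = 3.0
    use_kinship: bool = False
    max_candidates: int | None = None
    ebayes: EBayesConfig = None

    def __post_init__(self) -> None:
        if not 0 <= self.candidate_p <= 1:
            raise ValidationError("candidate_p must lie in [0, 1]")
        if self.lod_threshold <= 0:
            raise ValidationError("lod_threshold must be positive")
        if self.ebayes is None:
            self.ebayes = EBayesConfig(lod_threshold=self.lod_threshold)


@dataclass
class ScanHit:
    """One called QTN."""

    marker: str
    chrom: str
    pos: int
    effect: float
    lod: float
    stage1_p: float


def _as_values(y) -> np.ndarray:
    if isinstance(y, ContinuousPhenotype):
        return y.values
    if isinstance(y, OrdinalPhenotype):
        # ordinal levels coerced to their integer codes: the "scan alone
        # on hierarchical data" baseline treatment
        return y.as_numeric()
    return np.asarray(y, float)


def single_marker_scan(
    G: GenotypeMatrix,
    y,
    W: CovariateDesign | np.ndarray | None = None,
    kinship: np.ndarray | None = None,
) -> np.ndarray:
    """Per-marker p-values from OLS of y on [W | x_j] (GLS under kinship).

    The marker coefficient's two-sided t-test p-value is computed by
    residualizing both phenotype and marker on W (Frisch–Waugh), which
    is exact and vectorizes over the panel.  Monomorphic markers get
    p = 1.
    """
    yv = _as_values(y)
    n = len(yv)
    Wm = (
        np.ones((n, 1))
        if W is None
        else (W.W if isinstance(W, CovariateDesign) else np.atleast_2d(np.asarray(W, float)))
    )
    X = G.dosages.astype(float, copy=True)
    if not np.all(np.isfinite(X)):
        raise ValidationError("scan requires imputed (finite) dosages")
    if kinship is not None:
        T = _whitener(kinship)
        yv = T @ yv
        Wm = T @ Wm
        X = T @ X

    Wp = np.linalg.pinv(Wm)
    Xr = X - Wm @ (Wp @ X)
    yr = yv - Wm @ (Wp @ yv)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    syy = float(yr @ yr)
    scale = max(1.0, float(np.abs(yv).max()))
    if syy <= n * (1e-12 * scale) ** 2:
        # phenotype is constant after covariate adjustment (up to float
        # noise): nothing can associate with it
        logger.warning("phenotype is numerically constant; all scan p-values 1")
        return np.ones(X.shape[1])
    dof = n - Wm.shape[1] - 1
    if dof <= 0:
        raise ValidationError("not enough residual degrees of freedom")
    p = np.ones(X.shape[1])
    ok = sxx > 1e-12 * n
    slope = np.zeros_like(p)
    slope[ok] = (Xr[:, ok].T @ yr) / sxx[ok]
    rss = np.maximum(syy - slope**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / np.where(ok, sxx, 1.0))
        t = np.where(se > 0, np.abs(slope) / se, np.inf)
    p[ok] = 2.0 * stats.t.sf(t[ok], dof)
    return p


def _whitener(K: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of the relationship matrix."""
    vals, vecs = np.linalg.eigh(K)
    vals = np.clip(vals, 1e-6, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def scan(
    G: GenotypeMatrix,
    y,
    W: CovariateDesign | np.ndarray | None = None,
    cfg: ScanConfig | None = None,
) -> list[ScanHit]:
    """Run the two-stage multi-locus scan and return LOD >= threshold hits.

    Deterministic for a fixed input and configuration: there is no
    internal randomness anywhere in the scan.
    """
    cfg = cfg or ScanConfig()
    kin = kinship_matrix(G) if cfg.use_kinship else None
    p = single_marker_scan(G, y, W, kinship=kin)
    if cfg.candidate_p == 0:
        return []
    cand = np.flatnonzero(p <= cfg.candidate_p)
    cap = cfg.max_candidates or min(2 * G.n, G.m)
    if cand.size > cap:
        cand = cand[np.argsort(p[cand], kind="stable")[:cap]]
        cand = np.sort(cand)
    if cand.size == 0:
        return []
    X = G.centered(cand)
    n = len(_as_values(y))
    Wm = np.ones((n, 1)) if W is None else W
    fit = eb_fit(_as_values(y), Wm, X, cfg.ebayes)
    hits = [
        ScanHit(
            marker=G.markers[j],
            chrom=str(G.chrom[j]),
            pos=int(G.pos[j]),
            effect=float(fit.beta_mean[k]),
            lod=float(fit.lod[k]),
            stage1_p=float(p[j]),
        )
        for k, j in enumerate(cand)
        if fit.lod[k] >= cfg.lod_threshold
    ]
    hits.sort(key=lambda h: (h.chrom, h.pos))
    return hits


def hits_to_frame(hits: list[ScanHit]):
    """Tabulate scan hits (`marker chrom pos effect lod stage1_p`)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "marker": h.marker,
                "chrom": h.chrom,
                "pos": h.pos,
                "effect": h.effect,
                "lod": h.lod,
                "stage1_p": h.stage1_p,
            }
            for h in hits
        ],
        columns=["marker", "chrom", "pos", "effect", "lod", "stage1_p"],
    )


def kinship_matrix(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden-style standardized marker covariance, mean diagonal 1.

    Each marker column is centered and scaled by sqrt(2 p (1-p)); the
    cross-product over markers is then rescaled so the average diagonal
    is one.  Symmetric positive semidefinite by construction.
    """
    if G.m < 2:
        raise ValidationError("kinship needs at least 2 markers")
    D = G.dosages
    if not np.all(np.isfinite(D)):
        raise ValidationError("kinship requires imputed (finite) dosages")
    freq = D.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * freq * (1.0 - freq))
    ok = denom > 0
    Z = np.zeros_like(D)
    Z[:, ok] = (D[:, ok] - 2.0 * freq[ok]) / denom[ok]
    K = Z @ Z.T / ok.sum()
    K /= np.mean(np.diag(K))
    return K
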