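"""Per-probe linear models with a random block effect, and moderated t-tests.

The hybridization block (chip or mouse pool) is modelled as a random effect
through a compound-symmetry covariance: samples sharing a block have a
common within-block correlation rho, samples in different blocks are
independent.  A single consensus rho is estimated across probes (restricted
maximum likelihood per probe, then a trimmed mean on Fisher's z scale) and
plugged into a per-probe generalized least-squares fit of the group-means
design.

Empirical-Bayes moderation shrinks the per-probe residual variances s_g^2
toward a prior: sigma_g^2 ~ s0^2 * d0 / chi^2_{d0} (scaled inverse
chi-square).  The hyperparameters (d0, s0^2) are estimated by matching the
empirical mean and variance of log s_g^2 to their theoretical values
(digamma/trigamma moment equations).  The moderated statistic

    t_g = logFC_g / (u_c * s_tilde_g),
    s_tilde_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom (normal
when d0 is infinite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import DesignSpec, ExpressionExperiment, ValidationError
from .enrich import bh_adjust, holm_adjust

logger = logging.getLogger("eaexpr")


# ---------------------------------------------------------------------------
# design / whitening helpers
# ---------------------------------------------------------------------------

def _design_matrix(design: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Group-means (cell means) design matrix, one column per group."""
    levels = sorted(design.group.unique())
    X = np.column_stack([(design.group == g).to_numpy(float) for g in levels])
    empty = [g for g, n in zip(levels, X.sum(axis=0)) if n == 0]
    if empty:
        raise ValidationError(f"aliased group(s) with no samples: {empty}")
    return X, levels


def _block_slices(design: DesignSpec) -> list[np.ndarray]:
    blocks = design.block
    return [np.flatnonzero((blocks == b).to_numpy()) for b in blocks.unique()]


def _whitener(rho: float, block_indices: list[np.ndarray], n: int) -> tuple[np.ndarray, float]:
    """Inverse square root of the compound-symmetry covariance (unit
    diagonal, rho within blocks) and log|Sigma|."""
    W = np.zeros((n, n))
    logdet = 0.0
    for idx in block_indices:
        m = len(idx)
        lam1 = 1.0 - rho                 # eigenvalue on the contrast space
        lam2 = 1.0 - rho + m * rho       # eigenvalue on the block mean
        if lam1 <= 0 or lam2 <= 0:
            raise ValidationError(f"rho={rho} outside the admissible range")
        J = np.full((m, m), 1.0 / m)
        Wb = (np.eye(m) - J) / np.sqrt(lam1) + J / np.sqrt(lam2)
        W[np.ix_(idx, idx)] = Wb
        logdet += (m - 1) * np.log(lam1) + np.log(lam2)
    return W, logdet


def _admissible_range(design: DesignSpec) -> tuple[float, float]:
    m_max = int(design.block.value_counts().max())
    return (-1.0 / (m_max - 1) if m_max > 1 else -1.0, 1.0)


# ---------------------------------------------------------------------------
# consensus correlation
# ---------------------------------------------------------------------------

def estimate_consensus_correlation(
    exp: ExpressionExperiment,
    design: DesignSpec,
    trim: float = 0.15,
    n_grid: int = 61,
    return_per_probe: bool = False,
):
    """Consensus within-block correlation.

    Per probe, the REML profile likelihood of the compound-symmetry model is
    maximized over a grid on Fisher's z scale (with parabolic refinement);
    the consensus is tanh of the trimmed mean (``trim`` per tail) of
    atanh of the per-probe maxima, clamped to the admissible range.
    """
    if design.block.nunique() < 2:
        raise ValidationError(
            "single block: no within-block correlation is identifiable; "
            "use ordinary least squares (fit_gls with rho=0)"
        )
    Y = exp.intensities.to_numpy(dtype=float)
    X, _ = _design_matrix(design)
    n, p = X.shape
    block_idx = _block_slices(design)
    lo, _ = _admissible_range(design)
    lo_grid = max(lo + 0.02, -0.9)
    zgrid = np.linspace(np.arctanh(lo_grid), np.arctanh(0.98), n_grid)
    rgrid = np.tanh(zgrid)

    ll = np.empty((len(rgrid), Y.shape[0]))
    for i, rho in enumerate(rgrid):
        W, logdet = _whitener(rho, block_idx, n)
        Xw = W @ X
        Yw = Y @ W.T                                    # probes x samples
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ Yw.T)        # p x probes
        resid = Yw - beta.T @ Xw.T
        rss = np.einsum("ij,ij->i", resid, resid)
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        ll[i] = -0.5 * (logdet + logdet_xtx + (n - p) * np.log(np.maximum(rss, 1e-300)))

    best = np.argmax(ll, axis=0)
    z_hat = zgrid[best]
    # parabolic refinement for interior maxima
    interior = (best > 0) & (best < len(rgrid) - 1)
    if interior.any():
        i0 = best[interior]
        y0, y1, y2 = (ll[i0 - 1, np.flatnonzero(interior)],
                      ll[i0, np.flatnonzero(interior)],
                      ll[i0 + 1, np.flatnonzero(interior)])
        denom = y0 - 2 * y1 + y2
        step = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        dz = zgrid[1] - zgrid[0]
        z_hat[interior] = zgrid[i0] + np.clip(step, -1.0, 1.0) * dz

    # degenerate probes (zero residual variance) carry no information
    W0, _ = _whitener(0.0, block_idx, n)
    resid0 = Y @ W0.T
    X0 = W0 @ X
    beta0 = np.linalg.lstsq(X0, resid0.T, rcond=None)[0]
    rss0 = np.einsum("ij,ij->i", resid0 - beta0.T @ X0.T, resid0 - beta0.T @ X0.T)
    ok = rss0 > 1e-12 * np.maximum(np.einsum("ij,ij->i", Y, Y), 1.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("consensus correlation: %d degenerate probe(s) dropped", n_dropped)
    if not ok.any():
        # all probes degenerate: duplicated samples within blocks
        return float(np.tanh(np.arctanh(0.98)))
    consensus = float(np.tanh(stats.trim_mean(z_hat[ok], trim)))
    consensus = float(np.clip(consensus, lo + 0.01, 0.99))
    if return_per_probe:
        return consensus, pd.Series(np.tanh(z_hat), index=exp.intensities.index)
    return consensus


# ---------------------------------------------------------------------------
# GLS fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Per-probe GLS estimates under the consensus-correlation model."""

    coef: pd.DataFrame            # probes x groups
    s2: pd.Series                 # residual variance per probe
    df_resid: float               # n - rank(design), shared
    cov_unscaled: np.ndarray      # (X' Sigma^-1 X)^-1, groups x groups
    group_levels: list[str]
    rho: float
    n_samples: int


def fit_gls(
    exp: ExpressionExperiment, design: DesignSpec, rho: float = 0.0
) -> FitResult:
    """Generalized least squares per probe with block-compound-symmetric
    covariance (unit diagonal, ``rho`` off-diagonal within blocks)."""
    Y = exp.intensities.to_numpy(dtype=float)
    X, levels = _design_matrix(design)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("rank-deficient design matrix")
    lo, hi = _admissible_range(design)
    if not (lo < rho < hi):
        raise ValidationError(f"rho={rho} outside admissible range ({lo:.3f}, 1)")
    W, _ = _whitener(rho, _block_slices(design), n)
    Xw = W @ X
    Yw = Y @ W.T
    XtX = Xw.T @ Xw
    cov_unscaled = np.linalg.inv(XtX)
    beta = cov_unscaled @ (Xw.T @ Yw.T)             # p x probes
    resid = Yw - beta.T @ Xw.T
    rss = np.einsum("ij,ij->i", resid, resid)
    d = n - p
    return FitResult(
        coef=pd.DataFrame(beta.T, index=exp.intensities.index, columns=levels),
        s2=pd.Series(rss / d, index=exp.intensities.index),
        df_resid=float(d),
        cov_unscaled=cov_unscaled,
        group_levels=levels,
        rho=float(rho),
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class ModerationParams:
    """Scaled inverse-chi-square variance-prior hyperparameters."""

    d0: float      # prior degrees of freedom, may be inf
    s02: float     # prior variance


def _trigamma_inv(y: float) -> float:
    """Invert the (monotone decreasing) trigamma function."""
    if y <= 0:
        return np.inf
    f = lambda x: special.polygamma(1, x) - y
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def moderate(fit_or_s2, df: float | np.ndarray | None = None) -> ModerationParams:
    """Estimate (d0, s0^2) from the observed residual variances.

    Accepts a :class:`FitResult` or a vector of variances with ``df``.
    Method of moments on log s^2: the empirical variance in excess of the
    sampling component trigamma(d/2) identifies d0 through the trigamma
    inverse; the mean identifies s0^2.  Non-positive excess variance yields
    d0 = inf with a geometric-mean-based s0^2.
    """
    if isinstance(fit_or_s2, FitResult):
        s2 = fit_or_s2.s2.to_numpy(dtype=float)
        df = fit_or_s2.df_resid
    else:
        s2 = np.asarray(fit_or_s2, dtype=float)
        if df is None:
            raise ValidationError("df required when passing raw variances")
    if s2.size < 10:
        raise ValidationError("fewer than 10 probes: hyperparameters unidentifiable")
    dvec = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(dvec / 2.0) + np.log(dvec / 2.0)
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, dvec / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inv(evar)
        s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # zero excess dispersion: point-mass prior, geometric mean of s^2
        d0 = np.inf
        s02 = float(np.exp(np.mean(z)))
    return ModerationParams(d0=d0, s02=s02)


# ---------------------------------------------------------------------------
# contrast tests
# ---------------------------------------------------------------------------

def contrast_vector(contrast: dict[str, float], levels: list[str]) -> np.ndarray:
    c = np.zeros(len(levels))
    for g, w in contrast.items():
        if g not in levels:
            raise ValidationError(f"contrast references group {g!r} not in design")
        c[levels.index(g)] = w
    return c


def contrast_tests(
    fit: FitResult,
    params: ModerationParams,
    contrast: dict[str, float],
    adjust: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t-test of one zero-sum contrast for every probe.

    Returns a ContrastTable: ``logFC`` (log2), ``t``, ``p``, ``p_adj``,
    ``significant``, ``direction``.  ``params.d0 = 0`` yields the ordinary
    (unmoderated) t-statistic.
    """
    c = contrast_vector(contrast, fit.group_levels)
    lfc = fit.coef.to_numpy() @ c
    u = float(np.sqrt(c @ fit.cov_unscaled @ c))
    s2 = fit.s2.to_numpy(dtype=float)
    d = fit.df_resid
    d0, s02 = params.d0, params.s02
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    t = lfc / (u * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    if adjust == "BH":
        p_adj = bh_adjust(p)
    elif adjust == "holm":
        p_adj = holm_adjust(p)
    elif adjust == "none":
        p_adj = p.copy()
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    table = pd.DataFrame(
        {
            "logFC": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=fit.coef.index,
    )
    return table


def run_de(
    exp: ExpressionExperiment,
    contrasts: dict[str, dict[str, float]],
    adjust: str = "BH",
    alpha: float = 0.05,
    rho: float | None = None,
) -> tuple[dict[str, pd.DataFrame], float, ModerationParams]:
    """Convenience wrapper: consensus correlation, GLS, moderation, all
    contrast tables.  ``rho`` overrides the estimated consensus."""
    design = DesignSpec.from_experiment(exp, contrasts)
    if rho is None:
        rho = estimate_consensus_correlation(exp, design)
    fit = fit_gls(exp, design, rho)
    params = moderate(fit)
    tables = {
        name: contrast_tests(fit, params, cdef, adjust=adjust, alpha=alpha)
        for name, cdef in contrasts.items()
    }
    return tables, rho, params
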