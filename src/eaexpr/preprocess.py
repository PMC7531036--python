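"""Probe filtering, variance-stabilizing normalization, batch checks.

The detection filter retains probes that are reliably detected: detection
p < ``detect_alpha`` in at least ``detected_fraction`` of samples.  Read
literally, the source protocol ("removed if detection p < 0.05 in more than
10% of samples") would discard exactly the well-detected probes; the
``literal=True`` switch reproduces that verbatim rule for comparison, the
default implements the standard detection-filter semantics.

The variance-stabilizing transform is a generalized log (glog) of
affine-calibrated intensities:

    h_s(x) = log2( z + sqrt(z^2 + c) ) - 1,   z = (x - a_s) / b_s

with per-sample affine parameters (a_s, b_s) fitted robustly (trimmed least
squares against the across-sample reference mean) and a single curvature
constant c estimated so that additive background noise and multiplicative
high-intensity noise are balanced: c = sigma_bg^2 / (ln2 * sigma_mult)^2.
For c -> 0 the transform reduces to an affine map of log2.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionExperiment, ValidationError

logger = logging.getLogger("eaexpr")

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# detection / quality filter
# ---------------------------------------------------------------------------

def filter_probes(
    exp: ExpressionExperiment,
    detect_alpha: float = 0.05,
    detected_fraction: float = 0.9,
    drop_quality: set[str] = frozenset({"bad", "no_match"}),
    literal: bool = False,
) -> ExpressionExperiment:
    """Keep reliably detected probes of acceptable quality.

    Default rule: detection p < ``detect_alpha`` in >= ``detected_fraction``
    of samples AND quality not in ``drop_quality``.  ``literal=True`` instead
    removes probes detected in more than 1 - detected_fraction of samples
    (the verbatim protocol wording).
    """
    if not (0.0 <= detected_fraction <= 1.0):
        raise ValidationError("detected_fraction must lie in [0, 1]")
    if exp.detection_p is None:
        raise ValidationError("experiment has no detection p-values")
    D = exp.detection_p.to_numpy()
    frac_detected = (D < detect_alpha).mean(axis=1)
    if literal:
        keep_detect = ~(frac_detected > (1.0 - detected_fraction))
    else:
        keep_detect = frac_detected >= detected_fraction
    quality = exp.probe_annot["quality"].to_numpy()
    keep_quality = ~np.isin(quality, list(drop_quality))
    keep = keep_detect & keep_quality
    logger.info(
        "filter_probes: %d/%d retained (%d failed detection, %d failed quality)",
        int(keep.sum()), len(keep),
        int((~keep_detect).sum()), int((~keep_quality).sum()),
    )
    return exp.subset_probes(exp.intensities.index[keep])


# ---------------------------------------------------------------------------
# variance-stabilizing transform
# ---------------------------------------------------------------------------

def _trimmed_affine(x: np.ndarray, ref: np.ndarray, keep: float = 0.7,
                    n_iter: int = 5) -> tuple[float, float]:
    """Least-trimmed-squares-style affine fit x ~ a + b * ref."""
    mask = np.ones(len(x), dtype=bool)
    a, b = 0.0, 1.0
    for _ in range(n_iter):
        r, xk = ref[mask], x[mask]
        b = np.cov(r, xk)[0, 1] / max(np.var(r), 1e-12)
        a = xk.mean() - b * r.mean()
        resid = np.abs(x - (a + b * ref))
        cut = np.quantile(resid, keep)
        mask = resid <= cut
        if mask.sum() < 10:
            break
    if b <= 0:
        b = 1.0
    return float(a), float(b)


def glog2(z: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2: log2(z + sqrt(z^2 + c)) - 1, monotone for c > 0."""
    return np.log2(z + np.sqrt(z * z + c)) - 1.0


def vst_transform(
    exp: ExpressionExperiment, c: float | None = None, bg_tolerance: float = 5.0
) -> ExpressionExperiment:
    """Calibrate samples to a common scale and apply a glog transform.

    ``c`` overrides the estimated curvature constant.  Raw input is expected;
    intensities below ``-bg_tolerance`` (negative beyond what background
    correction could plausibly produce) raise an error.
    """
    if exp.scale != "raw":
        raise ValidationError("vst_transform expects a raw-scale experiment")
    X = exp.intensities.to_numpy(dtype=float)
    if X.min() < -bg_tolerance:
        raise ValidationError("negative intensities beyond background tolerance")
    ref = X.mean(axis=1)
    Z = np.empty_like(X)
    for j in range(X.shape[1]):
        a, b = _trimmed_affine(X[:, j], ref)
        Z[:, j] = (X[:, j] - a) / b

    # curvature constant from additive (background) and multiplicative noise
    order = np.argsort(ref)
    low = order[: max(10, len(ref) // 10)]          # bottom decile by mean
    high = order[-max(10, len(ref) // 4):]          # top quartile by mean
    sigma_bg = float(np.median(Z[low].std(axis=1, ddof=1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        logz = np.log2(np.clip(Z[high], 1e-6, None))
    sigma_mult = float(np.median(
        stats.median_abs_deviation(logz, axis=1, scale="normal")
    ))
    sigma_mult = max(sigma_mult, 1e-3)
    if c is None:
        c = (sigma_bg / (LN2 * sigma_mult)) ** 2
    logger.info(
        "vst_transform: sigma_bg=%.3g sigma_mult=%.3g c=%.4g", sigma_bg, sigma_mult, c
    )
    H = glog2(Z, c)
    out = replace(
        exp,
        intensities=pd.DataFrame(
            H, index=exp.intensities.index, columns=exp.intensities.columns
        ),
        scale="normalized",
    )
    return out.validate()


def decile_sd_ratio(
    exp: ExpressionExperiment, q: float = 0.1
) -> float:
    """Ratio of median within-group replicate sd in the top vs bottom
    mean-intensity decile — the mean-variance relationship the VST flattens."""
    X = exp.intensities
    groups = exp.groups
    sds = []
    for _, cols in groups.groupby(groups):
        sub = X[cols.index.tolist()]
        if sub.shape[1] >= 2:
            sds.append(sub.std(axis=1, ddof=1))
    rep_sd = pd.concat(sds, axis=1).median(axis=1)
    mean_int = X.mean(axis=1)
    lo_cut, hi_cut = mean_int.quantile(q), mean_int.quantile(1.0 - q)
    lo = rep_sd[mean_int <= lo_cut].median()
    hi = rep_sd[mean_int >= hi_cut].median()
    return float(hi / lo)


# ---------------------------------------------------------------------------
# technical-factor association
# ---------------------------------------------------------------------------

def batch_association(
    exp: ExpressionExperiment,
    n_pcs: int = 10,
    factors: tuple[str, ...] = ("block", "position"),
    flag_alpha: float = 1e-3,
) -> pd.DataFrame:
    """One-way ANOVA p-values of the first ``n_pcs`` sample-space principal
    components against each technical factor.

    Degenerate factors (fewer than two levels, or as many levels as samples)
    are skipped with a warning.  Returns a tidy table with columns
    ``pc``, ``factor``, ``p``, ``flagged``.
    """
    X = exp.intensities.to_numpy(dtype=float)
    n = X.shape[1]
    max_pcs = n - 1
    if n_pcs > max_pcs:
        logger.warning("batch_association: n_pcs truncated from %d to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    Xc = X - X.mean(axis=1, keepdims=True)
    # sample-space PCs: SVD of the centered matrix, scores = columns of V * s
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = (Vt[:n_pcs, :] * s[:n_pcs, None]).T    # samples x PCs

    rows = []
    for name in factors:
        if name not in exp.sample_annot.columns:
            logger.warning("batch_association: factor %r absent, skipped", name)
            continue
        fac = exp.sample_annot[name].astype(str)
        levels = fac.unique()
        if len(levels) < 2 or len(levels) >= n:
            logger.warning(
                "batch_association: factor %r degenerate (%d levels), skipped",
                name, len(levels),
            )
            continue
        for k in range(n_pcs):
            groups = [scores[fac.to_numpy() == lv, k] for lv in levels]
            _, p = stats.f_oneway(*groups)
            rows.append((k + 1, name, float(p), bool(p < flag_alpha)))
    return pd.DataFrame(rows, columns=["pc", "factor", "p", "flagged"])
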