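"""Gene-set principal-component disease scores and clustering stability.

PC scoring projects the normalized samples onto the leading principal
components of the submatrix of transcripts belonging to a gene set (PCA on
the covariance scale: variables centered, not scaled), standardizes the
scores to unit variance for display, and compares disease groups against
pooled controls.  Clustering stability repeats k-means with random
initializations and reports the modal partition and how often a given
healthy/diseased bipartition is respected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .enrich import bh_adjust, holm_adjust
from .io import ExpressionExperiment, ValidationError

logger = logging.getLogger("eaexpr")


# ---------------------------------------------------------------------------
# gene-set PC scores
# ---------------------------------------------------------------------------

@dataclass
class PCScoreResult:
    scores: pd.DataFrame            # samples x components, unit variance
    variance_explained: np.ndarray  # fractions, non-increasing
    n_probes: int


def pca_scores(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples x variables data on the covariance scale.

    Returns standardized scores (unit sample variance) and the
    variance-explained fractions.  Orientation is fixed so every component's
    loading sum is positive (sign-deterministic outputs).
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(s))
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :n_components] * s[:n_components]
    for k in range(n_components):
        if Vt[k].sum() < 0:
            scores[:, k] *= -1.0
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return scores / sd, frac[:n_components]


def geneset_pc_scores(
    exp: ExpressionExperiment,
    gene_set,
    n_components: int = 2,
) -> PCScoreResult:
    """PC scores of the samples over the probes of a gene set's members."""
    gene_set = set(gene_set)
    gm = exp.probe_annot["gene_id"]
    probes = [p for p in exp.intensities.index if gm.get(p) in gene_set]
    if len(probes) < 2:
        missing = sorted(gene_set - set(gm.dropna()))
        raise ValidationError(
            f"fewer than 2 member probes on the platform; missing genes: {missing[:10]}"
        )
    X = exp.intensities.loc[probes].to_numpy(dtype=float).T  # samples x probes
    scores, frac = pca_scores(X, n_components)
    return PCScoreResult(
        scores=pd.DataFrame(
            scores,
            index=exp.intensities.columns,
            columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
        ),
        variance_explained=frac,
        n_probes=len(probes),
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_score_groups(
    scores: pd.Series,
    groups: pd.Series,
    control_groups,
    test: str = "welch",
    adjust: str = "BH",
) -> pd.DataFrame:
    """Two-sided test of each non-control group against pooled controls.

    ``test``: "welch" (unequal-variance t) or "wilcoxon" (rank-sum).
    Groups with fewer than 2 samples are skipped with a warning.
    """
    control_groups = set(control_groups)
    ctrl = scores[groups.isin(control_groups)]
    rows = []
    for g in [g for g in groups.unique() if g not in control_groups]:
        vals = scores[groups == g]
        if len(vals) < 2:
            logger.warning("compare_score_groups: group %s has < 2 samples, skipped", g)
            continue
        if test == "welch":
            t, p = stats.ttest_ind(vals, ctrl, equal_var=False)
        elif test == "wilcoxon":
            t, p = stats.ranksums(vals, ctrl)
        else:
            raise ValidationError(f"unknown test {test!r}")
        rows.append({"group": g, "statistic": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"]) if adjust == "BH" else holm_adjust(df["p"])
        df["stars"] = [_stars(p) for p in df["p_adj"]]
    return df


# ---------------------------------------------------------------------------
# k-means stability
# ---------------------------------------------------------------------------

@dataclass
class PartitionRecord:
    labels: tuple[int, ...]   # canonical, relabeled by smallest member index
    frequency: int
    inertia: float            # within-cluster sum of squares (best repeat)


def canonicalize(labels) -> tuple[int, ...]:
    """Relabel clusters by order of first appearance (smallest member index),
    making the representation invariant to label permutations."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def kmeans_stability(
    features: np.ndarray | pd.DataFrame,
    k: int = 4,
    n_rep: int = 100,
    seed: int = 0,
) -> tuple[list[PartitionRecord], PartitionRecord]:
    """Repeat k-means with random initializations; aggregate canonical
    partitions and return (all records, modal partition)."""
    X = np.asarray(features, dtype=float)
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of samples {X.shape[0]}")
    ss = np.random.SeedSequence(int(seed))
    child_seeds = ss.generate_state(n_rep) % (2**31)
    tally: dict[tuple[int, ...], list] = {}
    for rep in range(n_rep):
        km = KMeans(n_clusters=k, n_init=1, init="random",
                    random_state=int(child_seeds[rep])).fit(X)
        canon = canonicalize(km.labels_)
        entry = tally.setdefault(canon, [0, np.inf])
        entry[0] += 1
        entry[1] = min(entry[1], float(km.inertia_))
    records = [
        PartitionRecord(labels=lab, frequency=f, inertia=inert)
        for lab, (f, inert) in sorted(tally.items(), key=lambda kv: -kv[1][0])
    ]
    return records, records[0]


def bipartition_respect(
    partitions: list[PartitionRecord] | list[tuple[int, ...]],
    side_a: np.ndarray,
    side_b: np.ndarray,
) -> float:
    """Fraction of repeats in which no cluster mixes the two sides
    (boolean masks over samples)."""
    side_a = np.asarray(side_a, dtype=bool)
    side_b = np.asarray(side_b, dtype=bool)
    total = 0
    respected = 0
    for part in partitions:
        labels = np.asarray(part.labels if isinstance(part, PartitionRecord) else part)
        freq = part.frequency if isinstance(part, PartitionRecord) else 1
        ok = True
        for lab in np.unique(labels):
            members = labels == lab
            if (members & side_a).any() and (members & side_b).any():
                ok = False
                break
        total += freq
        respected += freq if ok else 0
    return respected / total if total else 0.0
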