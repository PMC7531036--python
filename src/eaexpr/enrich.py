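"""Permutation gene-set overlap test, its closed-form oracle, and ORA.

The permutation test asks whether the observed overlap between a list of
differentially expressed (DE) genes and a test set (for example, prioritized
human MS susceptibility genes mapped to mouse) is larger than expected by
chance: each permutation draws as many genes as the DE list, uniformly
without replacement from the universe, and the p-value is the fraction of
permutations whose overlap with the test set is at least the observed one.
Because a uniformly drawn subset's overlap with a fixed set follows the
hypergeometric law exactly, the default implementation samples the overlap
count directly (one vectorized hypergeometric draw per permutation); a
literal subset-drawing path (``method="subset"``) is provided and the exact
hypergeometric tail is exposed separately as an analytic oracle.

Zero-exceedance convention: when no permutation reaches the observed
overlap, the p-value is stored as 1/n_perm and flagged censored (displayed
as "< 1/n_perm"); multiple-testing adjustment operates on the stored value.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError

logger = logging.getLogger("eaexpr")


# ---------------------------------------------------------------------------
# multiple-testing adjustments
# ---------------------------------------------------------------------------

def _check_pvals(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return p


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjustment: sort ascending, multiply the i-th smallest
    by (m - i + 1), enforce the running maximum, cap at 1."""
    p = _check_pvals(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = _check_pvals(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# overlap tests
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    """One row of an enrichment table."""

    set_name: str
    n_de: int            # unique DE genes in the universe
    n_set: int           # test set size after intersection with the universe
    n_universe: int
    n_overlap: int       # observed overlap
    n_perm: int
    n_ge: int            # permutations with overlap >= observed
    p_raw: float         # max(n_ge, 1) / n_perm
    censored: bool       # True iff n_ge == 0
    p_adj: float = np.nan
    seed: int = 0

    def display_p(self) -> str:
        return f"<{1.0 / self.n_perm:g}" if self.censored else f"{self.p_raw:.3g}"


def _clean_inputs(de_genes, test_set, universe):
    universe = sorted(set(universe))
    uni = set(universe)
    de = set(de_genes)
    outside = de - uni
    if outside:
        logger.warning(
            "permutation test: %d DE gene(s) outside the universe dropped", len(outside)
        )
        de &= uni
    test = set(test_set) & uni
    return de, test, universe


def permutation_overlap_test(
    de_genes,
    test_set,
    universe,
    n_perm: int = 100_000,
    seed: int = 0,
    method: str = "hypergeom",
    set_name: str = "",
) -> EnrichmentRecord:
    """Permutation test of DE-list / test-set overlap.

    ``method="hypergeom"`` draws each permutation's overlap count directly
    from its exact null law; ``method="subset"`` literally draws gene
    subsets (slower, used for cross-validation).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    de, test, universe = _clean_inputs(de_genes, test_set, universe)
    N, n_de, n_test = len(universe), len(de), len(test)
    if N < n_de:
        raise ValidationError("universe smaller than the DE set")
    observed = len(de & test)
    rng = np.random.default_rng(int(seed) % (2**31))
    if n_de == 0 or n_test == 0:
        n_ge = n_perm if observed == 0 else 0
    elif method == "hypergeom":
        draws = rng.hypergeometric(n_test, N - n_test, n_de, size=n_perm)
        n_ge = int((draws >= observed).sum())
    elif method == "subset":
        test_mask = np.zeros(N, dtype=bool)
        idx_of = {g: i for i, g in enumerate(universe)}
        for g in test:
            test_mask[idx_of[g]] = True
        n_ge = 0
        for _ in range(n_perm):
            pick = rng.choice(N, size=n_de, replace=False)
            if int(test_mask[pick].sum()) >= observed:
                n_ge += 1
    else:
        raise ValidationError(f"unknown method {method!r}")
    censored = n_ge == 0
    p_raw = max(n_ge, 1) / n_perm
    return EnrichmentRecord(
        set_name=set_name, n_de=n_de, n_set=n_test, n_universe=N,
        n_overlap=observed, n_perm=n_perm, n_ge=n_ge,
        p_raw=p_raw, censored=censored, seed=int(seed),
    )


def hypergeometric_overlap(de_genes, test_set, universe) -> float:
    """Exact upper-tail overlap probability P(X >= observed), X hypergeometric,
    computed in log space."""
    de, test, universe = _clean_inputs(de_genes, test_set, universe)
    N, n_de, n_test = len(universe), len(de), len(test)
    if N < n_de:
        raise ValidationError("universe smaller than the DE set")
    observed = len(de & test)
    if observed == 0:
        return 1.0
    # sf(k) = P(X > k); upper tail inclusive of `observed`
    logsf = stats.hypergeom.logsf(observed - 1, N, n_test, n_de)
    return float(np.exp(logsf))


def run_enrichment_suite(
    analysis_sets: dict[str, set[str]] | GeneSetCollection,
    collections: GeneSetCollection,
    universe,
    n_perm: int = 100_000,
    seed: int = 0,
    adjust: str = "holm",
) -> pd.DataFrame:
    """One permutation test per (analysis set x test set), adjusted across
    the whole table.

    Each test gets its own reproducible stream: the master seed offset by a
    CRC32 hash of the (analysis set, test set) name pair, so rows do not
    depend on execution order.
    """
    if isinstance(analysis_sets, GeneSetCollection):
        analysis_sets = {n: set(analysis_sets[n]) for n in analysis_sets.names()}
    records: list[EnrichmentRecord] = []
    for a_name, de_genes in analysis_sets.items():
        for t_name in collections.names():
            label = f"{a_name}|{t_name}"
            sub = (int(seed) + zlib.crc32(label.encode())) % (2**31)
            if len(de_genes) == 0:
                rec = EnrichmentRecord(
                    set_name=label, n_de=0, n_set=len(collections[t_name]),
                    n_universe=len(set(universe)), n_overlap=0, n_perm=n_perm,
                    n_ge=n_perm, p_raw=1.0, censored=False, seed=sub,
                )
                logger.warning("enrichment: empty analysis set %s", a_name)
            else:
                rec = permutation_overlap_test(
                    de_genes, collections[t_name], universe,
                    n_perm=n_perm, seed=sub, set_name=label,
                )
            records.append(rec)
    praw = np.array([r.p_raw for r in records])
    if adjust == "holm":
        padj = holm_adjust(praw)
    elif adjust == "BH":
        padj = bh_adjust(praw)
    elif adjust == "none":
        padj = praw.copy()
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    rows = []
    for r, pa in zip(records, padj):
        r.p_adj = float(pa)
        a_name, _, t_name = r.set_name.partition("|")
        rows.append(
            {
                "analysis_set": a_name, "test_set": t_name,
                "n_de": r.n_de, "n_set": r.n_set, "n_overlap": r.n_overlap,
                "n_perm": r.n_perm, "n_ge": r.n_ge,
                "p_raw": r.p_raw, "censored": r.censored,
                "p_display": r.display_p(), "p_adj": r.p_adj, "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def ora(
    gene_list,
    collections: GeneSetCollection,
    universe,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Overrepresentation analysis: hypergeometric test per set, adjusted
    across sets (generic machinery; no annotation database is shipped)."""
    rows = []
    for name in collections.names():
        de, test, uni = _clean_inputs(gene_list, collections[name], universe)
        p = hypergeometric_overlap(de, test, uni)
        rows.append(
            {
                "test_set": name, "n_de": len(de), "n_set": len(test),
                "n_overlap": len(de & test), "p_raw": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"]) if adjust == "BH" else holm_adjust(df["p_raw"])
    return df
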