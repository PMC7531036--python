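"""Permutation overlap test vs exact oracles, censoring convention, and the
step-down / step-up adjustments (including the published-table regression)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eaexpr as ex
from eaexpr.reference_tables import ALL_TABLES, two_sig_figs

UNIVERSE10 = [f"g{i}" for i in range(10)]


# ---------------------------------------------------------------------------
# adjustments
# ---------------------------------------------------------------------------

def test_holm_direct_evaluation():
    out = ex.holm_adjust([0.01, 0.02, 0.03])
    assert np.allclose(out, [0.03, 0.04, 0.04])
    assert ex.holm_adjust([0.03])[0] == pytest.approx(0.03)


def test_bh_direct_evaluation():
    out = ex.bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(out, [0.03, 0.03, 0.03])
    assert np.allclose(ex.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_adjustments_reject_invalid_pvalues():
    with pytest.raises(ex.ValidationError):
        ex.holm_adjust([0.5, 1.2])
    with pytest.raises(ex.ValidationError):
        ex.bh_adjust([-0.1])


def test_holm_reproduces_published_adjusted_cells():
    """Step-down adjustment of the published raw p columns (with the
    1/n_perm censoring convention) reproduces every printed adjusted cell at
    two significant figures, including the running-maximum pairs."""
    for tname, rows in ALL_TABLES.items():
        raw = [r[1] for r in rows]
        printed = [r[3] for r in rows]
        adj = ex.holm_adjust(raw)
        for (label, *_), a, want in zip(rows, adj, printed):
            assert two_sig_figs(a) == pytest.approx(want), (tname, label)


def test_table3_single_row_closed_form():
    """The sixth-smallest of eight raw p-values, 9.7e-3, adjusts to
    6 x 9.7e-3 = 5.8e-2 at two significant figures."""
    raw = [r[1] for r in ALL_TABLES["table3"]]
    adj = ex.holm_adjust(raw)
    i = raw.index(9.7e-3)
    assert two_sig_figs(adj[i]) == pytest.approx(5.8e-2)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_adjustments_permutation_equivariant_and_dominating(p, rnd):
    p = np.asarray(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    perm = np.asarray(perm)
    for adj in (ex.holm_adjust, ex.bh_adjust):
        a = adj(p)
        assert np.all(a >= p - 1e-12)          # adjusted >= raw
        assert np.all(a <= 1.0 + 1e-12)
        assert np.allclose(adj(p[perm]), a[perm])   # permutation-equivariant


def test_adjustment_not_idempotent_on_random_input():
    rng = np.random.default_rng(8)
    p = rng.random(20) * 0.02
    once = ex.holm_adjust(p)
    assert not np.allclose(ex.holm_adjust(once), once)


# ---------------------------------------------------------------------------
# hypergeometric oracle
# ---------------------------------------------------------------------------

def test_hypergeom_zero_overlap_is_one():
    assert ex.hypergeometric_overlap(["g8", "g9"], ["g0"], UNIVERSE10) == 1.0


def test_hypergeom_enumeration_toys():
    # universe 10, test 3, de 4, observed 2 -> 1/3 exactly
    de = ["g0", "g1", "g2", "g3"]
    test = ["g0", "g1", "g4"]
    assert ex.hypergeometric_overlap(de, test, UNIVERSE10) == pytest.approx(1 / 3)
    # universe 5, test 2, de 2, observed 2 -> C(2,2)C(3,0)/C(5,2) = 1/10
    uni5 = UNIVERSE10[:5]
    assert ex.hypergeometric_overlap(["g0", "g1"], ["g0", "g1"], uni5) == pytest.approx(0.1)


def _exact_by_enumeration(universe, test, n_de, observed):
    """Enumerate all C(N, n_de) DE-set draws and count overlap >= observed."""
    test = set(test)
    hits = total = 0
    for combo in itertools.combinations(universe, n_de):
        total += 1
        hits += len(set(combo) & test) >= observed
    return hits / total


def test_hypergeom_matches_full_enumeration():
    test = ["g0", "g1", "g2"]
    for n_de, observed in [(4, 1), (4, 2), (6, 2), (6, 3)]:
        exact = _exact_by_enumeration(UNIVERSE10, test, n_de, observed)
        de = [f"g{i}" for i in range(n_de - observed)]  # irrelevant to tail
        # compute the tail directly from the distribution parameters
        from scipy import stats as ss
        tail = ss.hypergeom.sf(observed - 1, 10, 3, n_de)
        assert tail == pytest.approx(exact, rel=1e-12)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_saturation():
    rec = ex.permutation_overlap_test(["g0", "g1"], UNIVERSE10, UNIVERSE10,
                                      n_perm=1000, seed=0)
    assert rec.n_ge == 1000 and rec.p_raw == 1.0 and not rec.censored


def test_permutation_toy_matches_exact():
    de = ["g0", "g1", "g2", "g3"]
    test = ["g0", "g1", "g4"]
    rec = ex.permutation_overlap_test(de, test, UNIVERSE10, n_perm=100_000, seed=5)
    se = math.sqrt((1 / 3) * (2 / 3) / 100_000)
    assert abs(rec.p_raw - 1 / 3) <= 3 * se


def test_subset_method_agrees_with_fast_path():
    """The literal subset-drawing permutation agrees with the direct
    overlap-law sampling within Monte-Carlo error."""
    universe = [f"g{i}" for i in range(60)]
    de = universe[:12]
    test = universe[6:21]
    fast = ex.permutation_overlap_test(de, test, universe, n_perm=20_000, seed=1)
    slow = ex.permutation_overlap_test(de, test, universe, n_perm=4000, seed=2,
                                       method="subset")
    exact = ex.hypergeometric_overlap(de, test, universe)
    for rec in (fast, slow):
        se = math.sqrt(exact * (1 - exact) / rec.n_perm)
        assert abs(rec.p_raw - exact) <= 3 * se + 1e-9


def test_censoring_convention():
    """Zero exceedances at n_perm = 100,000: stored p is 1e-5, displayed
    '<1e-05'."""
    universe = [f"g{i}" for i in range(1000)]
    de = universe[:50]
    test = universe[:50]          # observed overlap 50: unreachable by chance
    rec = ex.permutation_overlap_test(de, test, universe, n_perm=100_000, seed=9)
    assert rec.n_ge == 0 and rec.censored
    assert rec.p_raw == pytest.approx(1e-5)
    assert rec.display_p() == "<1e-05"


def test_permutation_input_handling():
    # too few permutations
    with pytest.raises(ex.ValidationError):
        ex.permutation_overlap_test(["g0"], ["g1"], UNIVERSE10, n_perm=50, seed=0)
    # DE genes outside the universe are dropped with a warning
    rec = ex.permutation_overlap_test(UNIVERSE10 + ["zz1", "zz2"], UNIVERSE10[:2],
                                      UNIVERSE10, n_perm=1000, seed=0)
    assert rec.n_de == 10


def test_permutation_grid_agrees_with_hypergeometric():
    """Seeded grid of overlap problems: Monte-Carlo estimate within three
    standard errors of the exact tail."""
    rng = np.random.default_rng(2024)
    n_perm = 20_000
    for N, f_test, f_de in [(50, 0.2, 0.3), (200, 0.1, 0.2), (1000, 0.05, 0.1),
                            (2000, 0.25, 0.05)]:
        universe = [f"g{i}" for i in range(N)]
        test = list(rng.choice(universe, size=int(f_test * N), replace=False))
        de = list(rng.choice(universe, size=int(f_de * N), replace=False))
        exact = ex.hypergeometric_overlap(de, test, universe)
        rec = ex.permutation_overlap_test(de, test, universe, n_perm=n_perm,
                                          seed=int(rng.integers(2**31)))
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(rec.p_raw - exact) <= 3 * se + 1 / n_perm, (N, exact, rec.p_raw)


# ---------------------------------------------------------------------------
# suite + ora
# ---------------------------------------------------------------------------

def test_suite_deterministic_and_order_independent():
    universe = [f"g{i}" for i in range(500)]
    rng = np.random.default_rng(0)
    analysis = {
        "setA": set(rng.choice(universe, 60, replace=False)),
        "setB": set(rng.choice(universe, 40, replace=False)),
    }
    coll = ex.GeneSetCollection({"t1": set(universe[:80]), "t2": set(universe[80:150])})
    t1 = ex.run_enrichment_suite(analysis, coll, universe, n_perm=2000, seed=11)
    t2 = ex.run_enrichment_suite(dict(reversed(list(analysis.items()))), coll,
                                 universe, n_perm=2000, seed=11)
    m1 = t1.set_index(["analysis_set", "test_set"])["p_raw"]
    m2 = t2.set_index(["analysis_set", "test_set"])["p_raw"]
    assert m1.sort_index().equals(m2.sort_index())


def test_suite_empty_analysis_set_flagged():
    universe = [f"g{i}" for i in range(100)]
    coll = ex.GeneSetCollection({"t": set(universe[:10])})
    table = ex.run_enrichment_suite({"empty": set()}, coll, universe,
                                    n_perm=1000, seed=0)
    row = table.iloc[0]
    assert row["n_de"] == 0 and row["p_raw"] == 1.0


def test_ora_empty_list_all_p_one():
    universe = [f"g{i}" for i in range(100)]
    coll = ex.GeneSetCollection({"a": set(universe[:10]), "b": set(universe[10:30])})
    table = ex.ora([], coll, universe)
    assert (table["p_raw"] == 1.0).all()
    assert (table["p_adj"] == 1.0).all()


def test_ora_matches_hypergeometric_setwise():
    universe = [f"g{i}" for i in range(100)]
    coll = ex.GeneSetCollection({"a": set(universe[:20]), "b": set(universe[50:70])})
    gene_list = universe[10:40]
    table = ex.ora(gene_list, coll, universe).set_index("test_set")
    for name in ("a", "b"):
        assert table.loc[name, "p_raw"] == pytest.approx(
            ex.hypergeometric_overlap(gene_list, coll[name], universe)
        )
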