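"""GLS with block correlation, consensus-rho estimation, moderation, and the
moderated t pipeline, including an independent limma cross-check."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import eaexpr as ex
from eaexpr.de import moderate
from conftest import clean_config


def _two_group_exp(values, groups, blocks):
    samples = pd.Index([f"s{i}" for i in range(len(values))], name="sample_id")
    probes = pd.Index(["p1"], name="probe_id")
    return ex.ExpressionExperiment(
        intensities=pd.DataFrame([values], index=probes, columns=samples),
        detection_p=None,
        sample_annot=pd.DataFrame(
            {"group": groups, "block": blocks,
             "position": [str(i) for i in range(len(values))]},
            index=samples),
        probe_annot=pd.DataFrame({"gene_id": ["g1"], "quality": ["good"]},
                                 index=probes),
        scale="normalized",
    ).validate()


def test_gls_two_group_closed_form():
    """y = (1,2,3,4), groups (A,A,B,B), rho = 0: contrast B-A gives
    logFC = 2, s^2 = 0.5, d = 2 (pooled two-sample means)."""
    exp = _two_group_exp([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"],
                         ["b1", "b2", "b1", "b2"])
    design = ex.DesignSpec.from_experiment(exp, {"B-A": {"B": 1.0, "A": -1.0}})
    fit = ex.fit_gls(exp, design, rho=0.0)
    assert fit.coef.loc["p1", "B"] - fit.coef.loc["p1", "A"] == pytest.approx(2.0)
    assert fit.s2.loc["p1"] == pytest.approx(0.5)
    assert fit.df_resid == 2


def test_gls_rho_zero_equals_ols(normalized):
    norm, _ = normalized
    design = ex.DesignSpec.from_experiment(norm, ex.EAE_CONTRASTS)
    gls = ex.fit_gls(norm, design, rho=0.0)
    # direct OLS oracle: per-group means
    for g in gls.group_levels:
        cols = norm.groups[norm.groups == g].index
        ols_mean = norm.intensities[cols].mean(axis=1)
        assert np.max(np.abs(gls.coef[g] - ols_mean)) < 1e-10


def test_gls_invariant_to_joint_sample_permutation(normalized):
    norm, _ = normalized
    design = ex.DesignSpec.from_experiment(norm, ex.EAE_CONTRASTS)
    fit = ex.fit_gls(norm, design, rho=0.2)
    cols = list(norm.intensities.columns)
    rng = np.random.default_rng(3)
    perm = [cols[i] for i in rng.permutation(len(cols))]
    shuffled = ex.ExpressionExperiment(
        intensities=norm.intensities[perm],
        detection_p=None,
        sample_annot=norm.sample_annot.loc[perm],
        probe_annot=norm.probe_annot,
        scale="normalized",
    ).validate()
    fit2 = ex.fit_gls(shuffled, ex.DesignSpec.from_experiment(shuffled, ex.EAE_CONTRASTS), rho=0.2)
    pd.testing.assert_frame_equal(fit.coef, fit2.coef)
    pd.testing.assert_series_equal(fit.s2, fit2.s2)


def test_contrast_with_unknown_group_errors():
    exp = _two_group_exp([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"],
                         ["b1", "b1", "b2", "b2"])
    design = ex.DesignSpec.from_experiment(exp, {})
    fit = ex.fit_gls(exp, design, 0.0)
    with pytest.raises(ex.ValidationError, match="not in design"):
        ex.contrast_tests(fit, ex.ModerationParams(d0=np.inf, s02=1.0),
                          {"A": 1.0, "Z": -1.0})


# ---------------------------------------------------------------------------
# consensus correlation
# ---------------------------------------------------------------------------

def test_consensus_rho_recovery():
    for rho_true, lo, hi in ((0.3, 0.2, 0.4), (0.0, -0.05, 0.05)):
        sb = np.sqrt(rho_true / (1 - rho_true)) if rho_true else 0.0
        cfg = clean_config(seed=17, n_probes=2000, sigma_block=sb)
        exp, truth = ex.simulate_experiment(cfg)
        norm = ex.vst_transform(ex.filter_probes(exp))
        design = ex.DesignSpec.from_experiment(norm, ex.EAE_CONTRASTS)
        rho_hat = ex.estimate_consensus_correlation(norm, design)
        assert lo <= rho_hat <= hi, (rho_true, rho_hat)


def test_consensus_upper_clamp_on_duplicated_samples():
    """Samples duplicated within blocks leave only block-shared residual
    variation: the estimate sits at the upper clamp."""
    rng = np.random.default_rng(0)
    n_probes = 60
    base = rng.normal(size=(n_probes, 4))  # one value per (probe, block)
    # 4 blocks of 2 samples (groups A, B); the two samples of a block are
    # duplicates, so all residual variation is block-shared
    values = np.repeat(base, 2, axis=1)
    samples = pd.Index([f"s{i}" for i in range(8)], name="sample_id")
    probes = pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id")
    exp = ex.ExpressionExperiment(
        intensities=pd.DataFrame(values, index=probes, columns=samples),
        detection_p=None,
        sample_annot=pd.DataFrame(
            {"group": ["A", "B"] * 4,
             "block": [f"b{i // 2}" for i in range(8)],
             "position": [str(i) for i in range(8)]},
            index=samples),
        probe_annot=pd.DataFrame({"gene_id": probes, "quality": "good"},
                                 index=probes),
        scale="normalized",
    ).validate()
    design = ex.DesignSpec.from_experiment(exp, {})
    rho = ex.estimate_consensus_correlation(exp, design)
    assert rho > 0.9


def test_consensus_single_block_errors(tiny_experiment):
    design = ex.DesignSpec.from_experiment(tiny_experiment, {})
    with pytest.raises(ex.ValidationError, match="least squares"):
        ex.estimate_consensus_correlation(tiny_experiment, design)


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

def test_moderate_identical_variances_gives_infinite_d0():
    params = moderate(np.full(100, 0.25), df=10.0)
    assert np.isinf(params.d0)
    assert params.s02 == pytest.approx(0.25, rel=1e-6)


def test_moderate_scale_equivariance():
    rng = np.random.default_rng(1)
    s2 = 4.0 * 0.05 / rng.chisquare(4.0, 3000) * rng.chisquare(10, 3000) / 10
    a = moderate(s2, df=10.0)
    b = moderate(2.0 * s2, df=10.0)
    assert b.s02 == pytest.approx(2.0 * a.s02, rel=1e-9)
    assert b.d0 == pytest.approx(a.d0, rel=1e-9)


def test_moderate_requires_enough_probes():
    with pytest.raises(ex.ValidationError):
        moderate(np.ones(5), df=4.0)


def test_moderate_recovers_prior_hyperparameters():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        sigma2 = 4.0 * 0.05 / rng.chisquare(4.0, 5000)
        s2 = sigma2 * rng.chisquare(18, 5000) / 18
        p = moderate(s2, df=18.0)
        hits += (3.2 <= p.d0 <= 4.8) and (0.04 <= p.s02 <= 0.06)
    assert hits >= 18


# ---------------------------------------------------------------------------
# contrast tests
# ---------------------------------------------------------------------------

def test_d0_zero_gives_ordinary_t(normalized):
    norm, _ = normalized
    design = ex.DesignSpec.from_experiment(norm, ex.EAE_CONTRASTS)
    fit = ex.fit_gls(norm, design, rho=0.0)
    tab = ex.contrast_tests(fit, ex.ModerationParams(d0=0.0, s02=1.0),
                            ex.EAE_CONTRASTS["OSE4-OSE0"])
    c = ex.de.contrast_vector(ex.EAE_CONTRASTS["OSE4-OSE0"], fit.group_levels)
    u = np.sqrt(c @ fit.cov_unscaled @ c)
    t_ord = (fit.coef.to_numpy() @ c) / (u * np.sqrt(fit.s2.to_numpy()))
    assert np.allclose(tab["t"].to_numpy(), t_ord)


def test_moderated_t_monotone_in_lfc():
    """For fixed u and variance, |t| increases with |logFC|."""
    fit = ex.FitResult(
        coef=pd.DataFrame({"A": np.zeros(5), "B": np.linspace(0.5, 2.5, 5)},
                          index=pd.Index([f"p{i}" for i in range(5)])),
        s2=pd.Series(np.full(5, 0.1), index=[f"p{i}" for i in range(5)]),
        df_resid=10.0, cov_unscaled=np.eye(2) * 0.25,
        group_levels=["A", "B"], rho=0.0, n_samples=8,
    )
    tab = ex.contrast_tests(fit, ex.ModerationParams(4.0, 0.1),
                            {"B": 1.0, "A": -1.0})
    assert (np.diff(np.abs(tab["t"].to_numpy())) > 0).all()
    # BH adjusted p are a monotone transform of raw p
    order = np.argsort(tab["p"].to_numpy())
    assert (np.diff(tab["p_adj"].to_numpy()[order]) >= -1e-15).all()
    assert tab["p_adj"].min() >= tab["p"].min()


def test_null_raw_p_calibrated():
    """pi = 0 synthetic data: fraction of raw p < 0.05 within binomial 99%
    bounds across 20 seeds."""
    fracs = []
    total = 0
    hits = 0
    for seed in range(20):
        cfg = clean_config(seed=seed, n_probes=400)
        exp, _ = ex.simulate_experiment(cfg)
        norm = ex.vst_transform(ex.filter_probes(exp))
        tables, _, _ = ex.run_de(norm, {"OSE4-OSE0": ex.EAE_CONTRASTS["OSE4-OSE0"]})
        p = tables["OSE4-OSE0"]["p"].to_numpy()
        hits += int((p < 0.05).sum())
        total += p.size
    frac = hits / total
    # p-values across probes are weakly dependent; allow 2x the iid band
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / total)
    assert abs(frac - 0.05) <= 2 * half_width


def test_fdr_and_sensitivity(contrast_tables):
    tables, rho, params, truth = contrast_tables
    tab = tables["OSE4-OSE0"]
    true_de = truth.de_indicator(ex.EAE_CONTRASTS["OSE4-OSE0"]).loc[tab.index]
    called = tab["significant"]
    fdr = (called & ~true_de).sum() / max(int(called.sum()), 1)
    sens = (called & true_de).sum() / max(int(true_de.sum()), 1)
    assert fdr <= 0.12      # single-seed bound; the averaged bound is 0.075
    assert sens >= 0.5


def test_direction_matches_logfc_sign(contrast_tables):
    tables, *_ = contrast_tables
    for tab in tables.values():
        sig = tab[tab["significant"]]
        assert (np.where(sig["logFC"] >= 0, "up", "down") == sig["direction"]).all()


def test_zscore_limit_with_infinite_d0():
    """d0 = inf and equal group sizes: the moderated test equals a z-test
    with the pooled prior variance."""
    exp = _two_group_exp([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"],
                         ["b1", "b2", "b1", "b2"])
    design = ex.DesignSpec.from_experiment(exp, {})
    fit = ex.fit_gls(exp, design, rho=0.0)
    s02 = 0.5
    tab = ex.contrast_tests(fit, ex.ModerationParams(np.inf, s02),
                            {"B": 1.0, "A": -1.0})
    # closed form: z = lfc / sqrt(s02 * (1/2 + 1/2))
    z = 2.0 / np.sqrt(s02 * (0.5 + 0.5))
    assert tab["t"].iloc[0] == pytest.approx(z)
    from scipy import stats
    assert tab["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(z))


def test_agrees_with_limma(tmp_path):
    """Independent oracle: consensus correlation, variance-prior
    hyperparameters and moderated t agree with limma's
    duplicateCorrelation / lmFit / eBayes on a small clean dataset."""
    cfg = clean_config(seed=42, n_probes=400, de_fraction=0.1)
    exp, _ = ex.simulate_experiment(cfg)
    norm = ex.vst_transform(ex.filter_probes(exp))
    design = ex.DesignSpec.from_experiment(norm, ex.EAE_CONTRASTS)
    rho = ex.estimate_consensus_correlation(norm, design)
    fit = ex.fit_gls(norm, design, rho)
    params = moderate(fit)
    tab = ex.contrast_tests(fit, params, ex.EAE_CONTRASTS["OSE4-OSE0"])

    norm.intensities.to_csv(tmp_path / "y.tsv", sep="\t")
    norm.sample_annot.to_csv(tmp_path / "s.tsv", sep="\t")
    script = f"""
    suppressMessages(library(limma))
    y <- as.matrix(read.delim("{tmp_path}/y.tsv", row.names=1, check.names=FALSE))
    s <- read.delim("{tmp_path}/s.tsv", row.names=1)
    grp <- factor(s$group); blk <- factor(s$block)
    design <- model.matrix(~0+grp); colnames(design) <- levels(grp)
    dc <- duplicateCorrelation(y, design, block=blk)
    fit <- lmFit(y, design, block=blk, correlation=dc$consensus.correlation)
    cm <- makeContrasts(OSE4-OSE0, levels=design)
    fit2 <- eBayes(contrasts.fit(fit, cm))
    out <- data.frame(lfc=fit2$coefficients[,1], t=fit2$t[,1])
    write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
    cat(dc$consensus.correlation, fit2$df.prior, fit2$s2.prior, "\\n")
    """
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    cons, d0_l, s02_l = map(float, r.stdout.split()[-3:])
    lim = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
    assert abs(rho - cons) < 0.05
    assert params.d0 == pytest.approx(d0_l, rel=0.05)
    assert params.s02 == pytest.approx(s02_l, rel=0.05)
    assert np.max(np.abs(tab["logFC"].to_numpy() - lim["lfc"].to_numpy())) < 1e-8
    rel = np.abs(tab["t"].to_numpy() - lim["t"].to_numpy()) / np.abs(lim["t"].to_numpy())
    assert np.median(rel) < 0.02
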