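"""Synthetic bead-array experiments with ground truth.

The generator emulates the randomized block structure of the two array
experiments the pipeline targets: a 24-sample spinal-cord experiment with six
mouse groups (WT, OSE0, OSE1, OSE4, CFA, MOG4) hybridized on four chips, one
sample per group per chip; and an 18-sample T-helper-cell experiment
(4 x TH0, 7 x TH1, 7 x TH17) from four mouse pools.

Model, on log2 scale, for an expressed probe g in sample s of group k on
block b:

    y_gs = baseline_g + delta_{g,k} + sigma_block * sigma_g * z_{g,b}
           + eps_gs,    eps_gs ~ N(0, sigma_g^2)

with per-probe residual variances sigma_g^2 drawn from a scaled
inverse-chi-square prior (d0_true, s0sq_true), so the downstream moderation
hyperparameters are recoverable by construction.  The block effect is scaled
by the probe's own residual sd; this makes the within-block correlation

    rho_true = sigma_block^2 / (1 + sigma_block^2)

identical for every probe — exactly the compound-symmetry model the
consensus-correlation estimator assumes.

On the raw scale, intensity = additive background + 2**(y + technical noise),
so raw-scale variance grows with the mean (the relationship the
variance-stabilizing transform must flatten).  A fraction of probes is not
expressed at all and shows background intensity only; detection p-values are
the upper-tail probability of the background distribution at the observed
intensity, mimicking bead-array detection semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionExperiment, GeneSetCollection, ValidationError

EAE_GROUPS = ("WT", "OSE0", "OSE1", "OSE4", "CFA", "MOG4")
#: Groups carrying planted effects relative to their healthy baselines; the
#: control contrasts (CFA-WT, OSE0-WT) are null by construction.
EAE_DE_GROUPS = ("OSE1", "OSE4", "MOG4")

TH_GROUPS = ("TH0", "TH1", "TH17")
TH_DE_GROUPS = ("TH1", "TH17")
TH_GROUP_SIZES = {"TH0": 4, "TH1": 7, "TH17": 7}

# fixed offsets deriving stage-specific child streams from the master seed
_STAGE_OFFSETS = {
    "variances": 1, "baseline": 2, "effects": 3, "blocks": 4,
    "residual": 5, "raw": 6, "background": 7, "geneset": 8,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_OFFSETS[stage],))
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment; defaults are the EAE design."""

    groups: tuple[str, ...] = EAE_GROUPS
    #: groups eligible for planted effects (the disease groups)
    de_groups: tuple[str, ...] = EAE_DE_GROUPS
    n_blocks: int = 4                     # chips / pools
    #: samples per group; None means one per group per block (balanced chips)
    group_sizes: dict[str, int] | None = None
    n_probes: int = 3000
    frac_two_probe_genes: float = 0.15    # genes measured by 2 probes
    frac_unannotated: float = 0.03        # probes with no gene id
    frac_bad_quality: float = 0.03        # probes labelled bad / no_match
    baseline_mean: float = 7.0            # log2 scale
    baseline_sd: float = 1.5
    #: block-effect sd in units of the probe's residual sd;
    #: implies rho_true = sigma_block^2 / (1 + sigma_block^2)
    sigma_block: float = 0.5774
    d0_true: float = 4.0                  # residual-variance prior df
    s0sq_true: float = 0.05               # residual-variance prior scale
    #: fraction of probes that are disease-responsive candidates; each
    #: candidate's direction of regulation is drawn once and shared across
    #: disease groups (stages of the same disease regulate shared
    #: transcripts in the same direction)
    de_fraction: float = 0.1
    lfc_magnitude: float = 1.0            # |log2 fold change| of planted effects
    #: probability that a DE group picks up a candidate probe; groups absent
    #: from the map use 1.0.  The defaults give the spinal-cord design its
    #: qualitative structure: a large common disease component, sets specific
    #: to either model, and a small mild-disease-specific set.
    group_de_inclusion: dict[str, float] = field(
        default_factory=lambda: {"OSE4": 0.9, "MOG4": 0.6, "OSE1": 0.4}
    )
    #: per-group multiplier on the effect magnitude; groups absent from the
    #: map use 1.0.  Mild disease (score 1) responds at half strength, so
    #: shared transcripts agree in direction but differ in magnitude.
    group_lfc_scale: dict[str, float] = field(
        default_factory=lambda: {"OSE1": 0.5}
    )
    expressed_fraction: float = 0.85
    bg_mean: float = 40.0                 # additive background, raw scale
    bg_sd: float = 8.0
    mult_sd: float = 0.1                  # technical lognormal noise, log2 sd
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.sigma_block < 0:
            raise ValidationError("sigma_block must be >= 0")
        if self.d0_true <= 0:
            raise ValidationError("d0_true must be > 0")
        if self.n_blocks < 2:
            raise ValidationError("need at least 2 blocks")
        if not set(self.de_groups) <= set(self.groups):
            raise ValidationError("de_groups must be a subset of groups")
        if not (0.0 < self.expressed_fraction <= 1.0):
            raise ValidationError("expressed_fraction must lie in (0, 1]")
        return self

    @property
    def rho_true(self) -> float:
        return self.sigma_block**2 / (1.0 + self.sigma_block**2)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated experiment."""

    #: probes x de_groups signed true log2 fold changes vs the group baseline
    true_lfc: pd.DataFrame
    #: per-probe true residual variance (log2 scale)
    residual_var: pd.Series
    rho_true: float
    d0_true: float
    s0sq_true: float
    expressed: pd.Series = field(default=None)  # boolean per probe
    #: filled by plant_gene_set
    planted_sets: dict[str, dict] = field(default_factory=dict)

    def de_indicator(self, contrast: dict[str, float]) -> pd.Series:
        """True DE status of every probe under a zero-sum group contrast."""
        lfc = self.contrast_lfc(contrast)
        return lfc.abs() > 1e-12

    def contrast_lfc(self, contrast: dict[str, float]) -> pd.Series:
        lfc = pd.Series(0.0, index=self.true_lfc.index)
        for grp, coef in contrast.items():
            if grp in self.true_lfc.columns:
                lfc = lfc + coef * self.true_lfc[grp]
        return lfc


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Assign samples to groups, blocks and on-block positions."""
    rows = []
    if config.group_sizes is None:
        # balanced: one sample per group per block; groups rotate across
        # positions (Latin-square style) so position is not confounded
        # with group
        k = len(config.groups)
        for b in range(config.n_blocks):
            for pos in range(k):
                rows.append((config.groups[(pos + b) % k], f"block{b + 1}", pos + 1))
    else:
        # distribute each group's samples across blocks round-robin
        counters = {b: 0 for b in range(config.n_blocks)}
        offset = 0
        for grp in config.groups:
            n = config.group_sizes[grp]
            for i in range(n):
                b = (i + offset) % config.n_blocks
                counters[b] += 1
                rows.append((grp, f"block{b + 1}", counters[b]))
            offset += n
    df = pd.DataFrame(rows, columns=["group", "block", "position"])
    df.index = pd.Index([f"S{i + 1:02d}" for i in range(len(df))], name="sample_id")
    df["position"] = df["position"].astype(str)
    return df


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionExperiment, SyntheticTruth]:
    """Simulate a raw-scale experiment plus its ground truth."""
    config.validate()
    G = config.n_probes
    sheet = _sample_sheet(config)
    n = len(sheet)
    probe_ids = pd.Index([f"p{i + 1:05d}" for i in range(G)], name="probe_id")

    # probe -> gene annotation: some genes carry two probes, some probes none
    rng_g = _rng(config.seed, "geneset")
    gene_ids: list[str | None] = []
    gi = 0
    pending: str | None = None
    for _ in range(G):
        if rng_g.random() < config.frac_unannotated:
            gene_ids.append(None)
            continue
        if pending is not None:
            gene_ids.append(pending)
            pending = None
            continue
        gi += 1
        gid = f"g{gi:05d}"
        gene_ids.append(gid)
        if rng_g.random() < config.frac_two_probe_genes:
            pending = gid
    quality = np.where(
        rng_g.random(G) < config.frac_bad_quality,
        rng_g.choice(["bad", "no_match"], size=G),
        rng_g.choice(["perfect", "good"], size=G, p=[0.8, 0.2]),
    )
    probe_annot = pd.DataFrame(
        {"gene_id": gene_ids, "quality": quality}, index=probe_ids
    )

    # per-probe residual variance from the scaled inverse-chi-square prior
    rng_v = _rng(config.seed, "variances")
    sigma2 = config.d0_true * config.s0sq_true / rng_v.chisquare(config.d0_true, G)
    sigma = np.sqrt(sigma2)

    rng_b = _rng(config.seed, "baseline")
    baseline = rng_b.normal(config.baseline_mean, config.baseline_sd, G)
    expressed = rng_b.random(G) < config.expressed_fraction

    # planted effects: disease-responsive candidates with a shared sign,
    # picked up by each DE group with its inclusion probability
    rng_e = _rng(config.seed, "effects")
    candidate = (rng_e.random(G) < config.de_fraction) & expressed
    shared_sign = np.where(rng_e.random(G) < 0.5, -1.0, 1.0)
    lfc = pd.DataFrame(0.0, index=probe_ids, columns=list(config.de_groups))
    for grp in config.de_groups:
        incl = config.group_de_inclusion.get(grp, 1.0)
        hit = candidate & (rng_e.random(G) < incl)
        scale = config.group_lfc_scale.get(grp, 1.0)
        lfc[grp] = np.where(hit, shared_sign * scale * config.lfc_magnitude, 0.0)

    # assemble log2 signal
    group_idx = {g: i for i, g in enumerate(config.groups)}
    blocks = sorted(sheet["block"].unique())
    block_idx = {b: i for i, b in enumerate(blocks)}
    rng_blk = _rng(config.seed, "blocks")
    z_block = rng_blk.standard_normal((G, len(blocks)))
    rng_r = _rng(config.seed, "residual")
    eps = rng_r.standard_normal((G, n)) * sigma[:, None]

    effects = np.zeros((G, len(config.groups)))
    for grp in config.de_groups:
        effects[:, group_idx[grp]] = lfc[grp].to_numpy()

    col_group = sheet["group"].map(group_idx).to_numpy()
    col_block = sheet["block"].map(block_idx).to_numpy()
    y = (
        baseline[:, None]
        + effects[:, col_group]
        + config.sigma_block * sigma[:, None] * z_block[:, col_block]
        + eps
    )

    # raw scale: additive background + exponentiated signal with technical noise
    rng_raw = _rng(config.seed, "raw")
    tech = rng_raw.normal(0.0, config.mult_sd, (G, n))
    rng_bg = _rng(config.seed, "background")
    bg = rng_bg.normal(config.bg_mean, config.bg_sd, (G, n))
    raw = np.clip(bg, 0.0, None) + np.where(expressed[:, None], 2.0 ** (y + tech), 0.0)
    detection = stats.norm.sf(raw, loc=config.bg_mean, scale=config.bg_sd)

    exp = ExpressionExperiment(
        intensities=pd.DataFrame(raw, index=probe_ids, columns=sheet.index),
        detection_p=pd.DataFrame(detection, index=probe_ids, columns=sheet.index),
        sample_annot=sheet,
        probe_annot=probe_annot,
        scale="raw",
    ).validate()
    truth = SyntheticTruth(
        true_lfc=lfc,
        residual_var=pd.Series(sigma2, index=probe_ids),
        rho_true=config.rho_true if config.sigma_block > 0 else 0.0,
        d0_true=config.d0_true,
        s0sq_true=config.s0sq_true,
        expressed=pd.Series(expressed, index=probe_ids),
    )
    return exp, truth


def th_config(**overrides) -> SimulationConfig:
    """Default configuration of the T-helper-cell experiment (18 samples,
    4 pools, unbalanced 4/7/7 group sizes)."""
    base = dict(
        groups=TH_GROUPS,
        de_groups=TH_DE_GROUPS,
        group_sizes=dict(TH_GROUP_SIZES),
        n_blocks=4,
        # polarized TH1 cells regulate far more transcripts specifically
        # than TH17 cells do in the emulated experiment
        group_de_inclusion={"TH1": 0.9, "TH17": 0.45},
        group_lfc_scale={},
    )
    base.update(overrides)
    return SimulationConfig(**base)


def simulate_th_experiment(
    config: SimulationConfig | None = None, **overrides
) -> tuple[ExpressionExperiment, SyntheticTruth]:
    """Simulate the T-helper-cell experiment (pools as blocks)."""
    if config is None:
        config = th_config(**overrides)
    return simulate_experiment(config)


def plant_gene_set(
    truth: SyntheticTruth,
    contrast: dict[str, float],
    set_size: int,
    omega: float,
    seed: int,
    universe: list[str] | None = None,
    gene_map: pd.Series | None = None,
    name: str = "planted",
) -> GeneSetCollection:
    """Plant a gene set whose DE-gene membership odds are ``omega``-fold
    those of non-DE genes, renormalized to expected size ``set_size``.

    ``gene_map`` maps probe_id -> gene_id; when omitted probes stand in for
    genes.  ``omega = 1`` yields uniform sampling; ``omega = inf`` samples
    from DE genes only.
    """
    de_probe = truth.de_indicator(contrast)
    if gene_map is not None:
        df = pd.DataFrame({"gene": gene_map, "de": de_probe}).dropna(subset=["gene"])
        de_by_gene = df.groupby("gene")["de"].any()
    else:
        de_by_gene = de_probe.copy()
        de_by_gene.index = de_by_gene.index.astype(str)
    if universe is not None:
        de_by_gene = de_by_gene.reindex(universe, fill_value=False)
    genes = de_by_gene.index.to_numpy()
    is_de = de_by_gene.to_numpy(dtype=bool)
    G = len(genes)
    if set_size > G:
        raise ValidationError(f"set_size {set_size} exceeds universe size {G}")
    n_de = int(is_de.sum())
    n_non = G - n_de

    if np.isinf(omega):
        q = max(0.0, (set_size - n_de) / n_non) if n_non else 0.0
        p_de = min(1.0, set_size / n_de) if n_de else 0.0
    else:
        # solve for non-DE membership probability q so that expected size is K
        def expected(q: float) -> float:
            p_de = omega * q / (1.0 - q + omega * q)
            return n_de * p_de + n_non * q

        from scipy.optimize import brentq

        if expected(1.0 - 1e-12) < set_size:
            q = 1.0
        else:
            q = brentq(lambda x: expected(x) - set_size, 1e-15, 1.0 - 1e-12)
        p_de = omega * q / (1.0 - q + omega * q)

    rng = np.random.default_rng(int(seed) % (2**31))
    prob = np.where(is_de, p_de, q)
    member = rng.random(G) < prob
    members = frozenset(genes[member])
    truth.planted_sets[name] = {
        "omega": omega, "target_size": set_size, "realized_size": len(members),
        "n_de_genes": n_de,
    }
    return GeneSetCollection(
        {name: members},
        {name: f"planted omega={omega} target_size={set_size}"},
    )
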