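# eaexpr

Statistical pipeline for bead-array expression studies of experimental
autoimmune encephalomyelitis (EAE): blocked moderated-t differential
expression, directional contrast set algebra, permutation gene-set overlap
enrichment, gene-set principal-component disease scoring, k-means
partition-stability analysis, and paired exact binomial fold-change tests —
together with a synthetic-data generator that emulates the study designs so
every stage is testable without any data download.

## Who this is for

Analysts comparing spontaneous (opticospinal, OSE) and induced (MOG₃₅₋₅₅)
EAE models at the transcriptome level, and anyone who needs the same
machinery for similar randomized-block array designs: a small number of
experimental groups hybridized across chips (or cell pools), probe-level
intensities with detection p-values, and downstream questions about
enrichment of externally defined gene lists (e.g., prioritized human
MS susceptibility genes, T-helper-cell signatures).

## The statistics at the core

**Blocked moderated t.** Per probe *g*, a group-means linear model is fitted
by generalized least squares with a compound-symmetry covariance: samples on
the same chip/pool share a within-block correlation ρ, estimated once across
all probes (per-probe REML, then tanh of a 15%-trimmed mean of atanh of the
per-probe estimates). Residual variances are shrunk toward a scaled
inverse-χ² prior whose hyperparameters (d₀, s₀²) are estimated by
digamma/trigamma moment matching on log s²_g, giving

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t̃_g  = logFC_g / (u_c · s̃_g)   ~  t(d₀ + d_g),

with Benjamini–Hochberg adjustment within each contrast.

**Permutation overlap enrichment.** For a list of differentially expressed
genes and a test set, each of n_perm = 100,000 permutations draws an equally
sized random gene set from the universe and records whether its overlap with
the test set reaches the observed one; p = max(exceedances, 1)/n_perm, with
zero exceedances reported censored as "< 1/n_perm". Tables of such tests are
adjusted by the Holm step-down procedure (BH selectable). The exact
hypergeometric tail is provided as an analytic oracle, and generic
hypergeometric ORA with BH adjustment is included.

**Paired binomial tests.** Probe-paired comparisons of |logFC| magnitude and
direction agreement between contrasts use the exact two-sided binomial test
against 1/2, computed in log space (accurate far below double-precision
underflow), with 95% Clopper–Pearson intervals.

## Worked example

Run the whole pipeline on the default synthetic spinal-cord design
(six groups — WT, OSE0, OSE1, OSE4, CFA, MOG4 — on four chips, one sample
per group per chip, 3,000 probes):

```bash
eaexpr run --seed 7 --out-dir demo
```

Selected output from `demo/summary.json`:

```
"n_probes_filtered": 2324,
"consensus_correlation": 0.156,
"d0": 5.38, "s02": 0.0449,
"n_significant": {"OSE4-OSE0": 176, "MOG4-CFA": 108, "OSE1-OSE0": 3,
                  "OSE4-WT": 161, "CFA-WT": 0, "OSE0-WT": 0}
```

2,324 of 3,000 probes survive the detection/quality filter. The consensus
within-chip correlation of 0.16 is the technical-noise-diluted trace of the
generator's planted block effect; d₀ ≈ 5.4 and s₀² ≈ 0.045 are the variance
prior recovered from the data (the generator plants d₀ = 4, s₀² = 0.05;
raw-scale noise adds a little apparent dispersion). The two control
contrasts are null by construction and yield 0 significant transcripts,
while the disease contrasts recover the planted effects.

The enrichment table (risk-gene rows; the planted "risk" set has
odds-ratio 4 membership bias toward OSE4-responsive genes):

```
analysis_set  n_de  overlap  p         p_adj
CDT             81       39  <1e-05    1e-04
OSE4sp          87       44  <1e-05    1e-04
MOG4sp          23        7  0.424     1
OSE1ex           3        1  0.61      1
```

CDT (transcripts shared by both disease models, clean of control contrasts)
and OSE4sp (OSE-specific) are strongly enriched; the MOG-specific set is
not — the qualitative pattern the pipeline is designed to detect. The paired
magnitude test reports that fold changes are systematically larger in
OSE4−OSE0 than in OSE1−OSE0 (n = 2,324 informative pairs, k = 1,278,
p = 1.6 × 10⁻⁶), mirroring the stronger expression response of full-blown
disease.

Every stage is also available separately (`eaexpr simulate | preprocess |
de | sets | enrich | score | paired`, see `--help`), and as library
functions (`eaexpr.run_de`, `eaexpr.permutation_overlap_test`, ...).

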