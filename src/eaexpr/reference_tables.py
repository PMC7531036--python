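"""Published enrichment-table p-values of the study whose design the
synthetic generator emulates, kept as regression inputs.

Three enrichment tables were published for that study: enrichment of MS
susceptibility genes in the spinal-cord analysis sets (table 1), enrichment
of T-helper-cell-specific transcripts in the same sets (table 2), and
enrichment of MS susceptibility genes within the T-helper-intersected sets
(table 3).  Each row carries the raw permutation p-value (100,000
permutations; zero exceedances stored as 1/n_perm and flagged censored) and
the printed step-down-adjusted value at two significant figures.  Applying
:func:`eaexpr.enrich.holm_adjust` to the raw columns must reproduce every
adjusted cell — the package's regression check that its adjustment and
censoring conventions match the published analysis.
"""

from __future__ import annotations

N_PERM_PUBLISHED = 100_000

#: (row label, raw p, censored flag, printed adjusted p)
TABLE1_MS_RISK = [
    ("CDT", 1.0e-5, True, 4.0e-5),
    ("OSE4sp", 4.4e-4, False, 8.8e-4),
    ("MOG4sp", 3.2e-1, False, 3.2e-1),
    ("OSE1ex", 1.0e-5, False, 4.0e-5),
]

TABLE2_TH_SPECIFIC = [
    ("CDT|TH1", 1.0e-5, True, 8.0e-5),
    ("CDT|TH17", 2.0e-2, False, 4.0e-2),
    ("OSE4sp|TH1", 1.0e-5, True, 8.0e-5),
    ("OSE4sp|TH17", 2.0e-3, False, 8.0e-3),
    ("MOG4sp|TH1", 1.1e-2, False, 3.3e-2),
    ("MOG4sp|TH17", 9.8e-2, False, 9.8e-2),
    ("OSE1ex|TH1", 2.0e-5, False, 1.2e-4),
    ("OSE1ex|TH17", 1.0e-3, False, 5.0e-3),
]

TABLE3_MS_RISK_IN_TH = [
    ("CDT|TH1", 6.5e-4, False, 5.2e-3),
    ("CDT|TH17", 2.1e-2, False, 1.1e-1),
    ("OSE4sp|TH1", 9.7e-3, False, 5.8e-2),
    ("OSE4sp|TH17", 4.7e-2, False, 1.6e-1),
    ("MOG4sp|TH1", 5.1e-1, False, 5.1e-1),
    ("MOG4sp|TH17", 1.3e-1, False, 2.6e-1),
    ("OSE1ex|TH1", 1.1e-3, False, 7.7e-3),
    ("OSE1ex|TH17", 3.9e-2, False, 1.6e-1),
]

ALL_TABLES = {
    "table1": TABLE1_MS_RISK,
    "table2": TABLE2_TH_SPECIFIC,
    "table3": TABLE3_MS_RISK_IN_TH,
}

#: Antisense transcripts removed from the 558 non-MHC MS-risk candidates to
#: form the 551-gene prioritized susceptibility list.
EXCLUDED_ANTISENSE_GENES = [
    "CTB-50L17.10",
    "RP11-345J4.5",
    "JAZF1-AS1",
    "ZEB1-AS1",
    "GATA3-AS1",
    "SSTR5-AS1",
    "RPL34-AS1",
]


def two_sig_figs(x: float) -> float:
    """Round to two significant figures (the precision of the printed cells)."""
    return float(f"{x:.1e}")
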