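"""Directional set algebra over contrast tables.

Builds the named analysis sets used downstream — common disease transcripts
(CDT), the model-specific sets (OSE4sp, MOG4sp), and the mild-disease sets
(OSE1ex, OSE1sp) — from boolean rules over per-contrast significance flags,
plus direction-separated Venn region counts.  Set membership is
direction-agnostic (a probe differentially expressed in any direction
belongs); the direction is kept as an annotation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import ValidationError

logger = logging.getLogger("eaexpr")

#: default control contrasts of the spinal-cord design
EAE_CONTROL_CONTRASTS = ("CFA-WT", "OSE0-WT")


def _check_universe(tables: dict[str, pd.DataFrame] | list[pd.DataFrame]):
    tabs = list(tables.values()) if isinstance(tables, dict) else list(tables)
    base = list(tabs[0].index)
    for t in tabs[1:]:
        if list(t.index) != base:
            raise ValidationError("contrast tables have mismatched probe universes")


# ---------------------------------------------------------------------------
# Venn regions, up and down separately
# ---------------------------------------------------------------------------

def directional_venn(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts of probes per inclusion/exclusion region across contrasts,
    tallied separately for up- and downregulation.

    A probe significant up in one contrast and down in another contributes
    to both direction-specific tallies (in different regions).
    """
    _check_universe(tables)
    names = list(tables)
    rows = []
    for direction in ("up", "down"):
        flags = pd.DataFrame(
            {
                n: tables[n]["significant"] & (tables[n]["direction"] == direction)
                for n in names
            }
        )
        for membership in itertools.product([False, True], repeat=len(names)):
            if not any(membership):
                continue
            mask = pd.Series(True, index=flags.index)
            for n, m in zip(names, membership):
                mask &= flags[n] if m else ~flags[n]
            rows.append(
                {
                    "direction": direction,
                    "region": "&".join(n for n, m in zip(names, membership) if m),
                    **{n: m for n, m in zip(names, membership)},
                    "count": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# named analysis sets
# ---------------------------------------------------------------------------

@dataclass
class TranscriptSet:
    """A named probe set with per-probe direction annotation and rule."""

    name: str
    probes: frozenset[str]
    direction: dict[str, str]     # probe -> up/down in the defining contrast
    rule: str                     # human-readable boolean provenance


@dataclass
class TranscriptSetCollection:
    sets: dict[str, TranscriptSet] = field(default_factory=dict)

    def __getitem__(self, name: str) -> TranscriptSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, ts: TranscriptSet) -> None:
        self.sets[ts.name] = ts

    def gene_sets(self, gene_map: pd.Series) -> dict[str, set[str]]:
        """Gene-level projections of every set."""
        return {
            name: collapse_to_genes(ts.probes, gene_map)
            for name, ts in self.sets.items()
        }


def _sig(tables: dict[str, pd.DataFrame], name: str) -> pd.Series:
    if name not in tables:
        raise ValidationError(f"required contrast {name!r} missing from tables")
    return tables[name]["significant"]


def define_analysis_sets(
    tables: dict[str, pd.DataFrame],
    disease_contrasts: tuple[str, str] = ("OSE4-OSE0", "MOG4-CFA"),
    mild_contrast: str = "OSE1-OSE0",
    control_contrasts: tuple[str, ...] = EAE_CONTROL_CONTRASTS,
) -> TranscriptSetCollection:
    """Build the five named spinal-cord analysis sets from significance flags.

    CDT     : significant in both disease contrasts, in no control contrast.
    OSE4sp  : significant in the first disease contrast only (not the second,
              not the controls).
    MOG4sp  : the mirror image of OSE4sp.
    OSE1ex  : significant in the mild contrast, in no control contrast.
    OSE1sp  : significant in the mild contrast and in no other contrast at all.
    """
    _check_universe(tables)
    ose4, mog4 = disease_contrasts
    s_ose4, s_mog4 = _sig(tables, ose4), _sig(tables, mog4)
    s_mild = _sig(tables, mild_contrast)
    s_ctrl = pd.Series(False, index=s_ose4.index)
    for c in control_contrasts:
        s_ctrl = s_ctrl | _sig(tables, c)
    # significant in any non-mild, non-control contrast (for OSE1sp's
    # "not in any other contrast")
    s_other = pd.Series(False, index=s_ose4.index)
    for name in tables:
        if name != mild_contrast:
            s_other = s_other | _sig(tables, name)

    rules = {
        "CDT": (s_ose4 & s_mog4 & ~s_ctrl,
                f"({ose4} & {mog4}) & ~controls"),
        "OSE4sp": (s_ose4 & ~s_mog4 & ~s_ctrl,
                   f"{ose4} & ~{mog4} & ~controls"),
        "MOG4sp": (s_mog4 & ~s_ose4 & ~s_ctrl,
                   f"{mog4} & ~{ose4} & ~controls"),
        "OSE1ex": (s_mild & ~s_ctrl,
                   f"{mild_contrast} & ~controls"),
        "OSE1sp": (s_mild & ~s_other,
                   f"{mild_contrast} & ~any other contrast"),
    }
    primary = {"CDT": ose4, "OSE4sp": ose4, "MOG4sp": mog4,
               "OSE1ex": mild_contrast, "OSE1sp": mild_contrast}
    out = TranscriptSetCollection()
    for name, (mask, rule) in rules.items():
        probes = frozenset(mask.index[mask])
        dirs = tables[primary[name]]["direction"]
        out.add(
            TranscriptSet(
                name=name,
                probes=probes,
                direction={p: dirs.loc[p] for p in probes},
                rule=rule,
            )
        )
    return out


def define_exclusive_sets(
    tables: dict[str, pd.DataFrame], suffix: str = "sp"
) -> TranscriptSetCollection:
    """Pairwise exclusive/common sets for a two-contrast design (the
    T-helper-cell experiment): significant in A only, in B only, in both."""
    _check_universe(tables)
    names = list(tables)
    if len(names) != 2:
        raise ValidationError("define_exclusive_sets expects exactly two tables")
    a, b = names
    sa, sb = _sig(tables, a), _sig(tables, b)
    out = TranscriptSetCollection()
    for name, mask, rule, src in (
        (f"{a}{suffix}", sa & ~sb, f"{a} & ~{b}", a),
        (f"{b}{suffix}", sb & ~sa, f"{b} & ~{a}", b),
        (f"{a}&{b}", sa & sb, f"{a} & {b}", a),
    ):
        probes = frozenset(mask.index[mask])
        dirs = tables[src]["direction"]
        out.add(TranscriptSet(name, probes, {p: dirs.loc[p] for p in probes}, rule))
    return out


def collapse_to_genes(probes, gene_map: pd.Series) -> set[str]:
    """Project a probe set to unique gene ids; unannotated probes dropped."""
    genes: set[str] = set()
    dropped = 0
    for p in probes:
        g = gene_map.get(p)
        if g is None or (isinstance(g, float) and pd.isna(g)) or g == "":
            dropped += 1
        else:
            genes.add(str(g))
    if dropped:
        logger.info("collapse_to_genes: %d unannotated probe(s) dropped", dropped)
    return genes


def direction_conflicts(ts: TranscriptSet, gene_map: pd.Series) -> set[str]:
    """Genes whose probes in the set disagree in direction (flagged, kept)."""
    by_gene: dict[str, set[str]] = {}
    for p in ts.probes:
        g = gene_map.get(p)
        if g is None or (isinstance(g, float) and pd.isna(g)):
            continue
        by_gene.setdefault(str(g), set()).add(ts.direction[p])
    return {g for g, d in by_gene.items() if len(d) > 1}
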